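"""The five-hypothesis candidate set and the per-individual AIC competition.

Every candidate model extends a *core* habitat-plus-movement model
(cosTurnAngle + lnStepLength + dist/dens of the three forest classes +
dist to wetlands):

corridor
    core + dens_f × lag_dens_f for each core forest class and
    dist_f × lag_dist_f for each linear class — selection for steps whose
    habitat composition resembles the previous step's.
lcp (least-cost paths)
    core + dens_f × lnStepLength + dens_f × cosTurnAngle for each core
    forest class — movement speed/straightness covary with feature density.
stepping_stone
    core + dist/dens of protected areas + dens_PA × lnStepLength +
    dens_PA × cosTurnAngle + dens_PA × lag_dens_PA — PA patches anchor
    short, tortuous residency.
global
    union of all terms, screened for pairwise collinearity (|r| >= 0.7,
    later-listed term dropped).

"Previous step" effects enter only as current × lagged interactions: a pure
lagged main effect is constant within a stratum and therefore structurally
inestimable under exact conditioning (the engine would drop it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clogit import DesignMatrix, FitResult, fit_clogit
from .covariates import CovariateConfig, density_in_buffer
from .errors import InsufficientDataError, SchemaError, StepSelectError
from .landscape import LandscapeStack
from .schema import FeatureSchema

__all__ = [
    "Term",
    "ModelSpec",
    "CompetitionResult",
    "build_candidate_set",
    "build_design",
    "akaike_weights",
    "compete",
    "pa_residency",
]

MODEL_NAMES = ("core", "corridor", "lcp", "stepping_stone", "global")

CORE_FOREST = ("deciduous", "coniferous", "mixed")


@dataclass(frozen=True)
class Term:
    """main(a) or interact(a, b); named 'a' or 'a:b'."""

    a: str
    b: str | None = None

    @property
    def name(self) -> str:
        return self.a if self.b is None else f"{self.a}:{self.b}"

    def column(self, table: pd.DataFrame) -> pd.Series:
        if self.b is None:
            return table[self.a]
        return table[self.a] * table[self.b]


def main(a: str) -> Term:
    return Term(a)


def interact(a: str, b: str) -> Term:
    return Term(a, b)


@dataclass
class ModelSpec:
    name: str
    terms: list[Term] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise StepSelectError(f"model {self.name!r} has duplicate terms")

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]


def core_terms(schema: FeatureSchema) -> list[Term]:
    for f in CORE_FOREST + ("wetlands",):
        if f not in schema:
            raise SchemaError(f"core model requires class {f!r} in the schema")
    terms = [main("cos_turn_angle"), main("ln_step_length")]
    for f in CORE_FOREST:
        terms += [main(f"dist_{f}"), main(f"dens_{f}")]
    terms.append(main("dist_wetlands"))
    return terms


def build_candidate_set(
    schema: FeatureSchema,
    table: pd.DataFrame,
    collinearity_threshold: float = 0.7,
) -> list[ModelSpec]:
    """The five candidate models; the global spec is screened for pairwise
    collinearity on the (scaled) table."""
    pa = schema.pa_name
    for f in schema.linear:
        if f not in schema:  # pragma: no cover - schema guarantees this
            raise SchemaError(f"missing linear class {f!r}")
    core = core_terms(schema)
    corridor = core + [interact(f"dens_{f}", f"lag_dens_{f}") for f in CORE_FOREST]
    corridor += [interact(f"dist_{f}", f"lag_dist_{f}") for f in schema.linear]
    lcp = core + [interact(f"dens_{f}", "ln_step_length") for f in CORE_FOREST]
    lcp += [interact(f"dens_{f}", "cos_turn_angle") for f in CORE_FOREST]
    stepping = core + [
        main(f"dist_{pa}"),
        main(f"dens_{pa}"),
        interact(f"dens_{pa}", "ln_step_length"),
        interact(f"dens_{pa}", "cos_turn_angle"),
        interact(f"dens_{pa}", f"lag_dens_{pa}"),
    ]
    union: list[Term] = []
    seen = set()
    for t in core + corridor + lcp + stepping:
        if t.name not in seen:
            union.append(t)
            seen.add(t.name)
    global_terms = _collinearity_screen(union, table, collinearity_threshold)
    return [
        ModelSpec("core", core),
        ModelSpec("corridor", corridor),
        ModelSpec("lcp", lcp),
        ModelSpec("stepping_stone", stepping),
        ModelSpec("global", global_terms),
    ]


def _collinearity_screen(
    terms: list[Term], table: pd.DataFrame, threshold: float
) -> list[Term]:
    """Drop the later member of any term pair with |Pearson r| >= threshold."""
    cols = {t.name: t.column(table).to_numpy(dtype=float) for t in terms}
    kept: list[Term] = []
    for t in terms:
        x = cols[t.name]
        collinear = False
        for prev in kept:
            y = cols[prev.name]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if np.isfinite(r) and abs(r) >= threshold:
                collinear = True
                break
        if not collinear:
            kept.append(t)
    return kept


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    columns = {t.name: t.column(table) for t in spec.terms}
    return DesignMatrix.from_table(table, columns)


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2) with Δ relative to the best AIC."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0 or not np.all(np.isfinite(aics)):
        raise ValueError("AIC values must be finite and non-empty")
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    return w / w.sum()


@dataclass
class CompetitionResult:
    """Per-individual AIC ranking and the hypothesis tallies."""

    table: pd.DataFrame  # individual, model, n_terms, loglik, aic, delta_aic,
    #                      akaike_weight, concordance, rank
    tallies: pd.DataFrame  # hypothesis, rank1, rank2
    fits: dict[tuple[str, str], FitResult]
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compete(
    tables: dict[str, pd.DataFrame],
    specs: list[ModelSpec],
) -> CompetitionResult:
    """Fit every candidate model per individual and rank by AIC.

    Ties break toward parsimony (fewer terms), then by model name.
    Individuals with any failed or non-converged fit are excluded from the
    tallies and listed in ``failures``.
    """
    rows = []
    fits: dict[tuple[str, str], FitResult] = {}
    failures: list[tuple[str, str, str]] = []
    for ind, table in tables.items():
        ind_rows = []
        ok = True
        for spec in specs:
            try:
                fit = fit_clogit(build_design(table, spec))
            except StepSelectError as exc:
                failures.append((str(ind), spec.name, str(exc)))
                ok = False
                break
            if not fit.converged:
                failures.append((str(ind), spec.name, "did not converge"))
                ok = False
                break
            fits[(str(ind), spec.name)] = fit
            ind_rows.append(
                {
                    "individual": str(ind),
                    "model": spec.name,
                    "n_terms": len(fit.terms),
                    "loglik": fit.loglik,
                    "aic": fit.aic,
                    "concordance": fit.concordance,
                }
            )
        if not ok:
            continue
        df = pd.DataFrame(ind_rows)
        df["delta_aic"] = df["aic"] - df["aic"].min()
        df["akaike_weight"] = akaike_weights(df["aic"].to_numpy())
        df = df.sort_values(["aic", "n_terms", "model"], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    if rows:
        full = pd.concat(rows, ignore_index=True)
    else:
        full = pd.DataFrame(
            columns=[
                "individual", "model", "n_terms", "loglik", "aic",
                "concordance", "delta_aic", "akaike_weight", "rank",
            ]
        )
    tallies = pd.DataFrame(
        {
            "hypothesis": list(MODEL_NAMES),
            "rank1": [
                int(((full["model"] == m) & (full["rank"] == 1)).sum())
                for m in MODEL_NAMES
            ],
            "rank2": [
                int(((full["model"] == m) & (full["rank"] == 2)).sum())
                for m in MODEL_NAMES
            ],
        }
    )
    return CompetitionResult(table=full, tallies=tallies, fits=fits, failures=failures)


def pa_residency(
    steps: pd.DataFrame,
    stack: LandscapeStack,
    schema: FeatureSchema | None = None,
    cov_config: CovariateConfig | None = None,
    classes: tuple[str, ...] = CORE_FOREST,
) -> pd.DataFrame:
    """Pearson correlations between movement metrics and forest density for
    steps ending inside a protected area.

    Returns a tidy frame (metric, class, r, df, p) with df = n − 2.
    """
    schema = schema or stack.schema
    cov = cov_config or CovariateConfig()
    end = steps[["end_x", "end_y"]].to_numpy()
    inside = stack.in_pa(end[:, 0], end[:, 1])
    sub = steps[inside]
    if len(sub) < 3:
        raise InsufficientDataError(
            f"only {len(sub)} steps end inside a protected area (need >= 3)"
        )
    pts = sub[["end_x", "end_y"]].to_numpy()
    rows = []
    for cls in classes:
        dens = density_in_buffer(stack, cls, pts, cov)
        for metric, series in (
            ("step_length", sub["length_m"].to_numpy()),
            ("cos_turn_angle", sub["cos_turn"].to_numpy()),
        ):
            mask = np.isfinite(series)
            x, y = series[mask], dens[mask]
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append(
                {"metric": metric, "class": cls, "r": r, "df": len(x) - 2, "p": p}
            )
    return pd.DataFrame(rows)
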