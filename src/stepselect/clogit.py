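"""Matched-stratum conditional logistic regression, from scratch.

The partial likelihood conditions on one chosen step per stratum of
candidates:

    ℓ(β) = Σ_s [ βᵀx_case(s) − log Σ_{j∈s} exp(βᵀx_j) ]

which is the likelihood of a softmax choice among the stratum's rows — the
exact dual of the simulator's candidate-selection rule. ℓ is concave;
Newton–Raphson with step-halving converges in a handful of iterations.

Structurally inestimable columns (constant within every stratum — e.g. a
lagged covariate entered as a main effect) contribute nothing to the
conditional likelihood and are dropped with a warning, as are columns that
are exactly collinear within strata. Inference is Wald (β̂/SE from the
inverse observed information), model quality is AIC (2k − 2ℓ̂) and the
within-stratum concordance: the fraction of (case, control) pairs the
linear predictor ranks correctly, ties counted half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DesignError, SeparationError

__all__ = ["DesignMatrix", "FitResult", "partial_loglik", "fit_clogit", "concordance"]

MAX_ITER = 100
TOL_LOGLIK = 1e-8
TOL_SCORE = 1e-6
SEPARATION_BETA = 15.0
SEPARATION_COND = 1e12


@dataclass
class DesignMatrix:
    """Stacked case-control design: rows grouped into strata.

    X : (n, p) float matrix, finite.
    y : (n,) 0/1, exactly one 1 per stratum.
    strata : (n,) labels; rows of a stratum need not be contiguous.
    """

    X: np.ndarray
    y: np.ndarray
    strata: np.ndarray
    terms: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.terms):
            raise DesignError("X must be (n, p) with p == len(terms)")
        if not np.all(np.isfinite(self.X)):
            raise DesignError("design matrix contains non-finite values")
        # sort rows by stratum once; all computations use contiguous groups
        order = np.argsort(np.asarray(self.strata), kind="stable")
        self.X = self.X[order]
        self.y = self.y[order]
        self.strata = np.asarray(self.strata)[order]
        uniq, starts = np.unique(self.strata, return_index=True)
        self._starts = np.sort(starts)
        counts = np.diff(np.append(self._starts, len(self.y)))
        if counts.min() < 2:
            raise DesignError("every stratum needs >= 1 control row")
        case_per = np.add.reduceat(self.y.astype(int), self._starts)
        if not np.all(case_per == 1):
            s = uniq[np.argmax(case_per != 1)]
            raise DesignError(f"stratum {s!r} has {case_per[case_per != 1][0]} cases")
        self._counts = counts
        self._case_idx = np.nonzero(self.y == 1)[0]
        self._row_stratum = np.repeat(np.arange(len(self._starts)), counts)

    @property
    def n_strata(self) -> int:
        return len(self._starts)

    @classmethod
    def from_table(cls, table: pd.DataFrame, columns: dict[str, pd.Series] | list[str]):
        """Build from a case-control table; ``columns`` maps term name -> series
        (allowing interaction products) or lists plain column names."""
        if isinstance(columns, list):
            columns = {c: table[c] for c in columns}
        X = np.column_stack([np.asarray(v, dtype=float) for v in columns.values()])
        return cls(
            X=X,
            y=table["case"].to_numpy(),
            strata=table["stratum_id"].to_numpy(),
            terms=list(columns),
        )


@dataclass
class FitResult:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    aic: float
    concordance: float
    dropped_terms: list[str] = dc_field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "z": [float(v) for v in self.z],
            "p": [float(v) for v in self.p],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "concordance": float(self.concordance),
            "dropped_terms": self.dropped_terms,
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        for k in ("beta", "se", "z", "p"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _logsumexp_groups(eta: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-stratum log-sum-exp and per-row softmax weights."""
    starts = design._starts
    m = np.maximum.reduceat(eta, starts)
    shifted = np.exp(eta - m[design._row_stratum])
    denom = np.add.reduceat(shifted, starts)
    lse = m + np.log(denom)
    w = shifted / denom[design._row_stratum]
    return lse, w


def partial_loglik(beta: np.ndarray, design: DesignMatrix) -> float:
    """Conditional (partial) log-likelihood at beta; always <= 0."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise DesignError(
            f"beta has length {beta.size}, design has {design.X.shape[1]} terms"
        )
    eta = design.X @ beta
    lse, _ = _logsumexp_groups(eta, design)
    return float(eta[design._case_idx].sum() - lse.sum())


def _score_info(beta, design):
    eta = design.X @ beta
    lse, w = _logsumexp_groups(eta, design)
    ll = float(eta[design._case_idx].sum() - lse.sum())
    xbar = np.zeros((design.n_strata, design.X.shape[1]))
    wX = w[:, None] * design.X
    np.add.reduceat(wX, design._starts, axis=0, out=xbar)
    score = design.X[design._case_idx].sum(axis=0) - xbar.sum(axis=0)
    info = design.X.T @ wX - xbar.T @ xbar  # observed information (PSD)
    return ll, score, info


def _screen_columns(design: DesignMatrix) -> tuple[np.ndarray, list[str]]:
    """Indices of estimable columns; drops within-stratum-constant and
    within-stratum collinear columns."""
    X, starts, counts = design.X, design._starts, design._counts
    means = np.add.reduceat(X, starts, axis=0) / counts[:, None]
    centered = X - means[design._row_stratum]
    scale = np.abs(X).max(axis=0) + 1.0
    keep: list[int] = []
    dropped: list[str] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = centered[:, j]
        if np.abs(col).max() <= 1e-12 * scale[j]:
            dropped.append(design.terms[j])  # constant within every stratum
            continue
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        if np.linalg.norm(resid) <= 1e-10 * np.linalg.norm(col):
            dropped.append(design.terms[j])  # exactly collinear within strata
            continue
        basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
        keep.append(j)
    return np.array(keep, dtype=int), dropped


def fit_clogit(design: DesignMatrix, start: np.ndarray | None = None) -> FitResult:
    """Newton–Raphson fit of the conditional logistic regression."""
    keep, dropped = _screen_columns(design)
    if dropped:
        warnings.warn(
            "dropped inestimable term(s): " + ", ".join(dropped), stacklevel=2
        )
    if len(keep) == 0:
        raise DesignError("no estimable terms (all constant within strata)")
    sub = DesignMatrix(
        X=design.X[:, keep],
        y=design.y,
        strata=design.strata,
        terms=[design.terms[j] for j in keep],
    )
    p = len(keep)
    # per-term scale for the separation check (sd of within-stratum-centred col)
    means = np.add.reduceat(sub.X, sub._starts, axis=0) / sub._counts[:, None]
    col_sd = (sub.X - means[sub._row_stratum]).std(axis=0)

    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    ll, score, info = _score_info(beta, sub)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.linalg.cond(info) > SEPARATION_COND:
            j = int(np.argmax(np.abs(beta) * col_sd))
            raise SeparationError(sub.terms[j], "information matrix is singular "
                                  f"(suspect term {sub.terms[j]!r})")
        try:
            delta = linalg.solve(info, score, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise SeparationError(sub.terms[int(np.argmax(np.abs(score)))],
                                  f"Newton step failed: {exc}") from exc
        step = 1.0
        for _ in range(30):  # step-halving keeps ℓ non-decreasing
            cand = beta + step * delta
            ll_new = partial_loglik(cand, sub)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        beta = beta + step * delta
        std_beta = np.abs(beta) * col_sd
        if std_beta.max() > SEPARATION_BETA:
            raise SeparationError(sub.terms[int(np.argmax(std_beta))])
        ll_prev = ll
        ll, score, info = _score_info(beta, sub)
        if abs(ll - ll_prev) < TOL_LOGLIK and np.abs(score).max() < TOL_SCORE:
            converged = True
            break

    # complete separation: the likelihood is still rising along β̂ even though
    # the iteration has numerically flattened out
    std_beta = np.abs(beta) * col_sd
    if std_beta.max() > 2.0 and partial_loglik(1.5 * beta, sub) >= ll - 1e-10:
        raise SeparationError(sub.terms[int(np.argmax(std_beta))])
    cov = linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    aic = 2 * p - 2 * ll
    fit = FitResult(
        terms=sub.terms,
        beta=beta,
        se=se,
        z=z,
        p=pvals,
        loglik=ll,
        aic=aic,
        concordance=0.0,
        dropped_terms=dropped,
        converged=converged,
        iterations=it,
    )
    fit.concordance = concordance(fit, sub)
    return fit


def concordance(fit: FitResult, design: DesignMatrix) -> float:
    """Within-stratum c-index: P(η_case > η_control), ties 0.5."""
    cols = [design.terms.index(t) for t in fit.terms]
    eta = design.X[:, cols] @ fit.beta
    eta_case = eta[design._case_idx][design._row_stratum]
    is_control = design.y == 0
    diff = eta_case[is_control] - eta[is_control]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / is_control.sum())
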