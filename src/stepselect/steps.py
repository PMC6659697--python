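"""From GPS fixes to the matched used/available case-control design.

A *step* is the straight-line segment between two consecutive fixes at the
nominal interval; its turn angle is the wrapped difference of consecutive
headings. Gaps longer than 1.5× the nominal interval split a track into
bursts, and the first step of each burst (no previous heading) never enters
a stratum. Each usable used step is matched with k available steps sharing
its start point: lengths drawn from the individual's fitted log-normal,
turns drawn uniformly on (−π, π] around the previous used heading. One used
plus k available rows form one stratum of the conditional-logit design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateConfig, density_in_buffer, distance_to
from .errors import ConfigurationError, DesignError, InsufficientDataError
from .landscape import LandscapeStack
from .schema import FeatureSchema
from .simulate import Track, wrap_angle

__all__ = [
    "StepDistribution",
    "derive_steps",
    "fit_step_distribution",
    "generate_available",
    "attach_covariates",
    "validate_case_control",
]

STEP_COLUMNS = [
    "individual_id",
    "burst_id",
    "t_start",
    "start_x",
    "start_y",
    "end_x",
    "end_y",
    "length_m",
    "heading_rad",
    "turn_rad",
    "cos_turn",
    "ln_length",
    "prev_heading_rad",
]


@dataclass(frozen=True)
class StepDistribution:
    """Per-individual log-normal step-length MLE (sample-sd convention)."""

    meanlog: float
    sdlog: float


def derive_steps(track: Track, nominal_interval_s: float = 300.0) -> pd.DataFrame:
    """Derive the step series (lengths, headings, turns) from one track.

    Zero-length steps are dropped with a warning (their log-length is
    undefined); turns are then taken relative to the last defined heading
    within the burst.
    """
    if len(track) < 3:
        raise InsufficientDataError(
            f"{track.individual_id}: need >= 3 fixes, got {len(track)}"
        )
    t, x, y = track.t, track.x, track.y
    dt = np.diff(t)
    burst = np.concatenate([[0], np.cumsum(dt > 1.5 * nominal_interval_s)])

    rows = []
    prev_heading = {}
    n_zero = 0
    for i in range(len(t) - 1):
        if burst[i] != burst[i + 1]:
            continue  # gap: no step across a burst boundary
        dx, dy = x[i + 1] - x[i], y[i + 1] - y[i]
        length = float(np.hypot(dx, dy))
        if length == 0.0:
            n_zero += 1
            continue
        heading = float(np.arctan2(dy, dx))
        b = int(burst[i])
        ph = prev_heading.get(b)
        turn = float(wrap_angle(heading - ph)) if ph is not None else np.nan
        rows.append(
            {
                "individual_id": track.individual_id,
                "burst_id": b,
                "t_start": float(t[i]),
                "start_x": float(x[i]),
                "start_y": float(y[i]),
                "end_x": float(x[i + 1]),
                "end_y": float(y[i + 1]),
                "length_m": length,
                "heading_rad": heading,
                "turn_rad": turn,
                "cos_turn": float(np.cos(turn)) if np.isfinite(turn) else np.nan,
                "ln_length": float(np.log(length)),
                "prev_heading_rad": ph if ph is not None else np.nan,
            }
        )
        prev_heading[b] = heading
    if n_zero:
        warnings.warn(
            f"{track.individual_id}: dropped {n_zero} zero-length step(s)",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=STEP_COLUMNS)


def fit_step_distribution(steps: pd.DataFrame) -> StepDistribution:
    """Log-normal MLE on used step lengths (sdlog with the n−1 denominator)."""
    lengths = steps["length_m"].to_numpy()
    lengths = lengths[np.isfinite(lengths) & (lengths > 0)]
    if len(lengths) < 10:
        raise InsufficientDataError(f"need >= 10 positive steps, got {len(lengths)}")
    logs = np.log(lengths)
    sdlog = float(np.std(logs, ddof=1))
    if sdlog <= 0:
        raise InsufficientDataError("degenerate step lengths: sdlog must be > 0")
    return StepDistribution(meanlog=float(np.mean(logs)), sdlog=sdlog)


def generate_available(
    steps: pd.DataFrame,
    dist: StepDistribution,
    k: int,
    seed: int,
    stack: LandscapeStack,
) -> pd.DataFrame:
    """Assemble strata of 1 used + k available steps (geometry only).

    Only steps with a defined previous heading (not first-of-burst) and
    positive length form strata. Available endpoints falling outside the
    raster extent are redrawn up to 100 times, then clamped to the boundary.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    usable = steps[np.isfinite(steps["turn_rad"])].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    x0, y0 = stack.origin
    w, h = stack.extent_m

    n = len(usable)
    records = []
    n_clamped = 0
    for s in range(n):
        row = usable.iloc[s]
        sid = f"{row.individual_id}_s{s:06d}"
        records.append(
            {
                "stratum_id": sid,
                "case": 1,
                "individual_id": row.individual_id,
                "start_x": row.start_x,
                "start_y": row.start_y,
                "end_x": row.end_x,
                "end_y": row.end_y,
                "length_m": row.length_m,
                "turn_rad": row.turn_rad,
                "cos_turn_angle": row.cos_turn,
                "ln_step_length": row.ln_length,
            }
        )
        L = rng.lognormal(dist.meanlog, dist.sdlog, k)
        turns = rng.uniform(-np.pi, np.pi, k)
        headings = row.prev_heading_rad + turns
        ex = row.start_x + L * np.cos(headings)
        ey = row.start_y + L * np.sin(headings)
        for _ in range(100):
            bad = ~stack.contains(ex, ey)
            if not bad.any():
                break
            nb = int(bad.sum())
            L[bad] = rng.lognormal(dist.meanlog, dist.sdlog, nb)
            turns[bad] = rng.uniform(-np.pi, np.pi, nb)
            headings = row.prev_heading_rad + turns
            ex[bad] = row.start_x + L[bad] * np.cos(headings[bad])
            ey[bad] = row.start_y + L[bad] * np.sin(headings[bad])
        bad = ~stack.contains(ex, ey)
        if bad.any():
            n_clamped += int(bad.sum())
            ex[bad] = np.clip(ex[bad], x0 + 1e-6, x0 + w - 1e-6)
            ey[bad] = np.clip(ey[bad], y0 + 1e-6, y0 + h - 1e-6)
            L[bad] = np.hypot(ex[bad] - row.start_x, ey[bad] - row.start_y)
        for j in range(k):
            records.append(
                {
                    "stratum_id": sid,
                    "case": 0,
                    "individual_id": row.individual_id,
                    "start_x": row.start_x,
                    "start_y": row.start_y,
                    "end_x": ex[j],
                    "end_y": ey[j],
                    "length_m": float(L[j]),
                    "turn_rad": float(wrap_angle(turns[j])),
                    "cos_turn_angle": float(np.cos(turns[j])),
                    "ln_step_length": float(np.log(L[j])),
                }
            )
    if n_clamped:
        warnings.warn(
            f"{n_clamped} available endpoint(s) clamped to the extent boundary",
            stacklevel=2,
        )
    return pd.DataFrame.from_records(records)


def attach_covariates(
    table: pd.DataFrame,
    stack: LandscapeStack,
    schema: FeatureSchema | None = None,
    cov_config: CovariateConfig | None = None,
) -> pd.DataFrame:
    """Attach dist/dens for every class at each candidate end point, plus the
    lagged covariates at the stratum's shared start point (the previous used
    step's end)."""
    schema = schema or stack.schema
    cov = cov_config or CovariateConfig()
    out = table.copy()
    end_pts = out[["end_x", "end_y"]].to_numpy()
    # one lag evaluation per stratum, broadcast to its rows
    strata = out.groupby("stratum_id", sort=False)
    lag_pts = strata[["start_x", "start_y"]].first()
    lag_arr = lag_pts.to_numpy()
    stratum_pos = strata.ngroup().to_numpy()  # row -> stratum ordinal
    for name in schema.names:
        out[f"dist_{name}"] = distance_to(stack, name, end_pts, cov)
        out[f"dens_{name}"] = density_in_buffer(stack, name, end_pts, cov)
        lag_d = distance_to(stack, name, lag_arr, cov)
        lag_n = density_in_buffer(stack, name, lag_arr, cov)
        out[f"lag_dist_{name}"] = lag_d[stratum_pos]
        out[f"lag_dens_{name}"] = lag_n[stratum_pos]
    return out


def validate_case_control(table: pd.DataFrame, k: int | None = None) -> None:
    """Check stratum integrity: one case per stratum, uniform size, constant lag."""
    sizes = table.groupby("stratum_id").size()
    cases = table.groupby("stratum_id")["case"].sum()
    if not (cases == 1).all():
        bad = cases.index[cases != 1][0]
        raise DesignError(f"stratum {bad!r} has {int(cases[bad])} case rows (expected 1)")
    if sizes.nunique() != 1:
        raise DesignError("strata are not all the same size")
    if k is not None and sizes.iloc[0] != k + 1:
        raise DesignError(f"strata have {int(sizes.iloc[0])} rows, expected {k + 1}")
    lag_cols = [c for c in table.columns if c.startswith("lag_")]
    if lag_cols:
        spread = table.groupby("stratum_id")[lag_cols].agg(lambda s: s.max() - s.min())
        if (spread.to_numpy() != 0).any():
            raise DesignError("lagged covariates vary within a stratum")
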