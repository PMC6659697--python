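"""End-to-end orchestration: landscape → tracks → steps → strata → covariates
→ scaling → candidate set → AIC competition, with every artifact on disk.

A single global seed deterministically derives the per-stage sub-seeds, so a
rerun with the same configuration is bit-identical for all CSV/JSON
artifacts. Real telemetry can replace simulated tracks at the build-steps
boundary (point ``run_pipeline`` at an existing telemetry CSV).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariates import CovariateConfig, scale_covariates
from .errors import StepSelectError
from .io import read_telemetry, write_case_control, write_telemetry
from .landscape import LandscapeConfig, generate_landscape
from .models import CompetitionResult, build_candidate_set, compete
from .schema import default_schema
from .simulate import MovementParams, SelectionParams, simulate_track
from .steps import (
    attach_covariates,
    derive_steps,
    fit_step_distribution,
    generate_available,
    validate_case_control,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "derive_subseed"]


def derive_subseed(seed: int, stage: str, index: int = 0) -> int:
    """Pure, documented seed derivation: SHA-256 of (seed, stage, index) mod 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    movement: MovementParams = field(default_factory=MovementParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    k: int = 10
    n_individuals: int = 2
    n_fixes: int = 500
    seed: int = 0
    collinearity_threshold: float = 0.7

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        if "landscape" in doc:
            kwargs["landscape"] = LandscapeConfig.from_dict(doc["landscape"])
        if "movement" in doc:
            kwargs["movement"] = MovementParams(**doc["movement"])
        if "selection" in doc:
            kwargs["selection"] = SelectionParams(**doc["selection"])
        if "covariates" in doc:
            kwargs["covariates"] = CovariateConfig(**doc["covariates"])
        for key in ("k", "n_individuals", "n_fixes", "seed", "collinearity_threshold"):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"]["extent_m"] = list(d["landscape"]["extent_m"])
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StepSelectError as exc:
                raise StepSelectError(f"[stage {name}] {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    config: RunConfig,
    output_dir: str | Path,
    telemetry_path: str | Path | None = None,
) -> CompetitionResult:
    """Run the full analysis; returns the competition result and writes all
    artifacts (rasters, telemetry, case-control table, fit JSONs, competition
    and tally CSVs, manifest) under ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = default_schema()

    logger.info("stage landscape: generating synthetic landscape")
    ls_cfg = dataclasses.replace(
        config.landscape, seed=derive_subseed(config.seed, "landscape")
    )
    stack = generate_landscape(ls_cfg, schema)
    stack.save(out / "landscape")

    if telemetry_path is None:
        logger.info("stage simulate: %d individual(s)", config.n_individuals)
        tracks = [
            simulate_track(
                stack,
                config.movement,
                config.selection,
                n_fixes=config.n_fixes,
                seed=derive_subseed(config.seed, "track", i),
                individual_id=f"sim{i:02d}",
                cov_config=config.covariates,
            )
            for i in range(config.n_individuals)
        ]
        write_telemetry(tracks, out / "telemetry.csv")
    else:
        logger.info("stage ingest: reading telemetry from %s", telemetry_path)
        tracks = read_telemetry(telemetry_path)

    logger.info("stage steps: deriving step series and strata")
    tables = {}
    all_steps = []
    for i, track in enumerate(tracks):
        steps = derive_steps(track, config.movement.fix_interval_s)
        all_steps.append(steps)
        dist = fit_step_distribution(steps)
        geom = generate_available(
            steps, dist, config.k, derive_subseed(config.seed, "available", i), stack
        )
        table = attach_covariates(geom, stack, schema, config.covariates)
        validate_case_control(table, config.k)
        tables[track.individual_id] = scale_covariates(table)
    pd.concat(all_steps, ignore_index=True).to_csv(out / "steps.csv", index=False)
    combined = pd.concat(tables.values(), ignore_index=True)
    write_case_control(combined, out / "case_control.csv")

    logger.info("stage compete: fitting 5 models per individual")
    any_table = next(iter(tables.values()))
    specs = build_candidate_set(schema, any_table, config.collinearity_threshold)
    result = compete(tables, specs)
    result.to_csv(out / "competition.csv")
    result.tallies.to_csv(out / "tallies.csv", index=False)
    fits_dir = out / "fits"
    fits_dir.mkdir(exist_ok=True)
    for (ind, model), fit in result.fits.items():
        fit.to_json(fits_dir / f"{ind}_{model}.json")

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stepselect_version": __version__,
        "n_individuals": len(tables),
        "n_strata": int(combined["stratum_id"].nunique()),
        "n_rows": int(len(combined)),
        "failures": result.failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
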