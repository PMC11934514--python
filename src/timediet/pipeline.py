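"""End-to-end orchestration: simulate/score/preprocess/fit/enumerate.

A :class:`RunConfig` (YAML-loadable) fixes every analysis setting —
zero-replacement cap, Box-Cox bounds, reallocation grid, equivalence
targets and tolerance, covariate-fixing policy — and
:func:`run_pipeline` executes the stages, writing a model artifact, the
banded option table, per-band summaries and a run log that records the
settings in effect and the sample size after each filtering step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import equivalence as eq
from . import io as tio
from . import synthetic
from .compositional import TIME_USE_PARTS, reference_profile, replace_zeros
from .model import fit_model, composition_block_test, standardized_betas
from .scoring import DIET_SCORE_COLUMNS, score_cohort


@dataclass
class RunConfig:
    """Settings of one pipeline run; unknown keys are rejected on load."""

    # io
    input_csv: str | None = None  # when None, a cohort is simulated
    output_dir: str = "timediet_run"
    # simulation
    simulate_n: int = 2000
    seed: int = 0
    # compositional preprocessing
    zero_cap: float = 10.0
    # model
    boxcox_lambda: float | None = None  # None -> profile-likelihood estimate
    boxcox_shift: float | None = None  # None -> 1 iff min(score) == 0
    # equivalence engine
    step: float = 10.0
    radius: float = 30.0
    targets: tuple[float, ...] = eq.DEFAULT_TARGETS
    tolerance: float = eq.DEFAULT_TOLERANCE
    include_negative: bool = True
    summary_bands: tuple[float, ...] = eq.DEFAULT_TARGETS
    # bands whose rows are written to options.csv; None -> the extreme
    # (+/- max target) bands, the "least flexible" equivalence sets
    write_bands: tuple[float, ...] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("targets", "summary_bands", "write_bands"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets"] = list(self.targets)
        d["summary_bands"] = list(self.summary_bands)
        if self.write_bands is not None:
            d["write_bands"] = list(self.write_bands)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns artifact paths and key results.

    Stages: (optional) cohort simulation -> item scoring -> complete-case
    filtering -> zero replacement -> reference profile -> Box-Cox OLS fit
    -> option enumeration -> per-band summaries. Failures are re-raised
    with the stage name, and files written by the failed run are removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # ---- input -------------------------------------------------------
        if config.input_csv is None:
            stage = "simulate"
            gen = synthetic.GeneratorConfig(n=config.simulate_n, zero_cap=config.zero_cap)
            cohort, _ = synthetic.generate_cohort(gen, seed=config.seed)
            cohort_path = outdir / "cohort.csv"
            tio.write_cohort(cohort, cohort_path)
            written.append(cohort_path)
        else:
            stage = "read"
            cohort = tio.read_cohort(config.input_csv)
        tio.validate_cohort(cohort)

        # ---- scoring and filtering ---------------------------------------
        stage = "score"
        scored = score_cohort(cohort)
        analytic, attrition = tio.complete_case_filter(scored)
        if len(analytic) < 14:
            raise ValueError(f"analytic sample too small (n={len(analytic)})")

        stage = "preprocess"
        analytic = analytic.copy()
        analytic[list(TIME_USE_PARTS)] = replace_zeros(
            analytic[list(TIME_USE_PARTS)].to_numpy(dtype=float), cap=config.zero_cap
        )
        reference = reference_profile(
            analytic[list(TIME_USE_PARTS)].to_numpy(),
            analytic[DIET_SCORE_COLUMNS].to_numpy(),
            step=config.step,
        )

        stage = "fit"
        model = fit_model(
            analytic, lam=config.boxcox_lambda, shift=config.boxcox_shift
        )
        block = composition_block_test(model)
        stdb = standardized_betas(model)
        model_path = outdir / "model.json"
        model.save(model_path)
        written.append(model_path)

        stage = "enumerate"
        table = eq.enumerate_options(
            model,
            reference,
            step=config.step,
            radius=config.radius,
            targets=config.targets,
            tolerance=config.tolerance,
            include_negative=config.include_negative,
        )
        write_bands = config.write_bands
        if write_bands is None:
            top = max(config.targets)
            write_bands = (-top, top) if config.include_negative else (top,)
        options_path = outdir / "options.csv"
        table.write_csv(options_path, bands=write_bands)
        written.append(options_path)

        stage = "summarize"
        summary_paths = {}
        for band in config.summary_bands:
            s = eq.summarize_options(table, band)
            p = outdir / f"summary_band_{band:+g}.csv"
            s.to_csv(p, index=False, float_format="%.6f")
            written.append(p)
            summary_paths[band] = p

        stage = "log"
        log = {
            "config": config.to_dict(),
            "attrition": attrition,
            "reference_profile": reference.as_dict(),
            "boxcox": {"lambda": model.lam, "shift": model.shift},
            "block_test": dataclasses.asdict(block),
            "standardized_betas": stdb.to_dict(orient="records"),
            "band_counts": {str(k): v for k, v in table.band_counts().items()},
        }
        log_path = outdir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2))
        written.append(log_path)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    return {
        "analytic": analytic,
        "attrition": attrition,
        "reference": reference,
        "model": model,
        "block_test": block,
        "standardized_betas": stdb,
        "table": table,
        "paths": {
            "model": model_path,
            "options": options_path,
            "log": log_path,
            "summaries": summary_paths,
        },
    }
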