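"""Run orchestration: simulate -> threshold -> metrics -> associate.

One master seed deterministically derives an independent sub-seed per stage
(via numpy SeedSequence spawning), so changing, say, the SMW ensemble size
cannot perturb the simulated cohort. Each stage writes its artifacts under
the run directory and can be resumed from a prior run's outputs. Structured
progress goes to a logger (stderr by default) and a run manifest records the
config snapshot, seeds, package versions and wall-clock per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import io as cio
from . import metrics as gm
from . import synth
from . import threshold as thr

logger = logging.getLogger("netrait")

_STAGES = ("simulate", "threshold", "metrics", "associate")


class ConfigError(ValueError):
    """Raised with every config violation collected at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    seed: int = 0
    manifest: str | None = None          # input cohort (else simulate)
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    k: int | None = None                 # fixed K; else scan the grid
    k_min: int | None = None
    k_max: int | None = None
    k_step: int = 1
    n_random_threshold: int = 500
    n_random_smw: int = 500
    swap_factor: float = 10.0
    gcc_method: str = "average_local"
    cv_folds: int = 10
    cooks_multiplier: float = 3.0
    alpha_level: float = 0.01
    penalty_rule: str = "1se"

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {name: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
                for name, c in zip(_STAGES, children)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path_or_dict: str | Path | dict) -> RunConfig:
    """Parse, default and cross-validate a run config; reports every
    violation at once and rejects unknown keys."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
        raw = {k: v for k, v in raw.items() if k in known}
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(errors + [str(exc)]) from exc
    if cfg.manifest is None and cfg.simulate is None:
        errors.append("need either a manifest or a simulate block")
    if cfg.simulate:
        try:
            synth.config_from_dict({**cfg.simulate, "seed": 0})
        except (ValueError, TypeError) as exc:
            errors.append(f"simulate block: {exc}")
    if cfg.k is not None and cfg.k < 1:
        errors.append("k must be >= 1")
    if cfg.k is None and (cfg.k_min is not None) != (cfg.k_max is not None):
        errors.append("k_min and k_max must be given together")
    for name in ("n_random_threshold", "n_random_smw", "cv_folds"):
        if getattr(cfg, name) < 1:
            errors.append(f"{name} must be >= 1")
    if cfg.cv_folds < 3:
        errors.append("cv_folds must be >= 3")
    if cfg.cooks_multiplier <= 0:
        errors.append("cooks_multiplier must be > 0")
    if not (0 < cfg.alpha_level < 1):
        errors.append("alpha_level must be in (0, 1)")
    if cfg.gcc_method not in gm.GCC_METHODS:
        errors.append(f"gcc_method must be one of {gm.GCC_METHODS}")
    if cfg.penalty_rule not in ("min", "1se"):
        errors.append("penalty_rule must be 'min' or '1se'")
    if cfg.swap_factor <= 0:
        errors.append("swap_factor must be > 0")
    if errors:
        raise ConfigError(errors)
    return cfg


def _k_grid(cfg: RunConfig, cohort: cio.Cohort) -> list[int]:
    if cfg.k_min is not None and cfg.k_max is not None:
        return list(range(cfg.k_min, cfg.k_max + 1, cfg.k_step))
    grid = thr.default_k_grid(len(cohort.regions), step=cfg.k_step)
    # auto grid: stay within every subject's positive-edge budget
    max_k = min(w.positive_pairs() for w in cohort.connectomes)
    clipped = [k for k in grid if k <= max_k]
    if len(clipped) < len(grid):
        logger.info("clipping auto K grid at %d (sparsest subject)", max_k)
    if not clipped:
        raise ValueError("no feasible K in the default grid; give k_min/k_max")
    return clipped


def run_all(config: RunConfig, out_dir: str | Path,
            resume: bool = False) -> Path:
    """Execute every stage in order, writing artifacts under ``out_dir``.

    With ``resume=True``, a stage whose outputs already exist in ``out_dir``
    is loaded instead of recomputed. A failing stage aborts with its name;
    earlier outputs stay on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config": config.to_dict(), "stage_seeds": seeds,
                      "versions": _versions(), "wallclock_s": {}}
    stage = "simulate"
    try:
        # ---- simulate / load -------------------------------------------
        t0 = time.perf_counter()
        cohort_dir = out_dir / "cohort"
        if config.manifest is not None:
            logger.info("loading cohort from %s", config.manifest)
            cohort = cio.read_cohort(config.manifest)
        elif resume and (cohort_dir / "manifest.csv").exists():
            logger.info("resuming: cohort found in %s", cohort_dir)
            cohort = cio.read_cohort(cohort_dir / "manifest.csv")
        else:
            gen_cfg = synth.config_from_dict(
                {**config.simulate, "seed": seeds["simulate"]})
            logger.info("simulating cohort: %d subjects, %d nodes",
                        gen_cfg.n_subjects, gen_cfg.n_nodes)
            cohort, truth = synth.generate_cohort(gen_cfg)
            cio.write_cohort(cohort, cohort_dir)
            truth.save(cohort_dir / "ground_truth.json")
        manifest["wallclock_s"]["simulate"] = time.perf_counter() - t0

        # ---- threshold --------------------------------------------------
        stage = "threshold"
        t0 = time.perf_counter()
        scan = None
        scan_path = out_dir / "entropy_scan.csv"
        if config.k is not None:
            optimal_k = config.k
            logger.info("using fixed K = %d", optimal_k)
        elif resume and scan_path.exists():
            df = pd.read_csv(scan_path)
            scan = thr.EntropyScan(k_grid=df["k"].tolist(),
                                   h_actual=df["h_actual"].tolist(),
                                   h_null=df["h_null"].tolist(),
                                   n_random=config.n_random_threshold)
            optimal_k = scan.optimal_k
            logger.info("resuming: entropy scan loaded, K = %d", optimal_k)
        else:
            grid = _k_grid(config, cohort)
            logger.info("entropy scan over %d K values, %d null networks",
                        len(grid), config.n_random_threshold)
            scan = thr.scan_optimal_k(cohort.connectomes, grid,
                                      n_random=config.n_random_threshold,
                                      rng=seeds["threshold"],
                                      swap_factor=config.swap_factor)
            optimal_k = scan.optimal_k
            logger.info("optimal K = %d", optimal_k)
        nets = [thr.binarize_top_k(w, optimal_k) for w in cohort.connectomes]
        manifest["optimal_k"] = optimal_k
        manifest["wallclock_s"]["threshold"] = time.perf_counter() - t0

        # ---- metrics ----------------------------------------------------
        stage = "metrics"
        t0 = time.perf_counter()
        metrics_path = out_dir / "metrics.csv"
        if resume and metrics_path.exists():
            logger.info("resuming: metrics table loaded")
            metrics = gm.metrics_from_long_table(
                pd.read_csv(metrics_path, float_precision="round_trip"))
        else:
            logger.info("computing metrics (%d rewirings per subject)",
                        config.n_random_smw)
            metrics = gm.compute_cohort_metrics(
                nets, subject_ids=cohort.subject_ids,
                n_random=config.n_random_smw, rng=seeds["metrics"],
                gcc_method=config.gcc_method)
        metrics_table = gm.metrics_long_table(metrics, cohort.regions.names)
        manifest["wallclock_s"]["metrics"] = time.perf_counter() - t0

        # ---- associate --------------------------------------------------
        stage = "associate"
        t0 = time.perf_counter()
        acfg = assoc.AssociationConfig(
            cv_folds=config.cv_folds,
            cooks_multiplier=config.cooks_multiplier,
            alpha_level=config.alpha_level,
            penalty_rule=config.penalty_rule,
            seed=seeds["associate"])
        model = assoc.run_association(metrics, cohort, acfg)
        logger.info("association: %d terms, %d subjects removed",
                    len(model.predictors), len(model.removed_subjects))
        manifest["wallclock_s"]["associate"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    cio.write_results(model, scan, metrics_table, out_dir)
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out_dir


def _versions() -> dict[str, str]:
    import networkx
    import sklearn
    import statsmodels
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__}
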