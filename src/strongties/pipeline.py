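"""End-to-end orchestration: generate -> indices -> estimation -> SIRS.

A run is driven by a :class:`RunConfig` (usually parsed from a YAML file),
executes the requested stages with deterministic per-stage seed substreams,
writes every artifact as delimited text plus aligned plain-text regression
tables, and records a manifest with SHA-256 checksums so reruns under the
same config are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, sirs as sirs_mod
from .indices import build_index_bundle
from .synthetic_data import ConfigError, GeneratorConfig, generate_population, write_table

__all__ = [
    "RunConfig",
    "StageError",
    "ConfigValidationError",
    "validate_config",
    "run",
    "ALL_STAGES",
]

log = logging.getLogger("strongties")

ALL_STAGES = ("generate", "indices", "fit", "sirs")
ALL_BATTERIES = ("baseline", "robustness", "heterogeneity", "mechanism")

_STAGE_KEYS = {name: k for k, name in enumerate(ALL_STAGES)}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigValidationError(ValueError):
    """Invalid run configuration; carries every violation, not just the first."""

    def __init__(self, violations: list[str]):
        super().__init__(
            "invalid run configuration:\n" + "\n".join(f"- {v}" for v in violations)
        )
        self.violations = violations


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs."""

    out_dir: Path = Path("results/run")
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    batteries: tuple[str, ...] = ALL_BATTERIES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sirs_params: sirs_mod.SIRSParams = field(
        default_factory=lambda: sirs_mod.SIRSParams(alpha=1.0, beta=0.2, lam=0.3, delta=0.1, N=1.0)
    )
    sirs_alpha_grid: tuple[float, ...] = tuple(np.round(np.linspace(0.4, 2.0, 33), 10))
    sirs_init: tuple[float, float, float] = (0.98, 0.02, 0.0)
    sirs_t_end: float = 400.0
    sirs_dt: float = 0.01
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream; independent of stage toggles."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGE_KEYS[stage],))
        return int(ss.generate_state(1)[0] % (2**31))


def validate_config(path) -> RunConfig:
    """Parse and cross-validate a YAML run configuration.

    Collects *every* violation before raising
    :class:`ConfigValidationError`; a missing seed is defaulted to 0 with a
    logged warning.  Unparseable YAML raises a parse error with location.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigValidationError([f"cannot parse {path}{loc}: {exc}"]) from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigValidationError([f"{path}: top level must be a mapping"])

    violations: list[str] = []
    seed = raw.get("seed")
    if seed is None:
        warnings.warn("config has no seed; defaulting to 0", stacklevel=2)
        log.warning("config %s has no seed; defaulting to 0", path)
        seed = 0
    elif not isinstance(seed, int):
        violations.append("seed must be an integer")
        seed = 0

    stages = tuple(raw.get("stages", ALL_STAGES))
    for s in stages:
        if s not in ALL_STAGES:
            violations.append(f"unknown stage {s!r}; valid stages: {list(ALL_STAGES)}")
    if "indices" in stages and "generate" not in stages:
        violations.append("stage 'indices' requires stage 'generate'")
    if "fit" in stages and "indices" not in stages:
        violations.append("stage 'fit' requires stage 'indices'")

    gen_raw = raw.get("generator", {}) or {}
    n = gen_raw.get("n", 20_000)
    if not isinstance(n, int) or n <= 0:
        violations.append("generator.n must be positive")
        n = 1
    missing_rate = gen_raw.get("missing_rate", 0.0)
    try:
        generator = GeneratorConfig(n=n, seed=seed, missing_rate=missing_rate)
    except ConfigError as exc:
        violations.append(str(exc))
        generator = GeneratorConfig(n=1, seed=seed)

    bats = tuple((raw.get("models", {}) or {}).get("batteries", ALL_BATTERIES))
    for b in bats:
        if b not in ALL_BATTERIES:
            violations.append(f"unknown battery {b!r}; valid: {list(ALL_BATTERIES)}")

    sirs_raw = raw.get("sirs", {}) or {}
    p = {k: sirs_raw.get(k, d) for k, d in
         (("alpha", 1.0), ("beta", 0.2), ("lam", 0.3), ("delta", 0.1), ("N", 1.0))}
    for name in ("alpha", "beta", "lam", "delta"):
        if not isinstance(p[name], (int, float)) or p[name] <= 0:
            violations.append(
                f"sirs.{name} must be > 0 (all contact/transition rates are assumed "
                "strictly positive)"
            )
            p[name] = 1.0
    if not isinstance(p["N"], (int, float)) or p["N"] <= 0:
        violations.append("sirs.N must be > 0")
        p["N"] = 1.0
    sirs_params = sirs_mod.SIRSParams(**{k: float(v) for k, v in p.items()})

    grid_raw = sirs_raw.get("alpha_grid")
    if grid_raw is None:
        grid = tuple(np.round(np.linspace(0.4, 2.0, 33), 10))
    elif isinstance(grid_raw, dict):
        grid = tuple(
            np.linspace(grid_raw.get("start", 0.4), grid_raw.get("stop", 2.0),
                        int(grid_raw.get("num", 33)))
        )
    else:
        grid = tuple(float(g) for g in grid_raw)
    if any(g <= 0 for g in grid):
        violations.append(
            "sirs.alpha_grid values must be > 0 (the tie-strength rate alpha is "
            "assumed strictly positive)"
        )
    elif any(np.diff(grid) <= 0):
        violations.append("sirs.alpha_grid must be strictly increasing")

    init_raw = sirs_raw.get("init", {"S": 0.98, "I": 0.02, "R": 0.0})
    init = (float(init_raw.get("S", 0.0)), float(init_raw.get("I", 0.0)),
            float(init_raw.get("R", 0.0)))
    if min(init) < 0:
        violations.append("sirs.init components must be nonnegative")
    elif abs(sum(init) - p["N"]) > 1e-9 * max(1.0, p["N"]):
        violations.append(f"sirs.init must sum to N = {p['N']}")

    if violations:
        raise ConfigValidationError(violations)

    return RunConfig(
        out_dir=Path(raw.get("out_dir", "results/run")),
        seed=seed,
        stages=stages,
        batteries=bats,
        generator=generator,
        sirs_params=sirs_params,
        sirs_alpha_grid=grid,
        sirs_init=init,
        sirs_t_end=float(sirs_raw.get("t_end", 400.0)),
        sirs_dt=float(sirs_raw.get("dt", 0.01)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: RunConfig) -> dict:
    return {
        "out_dir": str(config.out_dir),
        "seed": config.seed,
        "stages": list(config.stages),
        "batteries": list(config.batteries),
        "generator": {"n": config.generator.n, "seed": config.generator.seed,
                      "missing_rate": config.generator.missing_rate
                      if not isinstance(config.generator.missing_rate, dict)
                      else dict(config.generator.missing_rate)},
        "sirs": {
            "alpha": config.sirs_params.alpha, "beta": config.sirs_params.beta,
            "lam": config.sirs_params.lam, "delta": config.sirs_params.delta,
            "N": config.sirs_params.N,
            "alpha_grid": [float(a) for a in config.sirs_alpha_grid],
            "init": list(config.sirs_init),
            "t_end": config.sirs_t_end, "dt": config.sirs_dt,
        },
        "log_level": config.log_level,
    }


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict.

    Artifacts land in ``config.out_dir``; the manifest (also written as
    ``manifest.json``) lists every artifact with its SHA-256 checksum and
    marks a failed run's partial outputs as incomplete.  Rerunning with an
    identical config reproduces identical checksums.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {},
        "incomplete": False,
        "failed_stage": None,
    }

    cfg_path = out / "config_used.yaml"
    cfg_path.write_text(yaml.safe_dump(_config_dict(config), sort_keys=True))
    _register(manifest, "config_used", cfg_path)

    table = None
    indexed = None
    current = "generate"
    try:
        if "generate" in config.stages:
            t0 = time.time()
            log.info("stage generate: n=%d seed=%d", config.generator.n, config.seed)
            gen_cfg = replace(config.generator, seed=config.stage_seed("generate"))
            table = generate_population(gen_cfg)
            path = out / "dataset.csv"
            write_table(table, path)
            _register(manifest, "dataset", path)
            log.info("stage generate done in %.2fs (%d rows)", time.time() - t0, len(table))

        if "indices" in config.stages:
            current = "indices"
            t0 = time.time()
            indexed, diag = build_index_bundle(table)
            path = out / "indices.csv"
            write_table(indexed, path)
            _register(manifest, "indices", path)
            rep = out / "index_diagnostics.txt"
            rep.write_text("\n".join(diag.report_lines()) + "\n")
            _register(manifest, "index_diagnostics", rep)
            log.info(
                "stage indices done in %.2fs (KMO=%.4f, retained %d component(s))",
                time.time() - t0, diag.kmo_overall, diag.n_retained,
            )

        if "fit" in config.stages:
            current = "fit"
            for battery in config.batteries:
                t0 = time.time()
                fits = _run_battery(battery, indexed)
                frame = glm.battery_frame(fits)
                path = out / f"table_{battery}.csv"
                write_table(frame, path)
                _register(manifest, f"table_{battery}", path)
                txt = out / f"table_{battery}.txt"
                txt.write_text(glm.render_battery(fits, title=battery) + "\n")
                _register(manifest, f"table_{battery}_txt", txt)
                for f in fits:
                    log.info("  %s: n_used=%d after listwise deletion", f.label, f.n_used)
                log.info("stage fit[%s] done in %.2fs", battery, time.time() - t0)

        if "sirs" in config.stages:
            current = "sirs"
            t0 = time.time()
            eq = sirs_mod.steady_state(config.sirs_params)
            eq_frame = pd.DataFrame(
                [{
                    "alpha": config.sirs_params.alpha, "beta": config.sirs_params.beta,
                    "lam": config.sirs_params.lam, "delta": config.sirs_params.delta,
                    "N": config.sirs_params.N, "S_star": eq.S_star, "I_star": eq.I_star,
                    "R_star": eq.R_star, "endemic": eq.endemic,
                }]
            )
            path = out / "sirs_equilibrium.csv"
            write_table(eq_frame, path)
            _register(manifest, "sirs_equilibrium", path)

            cs = sirs_mod.comparative_statics(config.sirs_params, config.sirs_alpha_grid)
            path = out / "sirs_comparative_statics.csv"
            write_table(cs, path)
            _register(manifest, "sirs_comparative_statics", path)

            traj = sirs_mod.simulate(
                config.sirs_params, config.sirs_init, config.sirs_t_end,
                dt=config.sirs_dt, record_every=max(1, int(1.0 / config.sirs_dt)),
            )
            path = out / "sirs_trajectory.csv"
            write_table(traj.to_frame(), path)
            _register(manifest, "sirs_trajectory", path)
            log.info("stage sirs done in %.2fs (endemic=%s)", time.time() - t0, eq.endemic)
    except Exception as exc:
        manifest["incomplete"] = True
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageError(current, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_battery(name: str, indexed: pd.DataFrame):
    if name == "baseline":
        return glm.baseline_battery(indexed)
    if name == "robustness":
        return glm.robustness_battery(indexed)
    if name == "heterogeneity":
        return glm.heterogeneity_battery(indexed)
    if name == "mechanism":
        nested = glm.mechanism_battery(indexed)
        return [f for fits in nested.values() for f in fits]
    raise ValueError(f"unknown battery {name!r}")


def _register(manifest: dict, name: str, path: Path) -> None:
    manifest["artifacts"][name] = {
        "path": path.name,
        "sha256": _sha256(path),
        "bytes": path.stat().st_size,
    }
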