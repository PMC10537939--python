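"""YAML run configuration: validation, defaults, round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Optional, Tuple

import yaml

from .calibrate import GEOMETRIES, Scenario


@dataclass
class RunConfig:
    """Validated configuration for a simulation/calibration/enumeration run.

    Only ``Q`` and ``snr_db`` are required; everything else carries the
    package defaults.  Unknown keys are rejected by name, and validation
    reports every violation at once.
    """

    Q: int = None  # required
    snr_db: float = None  # required
    rho: float = 0.0
    translation_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    geometry_id: str = "desk64"
    n_reps: int = 100
    seed: int = 0
    n_samples: int = 100
    fs: float = 1000.0
    mode: str = "fixed"
    k_max: Optional[int] = None
    min_separation: float = 0.0
    noise_model: str = "white"
    n_trials: int = 1
    whiten_temporal: bool = False
    whiten_spatial: bool = False
    # threshold source: at most one of these; defaults to a fixed value of 2
    threshold_value: Optional[float] = None
    threshold_table: Optional[str] = None  # path to a JSON table
    threshold_alpha: Optional[float] = None
    out_dir: str = "results"

    def validate(self) -> None:
        problems = []
        if self.Q is None:
            problems.append("Q: required")
        elif not (isinstance(self.Q, int) and self.Q >= 0):
            problems.append(f"Q: must be a non-negative integer, got {self.Q!r}")
        if self.snr_db is None:
            problems.append("snr_db: required")
        if not (0.0 <= float(self.rho) < 1.0):
            problems.append(f"rho: must be in [0, 1), got {self.rho!r}")
        if self.geometry_id not in GEOMETRIES:
            problems.append(
                f"geometry_id: unknown {self.geometry_id!r}; options {sorted(GEOMETRIES)}"
            )
        if self.n_reps < 1:
            problems.append("n_reps: must be >= 1")
        if self.mode not in ("fixed", "free"):
            problems.append(f"mode: must be 'fixed' or 'free', got {self.mode!r}")
        if self.noise_model not in ("white", "ar6"):
            problems.append(f"noise_model: must be 'white' or 'ar6', got {self.noise_model!r}")
        if self.threshold_alpha is not None and not (0 < self.threshold_alpha < 1):
            problems.append("threshold_alpha: must be in (0, 1)")
        n_sources = sum(
            x is not None
            for x in (self.threshold_value, self.threshold_table, self.threshold_alpha)
        )
        if n_sources > 1:
            problems.append(
                "threshold: set only one of threshold_value / threshold_table / threshold_alpha"
            )
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    def threshold_spec(self):
        """Resolve the configured threshold source (default: fixed value 2)."""
        from .model_order import NominalAlpha, ThresholdTable

        if self.threshold_table is not None:
            return ThresholdTable.load(self.threshold_table)
        if self.threshold_alpha is not None:
            return NominalAlpha(self.threshold_alpha)
        return 2.0 if self.threshold_value is None else float(self.threshold_value)

    def scenario(self) -> Scenario:
        return Scenario(
            Q=self.Q,
            snr_db=self.snr_db,
            rho=self.rho,
            translation_mm=tuple(self.translation_mm),
            geometry_id=self.geometry_id,
            n_reps=self.n_reps,
            seed=self.seed,
            n_samples=self.n_samples,
            fs=self.fs,
            mode=self.mode,
            k_max=self.k_max,
            min_separation=self.min_separation,
        )

    def save(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with an error naming each one; validation
    errors list every violation, not just the first.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration key(s): {', '.join(unknown)}")
    if "translation_mm" in raw and raw["translation_mm"] is not None:
        raw["translation_mm"] = tuple(raw["translation_mm"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
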