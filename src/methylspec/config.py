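"""Run configuration: a flat key-value (YAML) schema shared by the
library pipeline and the CLI.

Validation reports *every* offending key at once, so a config file can
be fixed in one pass.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run.

    Defaults reflect the study conditions: 283.15 K, r bins of 0.05 Å
    on [2, 6] Å, θ bins of 5° on [0°, 180°], a WHAM grid of 0.05 Å on
    [−2.5, 2.5] Å with tolerance 1e-6 kcal/mol, the k(R−c)² bias
    convention (``half_k=False``), and a 3.0 kcal/mol blocking
    threshold for the specificity call.
    """

    temperature: float = 283.15  # K
    seed: int = 0
    outdir: str = "methylspec_out"
    stages: tuple[str, ...] = ("simulate", "geom", "pmf", "triplet", "classify")

    # histogram bins (geometry stage)
    r_min: float = 2.0
    r_max: float = 6.0
    r_bin_width: float = 0.05
    theta_bin_width: float = 5.0

    # WHAM (pmf stage)
    wham_r_min: float = -2.5
    wham_r_max: float = 2.5
    wham_bin_width: float = 0.05
    wham_tolerance: float = 1e-6  # kcal/mol on max|Δf_i|
    wham_max_iterations: int = 100_000
    half_k: bool = False  # True → ½k(R−c)² bias convention

    # specificity
    threshold: float = 3.0  # kcal/mol

    # synthetic-data stage
    n_frames: int = 10_000
    frame_preset: str = "reactive_wt_like"
    n_windows: int = 20
    n_per_window: int = 5_000
    potential_barrier: float = 13.4  # kcal/mol
    potential_R_a: float = -1.4
    potential_R_b: float = 1.2

    # optional external inputs
    frames_path: str | None = None
    frames_format: str = "xyz"
    windows_dir: str | None = None
    windows_metadata: str | None = None  # CSV: center,force_constant per row
    barriers_csv: str | None = None  # CSV: enzyme,step,barrier
    correction_curve: str | None = None  # 2-column (R, dE) file

    _VALID_STAGES = ("simulate", "geom", "pmf", "triplet", "classify")

    def validate(self) -> None:
        problems = []
        for key in ("temperature", "r_bin_width", "theta_bin_width",
                    "wham_bin_width", "wham_tolerance", "threshold"):
            if getattr(self, key) <= 0:
                problems.append(f"{key} must be > 0 (got {getattr(self, key)})")
        if self.r_max <= self.r_min:
            problems.append(f"r_max ({self.r_max}) must exceed r_min ({self.r_min})")
        if self.wham_r_max <= self.wham_r_min:
            problems.append("wham_r_max must exceed wham_r_min")
        if self.wham_max_iterations < 1:
            problems.append("wham_max_iterations must be >= 1")
        for s in self.stages:
            if s not in self._VALID_STAGES:
                problems.append(f"unknown stage {s!r}")
        if problems:
            raise ConfigError(problems)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = [k for k in data if k not in known]
        if unknown:
            raise ConfigError([f"unknown key {k!r}" for k in sorted(unknown)])
        if "stages" in data:
            data = {**data, "stages": tuple(data["stages"])}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(["config file must hold a flat key-value mapping"])
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
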