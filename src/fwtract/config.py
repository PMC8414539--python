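"""Pipeline configuration: YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .stats import DEFAULT_ALPHA, DEFAULT_COVARIATES


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    When ``dwi`` (paths to a 4-D NIfTI plus bval/bvec) or ``cohort_csv`` is
    given, the corresponding simulation stage is skipped and the files are
    consumed instead.  ``templates`` may list NIfTI tract masks; otherwise
    the synthetic phantom's own region masks serve as the atlas.
    """

    seed: int = 0
    output_dir: str = "fwtract_out"
    dwi: dict | None = None  # {"dwi": ..., "bval": ..., "bvec": ...}
    templates: list | None = None
    cohort_csv: str | None = None
    phantom: dict = field(default_factory=lambda: {"snr": 40.0, "s0": 100.0})
    cohort: dict = field(default_factory=lambda: {"n_subjects": 200})
    fit: dict = field(default_factory=dict)  # FreeWaterOptions overrides
    roi: dict = field(default_factory=lambda: {"threshold": 0.0,
                                               "statistic": "mean"})
    analysis: dict = field(
        default_factory=lambda: {
            "alpha": DEFAULT_ALPHA,
            "covariates": list(DEFAULT_COVARIATES),
            "csf": "csf_abeta42",
            "outcome": "scd_total",
        }
    )

    def __post_init__(self) -> None:
        alpha = self.analysis.get("alpha", DEFAULT_ALPHA)
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    def input_paths(self) -> list[Path]:
        """Every externally supplied path; all must resolve before running."""
        paths: list[Path] = []
        if self.dwi:
            paths += [Path(self.dwi[k]) for k in ("dwi", "bval", "bvec")]
        if self.templates:
            paths += [Path(p) for p in self.templates]
        if self.cohort_csv:
            paths.append(Path(self.cohort_csv))
        return paths

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
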