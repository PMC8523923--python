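"""Run configuration: every analysis constant in one overridable place.

Defaults are the pipeline's canonical constants — ANOW passband
600–1,600 Hz, CAP passband 150–1,500 Hz, Tukey fence 3, smoothing
coefficient 0.005, SNR criterion 6 dB — and the configuration round-trips
losslessly through JSON.  A short SHA-256 prefix of the canonical JSON
identifies the configuration in every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import ValidationError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    anow_band: tuple[float, float] = (600.0, 1600.0)
    cap_band: tuple[float, float] = (150.0, 1500.0)
    artifact_fence: float = 3.0
    smoothing: float = 0.005
    snr_criterion: float = 6.0
    seed: int = 0
    output_dir: str = "results"
    # synthetic-cohort knobs used by the `all` pipeline
    n_hydropic: int = 18
    n_control: int = 8

    def __post_init__(self) -> None:
        for name in ("anow_band", "cap_band"):
            band = tuple(float(v) for v in getattr(self, name))
            if len(band) != 2 or not 0 < band[0] < band[1]:
                raise ValidationError(f"{name} must be (low, high) with 0 < low < high")
            object.__setattr__(self, name, band)
        if not 0 < self.smoothing < 1:
            raise ValidationError(f"smoothing must lie in (0, 1), got {self.smoothing}")
        if self.artifact_fence <= 0:
            raise ValidationError(f"artifact_fence must be > 0, got {self.artifact_fence}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anow_band"] = list(self.anow_band)
        d["cap_band"] = list(self.cap_band)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for name in ("anow_band", "cap_band"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Short stable identifier of this configuration."""
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
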