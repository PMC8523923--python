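"""Epoch archives and results tables.

An epoch archive is a directory holding ``epochs.bin`` — the raw row-major
64-bit float matrix (repetitions x samples, µV) — and ``meta.json`` with
the stimulus, polarity sequence, onset sample, units, and seed.  Results
are CSV tables with a JSON schema sidecar; every output records the
configuration hash that produced it, and identical input plus configuration
yields byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import EpochMatrix, ToneBurstSpec, ValidationError
from .recruit import LevelSeries, RecruitSlope, RegressionResult

__all__ = [
    "write_epoch_archive",
    "read_epoch_archive",
    "write_results",
    "read_results",
]

_META_REQUIRED = ("n_epochs", "n_samples", "sample_rate", "polarity_start", "onset_sample")


def write_epoch_archive(path: str | Path, epochs: EpochMatrix, seed: int | None = None) -> Path:
    """Write ``epochs.bin`` + ``meta.json`` under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "epochs.bin").write_bytes(np.ascontiguousarray(epochs.data, dtype="<f8").tobytes())
    meta = {
        "n_epochs": epochs.n_epochs,
        "n_samples": epochs.n_samples,
        "sample_rate": epochs.sample_rate,
        "polarity_start": int(epochs.polarity[0]),
        "onset_sample": epochs.onset_sample,
        "edge_invalid": epochs.edge_invalid,
        "units": "uV",
        "seed": seed,
    }
    if epochs.stimulus is not None:
        s = epochs.stimulus
        meta["stimulus"] = {
            "frequency": s.frequency,
            "duration": s.duration,
            "rise_fall": s.rise_fall,
            "level": s.level,
            "n_repetitions": s.n_repetitions,
            "polarity_start": s.polarity_start,
            "sample_rate": s.sample_rate,
        }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_epoch_archive(path: str | Path) -> EpochMatrix:
    """Read and validate an epoch archive written by `write_epoch_archive`."""
    path = Path(path)
    meta_path = path / "meta.json"
    bin_path = path / "epochs.bin"
    if not meta_path.exists():
        raise ValidationError(f"archive is missing meta.json: {path}")
    if not bin_path.exists():
        raise ValidationError(f"archive is missing epochs.bin: {path}")
    meta = json.loads(meta_path.read_text())
    for key in _META_REQUIRED:
        if key not in meta:
            raise ValidationError(f"meta.json is missing required field {key!r}")
    n_epochs, n_samples = int(meta["n_epochs"]), int(meta["n_samples"])
    raw = np.frombuffer(bin_path.read_bytes(), dtype="<f8")
    if raw.size != n_epochs * n_samples:
        raise ValidationError(
            f"epochs.bin holds {raw.size} values but meta.json declares "
            f"{n_epochs} x {n_samples} = {n_epochs * n_samples}"
        )
    stimulus = None
    if meta.get("stimulus"):
        stimulus = ToneBurstSpec(**meta["stimulus"])
    pol = int(meta["polarity_start"]) * (-1) ** np.arange(n_epochs)
    return EpochMatrix(
        data=raw.reshape(n_epochs, n_samples).copy(),
        sample_rate=float(meta["sample_rate"]),
        polarity=pol,
        stimulus=stimulus,
        onset_sample=int(meta["onset_sample"]),
        edge_invalid=int(meta.get("edge_invalid", 0)),
    )


_SERIES_COLUMNS = [
    "ear_id", "group", "label", "frequency_hz", "measure_kind",
    "level_db_spl", "response", "noise_floor", "snr_db",
]
_SLOPE_COLUMNS = [
    "ear_id", "group", "label", "frequency_hz",
    "threshold_db_spl", "median_slope", "n_grid_points_used",
]
_REGRESSION_COLUMNS = [
    "name", "slope", "intercept", "r_squared", "p_value", "ci_low", "ci_high", "n",
]


def write_results(
    out_dir: str | Path,
    level_series: Iterable[tuple[str, str, LevelSeries]] = (),
    slopes: Iterable[tuple[str, str, RecruitSlope]] = (),
    regressions: Mapping[str, RegressionResult] | None = None,
    config: RunConfig | None = None,
) -> Path:
    """Write the three results tables plus a schema sidecar.

    ``level_series`` and ``slopes`` are iterables of
    ``(ear_id, group, value)``; ``regressions`` maps a descriptive name to
    its result.  Column order is fixed, so identical inputs produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash if config is not None else "unconfigured"

    rows = []
    for ear_id, group, s in level_series:
        for i, level in enumerate(s.levels):
            rows.append({
                "ear_id": ear_id, "group": group, "label": s.label,
                "frequency_hz": s.frequency, "measure_kind": s.measure_kind,
                "level_db_spl": level, "response": s.response[i],
                "noise_floor": None if s.noise_floor is None else s.noise_floor[i],
                "snr_db": None if s.snr is None else s.snr[i],
            })
    _write_csv(out / "level_series.csv", rows, _SERIES_COLUMNS, cfg_hash)

    rows = [
        {
            "ear_id": ear_id, "group": group, "label": r.label,
            "frequency_hz": r.frequency, "threshold_db_spl": r.threshold,
            "median_slope": r.median_slope, "n_grid_points_used": r.n_grid_points_used,
        }
        for ear_id, group, r in slopes
    ]
    _write_csv(out / "recruit_slopes.csv", rows, _SLOPE_COLUMNS, cfg_hash)

    rows = [
        {
            "name": name, "slope": r.slope, "intercept": r.intercept,
            "r_squared": r.r_squared, "p_value": r.p_value,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "n": r.n,
        }
        for name, r in (regressions or {}).items()
    ]
    _write_csv(out / "regressions.csv", rows, _REGRESSION_COLUMNS, cfg_hash)

    schema = {
        "config_hash": cfg_hash,
        "config": config.to_dict() if config is not None else None,
        "files": {
            "level_series.csv": _SERIES_COLUMNS,
            "recruit_slopes.csv": _SLOPE_COLUMNS,
            "regressions.csv": _REGRESSION_COLUMNS,
        },
        "units": {
            "level_db_spl": "dB SPL",
            "response": "dB re 1 uV RMS (anow_magnitude), uV (cap_p2p), ms (delays)",
            "threshold_db_spl": "dB SPL",
            "median_slope": "response units per dB SPL",
        },
    }
    (out / "schema.json").write_text(json.dumps(schema, indent=2, sort_keys=True) + "\n")
    return out


def _write_csv(path: Path, rows: Sequence[dict], columns: Sequence[str], cfg_hash: str) -> None:
    df = pd.DataFrame(rows, columns=list(columns))
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_results(out_dir: str | Path, name: str) -> pd.DataFrame:
    """Read back one results table (commented header line skipped)."""
    return pd.read_csv(Path(out_dir) / name, comment="#")
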