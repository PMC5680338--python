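"""Read/write spectral datasets (wide CSV) and single spectra (JCAMP-DX).

The canonical on-disk format is a wide CSV: six reserved metadata columns
(sample_id, class_name, offal_type, fraction, replicate_id, acquisition_index)
followed by one column per wavenumber, one spectrum per row.  CSV was chosen
over a binary container so fixtures are human-inspectable and diffable.

JCAMP-DX reading supports the plain (AFFN) ``XYDATA=(X++(Y..Y))`` and
``XYPOINTS=(XY..XY)`` forms, which covers single-spectrum exchange from most
FT-IR vendors.  Interpolation onto a target grid is linear; extrapolation is
refused because silently extending a fingerprint corrupts its edges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_spectra import BEEF_MEAT, SpectralDataset, WavenumberGrid

__all__ = [
    "META_COLUMNS",
    "SpectrumRecord",
    "read_wide_csv",
    "write_wide_csv",
    "read_jcamp",
    "resample",
]

META_COLUMNS = [
    "sample_id",
    "class_name",
    "offal_type",
    "fraction",
    "replicate_id",
    "acquisition_index",
]


@dataclass
class SpectrumRecord:
    """A single spectrum plus free-form metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D of equal length")
        d = np.diff(self.wavenumbers)
        if not ((d > 0).all() or (d < 0).all()):
            raise ValueError("wavenumbers must be strictly monotone")


def _format_wavenumber(w: float) -> str:
    return f"{w:.10g}"


def write_wide_csv(dataset: SpectralDataset, path) -> None:
    """Write a dataset as wide CSV; full float precision, deterministic bytes."""
    path = Path(path)
    cols = [_format_wavenumber(w) for w in dataset.grid.values]
    spec_df = pd.DataFrame(dataset.intensities, columns=cols)
    out = pd.concat([dataset.meta[META_COLUMNS].reset_index(drop=True), spec_df], axis=1)
    out.to_csv(path, index=False, lineterminator="\n")


def read_wide_csv(path) -> SpectralDataset:
    """Read a wide-CSV dataset, validating grid monotonicity and metadata."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "class_name": str, "offal_type": str},
        float_precision="round_trip",
    )
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    spectral_cols = [c for c in df.columns if c not in META_COLUMNS]
    if len(spectral_cols) < 2:
        raise ValueError(f"{path}: needs at least 2 wavenumber columns")
    try:
        wavenumbers = np.array([float(c) for c in spectral_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber column header: {exc}") from exc
    d = np.diff(wavenumbers)
    if not ((d > 0).all() or (d < 0).all()):
        raise ValueError(f"{path}: wavenumber grid is not strictly monotone")
    if wavenumbers[0] < wavenumbers[-1]:  # store descending
        wavenumbers = wavenumbers[::-1]
        spectral_cols = spectral_cols[::-1]
    step = np.diff(wavenumbers)
    if not np.allclose(step, step[0], atol=1e-6):
        raise ValueError(f"{path}: wavenumber grid is not uniformly spaced")

    X = df[spectral_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        row = int(np.argwhere(np.isnan(X))[0, 0])
        raise ValueError(f"{path}: ragged or non-numeric spectral data at data row {row}")

    meta = df[META_COLUMNS].copy()
    meta["offal_type"] = meta["offal_type"].fillna("")
    # fraction empty -> inferred from class: 0 for beef meat, 1 for pure offal
    frac = pd.to_numeric(meta["fraction"], errors="coerce")
    inferred = np.where(meta["class_name"].to_numpy() == BEEF_MEAT, 0.0, 1.0)
    frac = frac.fillna(pd.Series(inferred, index=frac.index))
    bad = (frac < 0) | (frac > 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: fraction outside [0, 1] at data row {row}")
    meta["fraction"] = frac.astype(float)
    meta["replicate_id"] = meta["replicate_id"].astype(int)
    meta["acquisition_index"] = meta["acquisition_index"].astype(int)

    grid = WavenumberGrid(
        start_cm1=float(wavenumbers[0]),
        end_cm1=float(wavenumbers[-1]),
        n_points=len(wavenumbers),
    )
    return SpectralDataset(grid=grid, intensities=X, meta=meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# JCAMP-DX

_LABEL_RE = re.compile(r"^##(.+?)=(.*)$")


def _parse_numbers(text: str) -> list[float]:
    return [float(tok) for tok in re.split(r"[,;\s]+", text.strip()) if tok]


def read_jcamp(path) -> SpectrumRecord:
    """Read a single-spectrum JCAMP-DX file (AFFN XYDATA or XYPOINTS)."""
    path = Path(path)
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | "xydata" | "xypoints"
    block_kind = None
    for raw in path.read_text().splitlines():
        line = raw.split("$$")[0].strip()  # strip comments
        if not line:
            continue
        m = _LABEL_RE.match(line)
        if m:
            key = m.group(1).strip().upper().replace(" ", "")
            val = m.group(2).strip()
            if key == "XYDATA":
                mode = block_kind = "xydata"
                continue
            if key == "XYPOINTS":
                mode = block_kind = "xypoints"
                continue
            if key == "END":
                mode = None
                continue
            mode = None
            labels[key] = val
        elif mode is not None:
            data_lines.append(line)

    if not data_lines:
        raise ValueError(f"{path}: no XYDATA or XYPOINTS block found")

    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))

    if block_kind == "xydata":
        required = ["FIRSTX", "LASTX", "NPOINTS"]
        missing = [k for k in required if k not in labels]
        if missing:
            raise ValueError(f"{path}: missing required JCAMP labels: {missing}")
        npoints = int(float(labels["NPOINTS"]))
        firstx, lastx = float(labels["FIRSTX"]), float(labels["LASTX"])
        ys: list[float] = []
        for line in data_lines:
            nums = _parse_numbers(line)
            ys.extend(nums[1:])  # first number on each line is the X start
        if len(ys) != npoints:
            raise ValueError(
                f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found"
            )
        x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
        y = np.array(ys) * yfactor
    else:
        pairs = _parse_numbers(" ".join(data_lines))
        if len(pairs) % 2:
            raise ValueError(f"{path}: XYPOINTS block has an odd token count")
        x = np.array(pairs[0::2]) * xfactor
        y = np.array(pairs[1::2]) * yfactor

    meta = {k.lower(): v for k, v in labels.items() if k not in ("XFACTOR", "YFACTOR")}
    return SpectrumRecord(wavenumbers=x, intensities=y, metadata=meta)


def resample(record: SpectrumRecord, target_wavenumbers: np.ndarray) -> SpectrumRecord:
    """Linear interpolation onto a target grid; extrapolation is an error."""
    target = np.asarray(target_wavenumbers, dtype=float)
    lo, hi = record.wavenumbers.min(), record.wavenumbers.max()
    eps = 1e-9 * max(1.0, abs(hi))
    if target.min() < lo - eps or target.max() > hi + eps:
        raise ValueError(
            f"resampling target [{target.min()}, {target.max()}] extends beyond "
            f"the recorded range [{lo}, {hi}]; extrapolation is not supported"
        )
    order = np.argsort(record.wavenumbers)
    y = np.interp(target, record.wavenumbers[order], record.intensities[order])
    return SpectrumRecord(wavenumbers=target, intensities=y, metadata=dict(record.metadata))
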