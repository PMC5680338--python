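"""Synthetic FT-IR absorbance spectra of ground beef, offal, and their mixtures.

The generator emulates an attenuated-total-reflectance FT-IR screening study of
ground beef adulterated with edible by-products (offal).  Seven pure tissue
classes are modelled — beef meat plus three beef offal types (liver, omasum,
honey-comb tripe) and three pork offal types (heart, kidney, liver) — each as a
sum of Gaussian/Lorentzian absorption bands at the standard mid-infrared
assignments (amide I/II/III, lipid carbonyl, CH bending, phosphodiester and
polysaccharide stretches).  Binary meat–offal mixtures obey Beer–Lambert
additivity: the noiseless mixture signal is the mass-fraction-weighted convex
combination of the two parent signals, mixed *before* acquisition effects are
applied, because physical mixing precedes measurement.

Three nuisance processes mimic acquisition:

* additive white noise (``noise_sd``, absorbance units),
* a smooth positive baseline drift (``baseline_amp``, low-order polynomial plus
  a slow sinusoid),
* a multiplicative gain ("scatter", ``scatter_sd``) applied to the whole
  chemical signal, as produced by variable crystal contact.

Biological replicate-to-replicate variability is a log-normal jitter of band
amplitudes with a stated coefficient of variation, keeping absorbance positive.

Every stochastic operation takes an explicit seed; there is no global random
state, and identical inputs give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BEEF_MEAT",
    "BEEF_OFFAL_TYPES",
    "PORK_OFFAL_TYPES",
    "ALL_OFFAL_TYPES",
    "DISCRIMINATIVE_REGIONS",
    "WavenumberGrid",
    "BandSpec",
    "ClassProfile",
    "AcquisitionConfig",
    "AdulterationDesign",
    "SpectralDataset",
    "default_class_profiles",
    "render_pure_spectrum",
    "render_mixture_spectrum",
    "generate_study_dataset",
    "three_class_label",
]

BEEF_MEAT = "beef meat"
BEEF_OFFAL_TYPES = ("beef honey comb tripe", "beef liver", "beef omasum")
PORK_OFFAL_TYPES = ("pork heart", "pork kidney", "pork liver")
ALL_OFFAL_TYPES = BEEF_OFFAL_TYPES + PORK_OFFAL_TYPES

#: cm⁻¹ intervals (high, low) in which the class profiles are designed to
#: differ from beef meat; used by the feature-selection coherence checks.
DISCRIMINATIVE_REGIONS = ((1765.0, 1726.0), (1572.0, 1359.0), (1179.0, 1000.0))

AUTHENTIC = "authentic beef meat"
WITH_BEEF_OFFAL = "with beef offal"
WITH_PORK_OFFAL = "with pork offal"


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, descending wavenumber grid (instrument output convention)."""

    start_cm1: float = 4000.0
    end_cm1: float = 550.0
    n_points: int = 3451

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not self.start_cm1 > self.end_cm1:
            raise ValueError("grid is stored descending: start_cm1 must exceed end_cm1")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_cm1, self.end_cm1, self.n_points)

    @property
    def step_cm1(self) -> float:
        """Absolute spacing between adjacent points (1.0 cm⁻¹ at defaults)."""
        return (self.start_cm1 - self.end_cm1) / (self.n_points - 1)

    def contains(self, wavenumber: float) -> bool:
        return self.end_cm1 <= wavenumber <= self.start_cm1

    def interval_mask(self, interval: tuple[float, float]) -> np.ndarray:
        """Boolean mask of points inside the closed cm⁻¹ interval (order-free)."""
        hi, lo = max(interval), min(interval)
        v = self.values
        return (v >= lo - 1e-9) & (v <= hi + 1e-9)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: position, width (FWHM) and peak absorbance."""

    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError(f"band at {self.center_cm1} cm-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center_cm1} cm-1: amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, wavenumbers: np.ndarray, amplitude: float | None = None) -> np.ndarray:
        amp = self.amplitude if amplitude is None else amplitude
        d = wavenumbers - self.center_cm1
        if self.shape == "gaussian":
            return amp * np.exp(-4.0 * np.log(2.0) * (d / self.fwhm_cm1) ** 2)
        half = self.fwhm_cm1 / 2.0
        return amp * half**2 / (d**2 + half**2)


@dataclass(frozen=True)
class ClassProfile:
    """Band-model description of one pure tissue class."""

    class_name: str
    bands: tuple[BandSpec, ...]
    biological_cv: float = 0.01
    label_kind: str = "meat"  # meat | beef_offal | pork_offal

    def __post_init__(self) -> None:
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be >= 0")
        if self.label_kind not in ("meat", "beef_offal", "pork_offal"):
            raise ValueError(f"unknown label_kind {self.label_kind!r}")

    def signal(self, grid: WavenumberGrid, amplitudes: np.ndarray | None = None) -> np.ndarray:
        """Noiseless band-sum on ``grid``; optional per-band amplitude override."""
        v = grid.values
        out = np.zeros_like(v)
        for i, band in enumerate(self.bands):
            if not grid.contains(band.center_cm1):
                raise ValueError(
                    f"band center {band.center_cm1} cm-1 of class "
                    f"{self.class_name!r} lies outside the grid "
                    f"[{grid.end_cm1}, {grid.start_cm1}]"
                )
            amp = None if amplitudes is None else amplitudes[i]
            out += band.evaluate(v, amp)
        return out


@dataclass(frozen=True)
class AcquisitionConfig:
    """Instrument nuisance parameters (all in absorbance or relative units)."""

    noise_sd: float = 0.003
    baseline_amp: float = 0.05
    scatter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "baseline_amp", "scatter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noiseless(self) -> "AcquisitionConfig":
        return replace(self, noise_sd=0.0, baseline_amp=0.0, scatter_sd=0.0)


@dataclass(frozen=True)
class AdulterationDesign:
    """Sampling design: which mixtures exist and how often each is measured."""

    offal_types: tuple[str, ...] = ALL_OFFAL_TYPES
    fractions: tuple[float, ...] = (0.10, 0.25, 0.333, 0.50, 0.666)
    mixture_replicates: int = 3
    pure_replicates: int = 5
    spectra_per_sample: int = 5

    def __post_init__(self) -> None:
        if any(not 0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("mixture fractions must lie strictly inside (0, 1)")
        if min(self.pure_replicates, self.spectra_per_sample) < 1:
            raise ValueError("pure_replicates and spectra_per_sample must be >= 1")
        if self.mixture_replicates < 0:
            raise ValueError("mixture_replicates must be >= 0")


@dataclass
class SpectralDataset:
    """Aligned spectra matrix with one metadata row per spectrum.

    ``meta`` columns: sample_id, class_name, offal_type (empty string for pure
    meat), fraction (0 pure meat … 1 pure offal), replicate_id,
    acquisition_index.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.grid.n_points:
            raise ValueError(
                f"matrix has {self.intensities.shape[1]} columns but the grid "
                f"has {self.grid.n_points} points"
            )
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata rows must match spectra rows")
        frac = self.meta["fraction"].to_numpy(dtype=float)
        if ((frac < 0) | (frac > 1)).any():
            bad = int(np.argmax((frac < 0) | (frac > 1)))
            raise ValueError(f"fraction outside [0, 1] at row {bad}")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities[idx].copy(),
            meta=self.meta.iloc[idx].reset_index(drop=True).copy(),
        )

    def with_intensities(self, intensities: np.ndarray, grid: WavenumberGrid | None = None) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid if grid is None else grid,
            intensities=intensities,
            meta=self.meta.copy(),
        )


# ---------------------------------------------------------------------------
# default class profiles

_BAND_FWHM = {
    3290.0: 240.0, 2925.0: 50.0, 2854.0: 40.0,
    1740.0: 24.0, 1726.0: 20.0, 1638.0: 42.0, 1548.0: 40.0,
    1463.0: 28.0, 1399.0: 30.0, 1310.0: 36.0, 1236.0: 34.0,
    1175.0: 20.0, 1154.0: 22.0, 1118.0: 22.0, 1098.0: 20.0,
    1080.0: 20.0, 1032.0: 26.0,
}

# Peak absorbances (a.u.).  The amide I band (1638 cm⁻¹) is the shared
# normalisation anchor; class-to-class differences are deliberately confined
# to the lipid-carbonyl (1765–1726), amide-II/CH-bending (1572–1359) and
# C–O/phosphate/polysaccharide (1179–1000) regions, matching where real offal
# and muscle fingerprints diverge.  Livers carry strong nucleic-acid and
# glycogen signatures; the two stomach tissues (omasum, honey-comb tripe) are
# collagen/lipid-rich and mutually similar; pork heart and kidney sit between.
# Pork tissues additionally carry a species-linked signature — a higher
# 1726/1740 lipid-carbonyl ratio with small amide-II (1548) and tyrosine
# (1175) offsets — so the beef-vs-pork distinction survives dilution even for
# the near-identical liver pair.
_COMMON_AMPS = {3290.0: 0.45, 2925.0: 0.20, 2854.0: 0.10, 1638.0: 1.00, 1310.0: 0.13}

_CLASS_AMPS: dict[str, dict[float, float]] = {
    BEEF_MEAT: {
        1740.0: 0.3, 1726.0: 0.1, 1548.0: 0.62, 1463.0: 0.26, 1399.0: 0.2,
        1236.0: 0.15, 1175.0: 0.1, 1154.0: 0.12, 1118.0: 0.1, 1098.0: 0.12,
        1080.0: 0.1, 1032.0: 0.1,
    },
    "beef liver": {
        1740.0: 0.104, 1726.0: 0.058, 1548.0: 0.522, 1463.0: 0.41, 1399.0: 0.372,
        1236.0: 0.16, 1175.0: 0.184, 1154.0: 0.148, 1118.0: 0.254, 1098.0: 0.372,
        1080.0: 0.114, 1032.0: 0.492,
    },
    "pork liver": {
        1740.0: 0.04, 1726.0: 0.27, 1548.0: 0.466, 1463.0: 0.424, 1399.0: 0.358,
        1236.0: 0.16, 1175.0: 0.268, 1154.0: 0.162, 1118.0: 0.268, 1098.0: 0.386,
        1080.0: 0.1, 1032.0: 0.464,
    },
    "beef omasum": {
        1740.0: 0.552, 1726.0: 0.06, 1548.0: 0.76, 1463.0: 0.452, 1399.0: 0.316,
        1236.0: 0.15, 1175.0: 0.142, 1154.0: 0.064, 1118.0: 0.044, 1098.0: 0.064,
        1080.0: 0.086, 1032.0: 0.156,
    },
    "beef honey comb tripe": {
        1740.0: 0.524, 1726.0: 0.055, 1548.0: 0.732, 1463.0: 0.424, 1399.0: 0.33,
        1236.0: 0.15, 1175.0: 0.128, 1154.0: 0.078, 1118.0: 0.058, 1098.0: 0.078,
        1080.0: 0.072, 1032.0: 0.212,
    },
    "pork heart": {
        1740.0: 0.132, 1726.0: 0.3, 1548.0: 0.592, 1463.0: 0.368, 1399.0: 0.344,
        1236.0: 0.15, 1175.0: 0.198, 1154.0: 0.218, 1118.0: 0.128, 1098.0: 0.176,
        1080.0: 0.184, 1032.0: 0.296,
    },
    "pork kidney": {
        1740.0: 0.188, 1726.0: 0.31, 1548.0: 0.634, 1463.0: 0.382, 1399.0: 0.274,
        1236.0: 0.15, 1175.0: 0.212, 1154.0: 0.036, 1118.0: 0.212, 1098.0: 0.246,
        1080.0: 0.03, 1032.0: 0.212,
    },
}


def _label_kind(class_name: str) -> str:
    if class_name == BEEF_MEAT:
        return "meat"
    if class_name in BEEF_OFFAL_TYPES:
        return "beef_offal"
    return "pork_offal"


def default_class_profiles(biological_cv: float = 0.01) -> list[ClassProfile]:
    """The seven reference tissue profiles (beef meat + six offal types).

    Amplitudes are fixed reference compositions, not sampled quantities;
    ``biological_cv`` sets the replicate-to-replicate log-normal jitter used
    at render time.
    """
    profiles = []
    for name in (BEEF_MEAT,) + ALL_OFFAL_TYPES:
        amps = dict(_COMMON_AMPS)
        amps.update(_CLASS_AMPS[name])
        bands = tuple(
            BandSpec(center_cm1=c, fwhm_cm1=_BAND_FWHM[c], amplitude=a)
            for c, a in sorted(amps.items(), reverse=True)
        )
        profiles.append(
            ClassProfile(
                class_name=name,
                bands=bands,
                biological_cv=biological_cv,
                label_kind=_label_kind(name),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# deterministic seeding helpers

def _key_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    if isinstance(key, float):
        return zlib.crc32(repr(round(key, 6)).encode("ascii"))
    return int(key) & 0xFFFFFFFF


def _rng(*keys) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([_key_int(k) for k in keys]))


def _jittered_amplitudes(profile: ClassProfile, seed: int, replicate_id: int) -> np.ndarray:
    """Log-normal band amplitudes for one biological replicate (mean-preserving)."""
    base = np.array([b.amplitude for b in profile.bands])
    cv = profile.biological_cv
    if cv == 0:
        return base
    sigma = np.sqrt(np.log1p(cv**2))
    z = _rng(seed, "bio", profile.class_name, replicate_id).standard_normal(base.size)
    return base * np.exp(sigma * z - sigma**2 / 2.0)


def _true_signal(profile: ClassProfile, grid: WavenumberGrid, seed: int, replicate_id: int) -> np.ndarray:
    return profile.signal(grid, _jittered_amplitudes(profile, seed, replicate_id))


def _acquisition_effects(
    signal: np.ndarray,
    grid: WavenumberGrid,
    acq: AcquisitionConfig,
    sample_key: str,
    replicate_id: int,
    acquisition_index: int,
) -> np.ndarray:
    rng = _rng(acq.seed, "acq", sample_key, replicate_id, acquisition_index)
    gain = 1.0 + acq.scatter_sd * rng.standard_normal()
    gain = max(gain, 0.01)
    u = np.linspace(0.0, 1.0, grid.n_points)
    c0, c1, c2, phase = rng.uniform(0.0, 1.0, size=4)
    baseline = acq.baseline_amp * (
        0.3 * c0 + c1 * u + c2 * u**2 + 0.3 * (1.0 + np.sin(2.0 * np.pi * (0.35 * u + phase)))
    )
    noise = acq.noise_sd * rng.standard_normal(grid.n_points)
    return np.clip(signal * gain + baseline + noise, 0.0, None)


# ---------------------------------------------------------------------------
# rendering

def render_pure_spectrum(
    profile: ClassProfile,
    grid: WavenumberGrid,
    acq: AcquisitionConfig,
    replicate_id: int,
    acquisition_index: int = 0,
) -> np.ndarray:
    """One acquired spectrum of a pure tissue sample (biological replicate)."""
    true = _true_signal(profile, grid, acq.seed, replicate_id)
    return _acquisition_effects(true, grid, acq, profile.class_name, replicate_id, acquisition_index)


def render_mixture_spectrum(
    meat: ClassProfile,
    offal: ClassProfile,
    fraction: float,
    grid: WavenumberGrid,
    acq: AcquisitionConfig,
    replicate_id: int,
    acquisition_index: int = 0,
) -> np.ndarray:
    """One acquired spectrum of a meat–offal mixture at the given w/w fraction.

    Mixing happens on noiseless true signals (Beer–Lambert additivity), then
    acquisition effects are applied to the mixture.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    true = (1.0 - fraction) * _true_signal(meat, grid, acq.seed, replicate_id) + fraction * _true_signal(
        offal, grid, acq.seed, replicate_id
    )
    if fraction == 0.0:
        sample_key = meat.class_name
    elif fraction == 1.0:
        sample_key = offal.class_name
    else:
        sample_key = f"mix:{offal.class_name}:{fraction:.6f}"
    return _acquisition_effects(true, grid, acq, sample_key, replicate_id, acquisition_index)


def generate_study_dataset(
    design: AdulterationDesign = AdulterationDesign(),
    acq: AcquisitionConfig = AcquisitionConfig(),
    seed: int | None = None,
    grid: WavenumberGrid = WavenumberGrid(),
    biological_cv: float = 0.01,
) -> SpectralDataset:
    """Render the full sampling design: pure classes plus all binary mixtures.

    At defaults this yields 7 × 5 × 5 = 175 pure spectra and 6 × 5 × 3 = 90
    adulterated physical samples, each acquired 5 times (450 spectra).
    ``seed``, when given, overrides ``acq.seed`` for every random draw.
    """
    if seed is not None:
        acq = replace(acq, seed=int(seed))
    profiles = {p.class_name: p for p in default_class_profiles(biological_cv=biological_cv)}
    missing = [t for t in design.offal_types if t not in profiles]
    if missing:
        raise ValueError(f"no default profile for offal types: {missing}")
    meat = profiles[BEEF_MEAT]

    rows, recs = [], []
    for name in (BEEF_MEAT,) + tuple(design.offal_types):
        prof = profiles[name]
        frac = 0.0 if name == BEEF_MEAT else 1.0
        for rep in range(design.pure_replicates):
            for acq_i in range(design.spectra_per_sample):
                rows.append(render_pure_spectrum(prof, grid, acq, rep, acq_i))
                recs.append(
                    dict(
                        sample_id=f"pure-{name}-r{rep}",
                        class_name=name,
                        offal_type="" if name == BEEF_MEAT else name,
                        fraction=frac,
                        replicate_id=rep,
                        acquisition_index=acq_i,
                    )
                )
    for name in design.offal_types:
        prof = profiles[name]
        for fraction in design.fractions:
            for rep in range(design.mixture_replicates):
                for acq_i in range(design.spectra_per_sample):
                    rows.append(
                        render_mixture_spectrum(meat, prof, fraction, grid, acq, rep, acq_i)
                    )
                    recs.append(
                        dict(
                            sample_id=f"mix-{name}-f{fraction:.3f}-r{rep}",
                            class_name=name,
                            offal_type=name,
                            fraction=fraction,
                            replicate_id=rep,
                            acquisition_index=acq_i,
                        )
                    )
    meta = pd.DataFrame.from_records(recs)
    return SpectralDataset(grid=grid, intensities=np.vstack(rows), meta=meta)


def three_class_label(meta: pd.DataFrame) -> np.ndarray:
    """Authentication labels: authentic / with beef offal / with pork offal."""
    out = np.empty(len(meta), dtype=object)
    frac = meta["fraction"].to_numpy(dtype=float)
    offal = meta["offal_type"].to_numpy()
    for i in range(len(meta)):
        if frac[i] == 0.0:
            out[i] = AUTHENTIC
        elif offal[i] in BEEF_OFFAL_TYPES:
            out[i] = WITH_BEEF_OFFAL
        else:
            out[i] = WITH_PORK_OFFAL
    return out
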