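"""Synthetic spectrum generation with ground-truth annotation.

Everything the search and localization code is tested against comes from
here: ETD spectra with complete modification-preserving c/z ladders, HCD
spectra with staged neutral losses and an adenine diagnostic ion among the
strongest signals, and SILAC Lys8 MS1 isotope pairs including the
single-channel (ratio-impossible) cases.  All randomness flows from the
seed in :class:`NoiseModel`; a zero-noise model reproduces the exact
theoretical ladder.

Ground truth travels in a sidecar annotation (:class:`SyntheticSpectrum`)
that the analysis code paths never see — searches and localization consume
only the plain :class:`~adprscan.spectra.Spectrum`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .masses import (
    C13_C12,
    LYS8_DELTA,
    ModifiedPeptide,
    mz_from_neutral,
    peptide_neutral_mass,
    theoretical_fragments,
)
from .spectra import Spectrum

__all__ = [
    "NoiseModel",
    "SyntheticSpectrum",
    "simulate_etd",
    "simulate_hcd",
    "simulate_silac_ms1_pair",
]


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic distortion applied to a theoretical peak list.

    ``fragment_dropout_prob`` removes each fragment peak independently;
    ``mz_jitter_ppm`` is the standard deviation of multiplicative m/z error;
    ``intensity_cv`` the coefficient of variation of peak intensities;
    ``n_noise_peaks`` uniform chemical-noise peaks are drawn over
    ``noise_mz_range`` but never within ``noise_exclusion_ppm`` of a true
    fragment position.  Identical seed and inputs give identical output.
    """

    fragment_dropout_prob: float = 0.0
    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    n_noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (200.0, 2000.0)
    noise_exclusion_ppm: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_dropout_prob <= 1.0:
            raise ValueError("fragment_dropout_prob must be in [0, 1]")
        if self.mz_jitter_ppm < 0 or self.intensity_cv < 0:
            raise ValueError("jitter and intensity CV must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")
        if self.noise_mz_range[0] >= self.noise_mz_range[1]:
            raise ValueError("noise_mz_range must be (lo, hi) with lo < hi")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls(seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticSpectrum:
    """A simulated spectrum plus the ground truth that generated it."""

    spectrum: Spectrum
    peptide: ModifiedPeptide
    true_sites: tuple[int, ...]
    true_mode: Literal["HCD", "ETD"]


def _base_intensity(index: int, ladder_len: int, scale: float = 100.0) -> float:
    # smooth arch over the ladder: mid-sequence ions strongest, ends weakest
    frac = index / (ladder_len + 1)
    return scale * (0.4 + 0.6 * math.sin(math.pi * frac))


def _apply_noise(
    mz: list[float],
    intensity: list[float],
    noise: NoiseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    mz_arr = np.asarray(mz, dtype=float)
    int_arr = np.asarray(intensity, dtype=float)
    theoretical = mz_arr.copy()

    if noise.fragment_dropout_prob > 0 and len(mz_arr):
        keep = rng.random(len(mz_arr)) >= noise.fragment_dropout_prob
        mz_arr, int_arr = mz_arr[keep], int_arr[keep]
    if noise.mz_jitter_ppm > 0 and len(mz_arr):
        mz_arr = mz_arr * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm, len(mz_arr)) * 1e-6)
    if noise.intensity_cv > 0 and len(int_arr):
        int_arr = int_arr * np.maximum(rng.normal(1.0, noise.intensity_cv, len(int_arr)), 0.05)

    if noise.n_noise_peaks > 0:
        lo, hi = noise.noise_mz_range
        ref = int_arr.max() if len(int_arr) else 100.0
        placed: list[float] = []
        attempts = 0
        while len(placed) < noise.n_noise_peaks and attempts < 50 * noise.n_noise_peaks:
            attempts += 1
            cand = rng.uniform(lo, hi)
            tol = cand * noise.noise_exclusion_ppm * 1e-6
            if len(theoretical) and np.min(np.abs(theoretical - cand)) < tol:
                continue  # never sit on a true fragment position
            placed.append(cand)
        noise_int = rng.uniform(0.01, 0.3, len(placed)) * ref
        mz_arr = np.concatenate([mz_arr, placed])
        int_arr = np.concatenate([int_arr, noise_int])
    return mz_arr, int_arr


def _fragment_charges(precursor_charge: int) -> int:
    # singly charged fragments always; doubly charged once the precursor
    # carries three or more protons
    return 2 if precursor_charge >= 3 else 1


def simulate_etd(
    p: ModifiedPeptide,
    precursor_charge: int,
    noise: NoiseModel,
    title: str = "etd",
) -> SyntheticSpectrum:
    """ETD spectrum of a peptide: the complete intact c/z ladder plus noise.

    Only multiply-charged precursors are subjected to ETD, so
    ``precursor_charge`` must be at least 2.  With a zero noise model the
    output peak list is exactly the theoretical ladder.
    """
    if precursor_charge < 2:
        raise ValueError("ETD requires a multiply-charged precursor (charge >= 2)")
    frags = theoretical_fragments(p, "ETD", _fragment_charges(precursor_charge))
    n = len(p)
    mzs, ints = [], []
    for f in frags:
        mzs.append(f.mz)
        ints.append(_base_intensity(f.index, n - 1) / f.charge)
    rng = noise.rng()
    mz_arr, int_arr = _apply_noise(mzs, ints, noise, rng)
    spec = Spectrum(
        title=title,
        precursor_mz=mz_from_neutral(peptide_neutral_mass(p), precursor_charge),
        precursor_charge=precursor_charge,
        mode="ETD",
        mz=mz_arr,
        intensity=int_arr,
    )
    return SyntheticSpectrum(spec, p, tuple(sorted(p.placements)), "ETD")


def simulate_hcd(
    p: ModifiedPeptide,
    precursor_charge: int,
    noise: NoiseModel,
    title: str = "hcd",
    diagnostic_intensity_factor: float = 1.2,
) -> SyntheticSpectrum:
    """HCD spectrum: b/y ions in all loss states plus diagnostic reporter ions.

    Modification-spanning fragments appear intact, as phosphoribose
    remainders and fully stripped (the linkage is labile under collisional
    activation).  If the peptide carries a species with diagnostic ions,
    those are placed at ``diagnostic_intensity_factor`` times the strongest
    fragment — among the strongest signals in the spectrum, as observed for
    protonated adenine.  Unmodified peptides receive no diagnostic ions.
    """
    if precursor_charge < 1:
        raise ValueError("precursor charge must be >= 1")
    frags = theoretical_fragments(p, "HCD", _fragment_charges(precursor_charge))
    n = len(p)
    mzs, ints = [], []
    diag = []
    for f in frags:
        if f.series == "diag":
            diag.append(f.mz)
            continue
        mzs.append(f.mz)
        ints.append(_base_intensity(f.index, n - 1) / f.charge)
    top = max(ints) if ints else 100.0
    for d in diag:
        mzs.append(d)
        ints.append(diagnostic_intensity_factor * top)
    rng = noise.rng()
    mz_arr, int_arr = _apply_noise(mzs, ints, noise, rng)
    spec = Spectrum(
        title=title,
        precursor_mz=mz_from_neutral(peptide_neutral_mass(p), precursor_charge),
        precursor_charge=precursor_charge,
        mode="HCD",
        mz=mz_arr,
        intensity=int_arr,
    )
    return SyntheticSpectrum(spec, p, tuple(sorted(p.placements)), "HCD")


def simulate_silac_ms1_pair(
    p: ModifiedPeptide,
    true_ratio_H_over_L: float,
    charge: int,
    noise: NoiseModel,
    base_intensity: float = 1e5,
) -> tuple[np.ndarray, np.ndarray]:
    """SILAC Lys8 MS1 isotope pair for a peptide.

    Returns (light_cluster, heavy_cluster), each an array of (m/z, intensity)
    rows over three isotopologue peaks.  The clusters are separated by
    ``#K * 8.01420 / charge`` Th and their summed intensities stand in the
    requested H/L ratio before noise.  A ratio of 0 yields a light-only pair
    and ``inf`` a heavy-only pair, emulating the single-channel observations
    where one SILAC state gives no signal at all.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if true_ratio_H_over_L < 0:
        raise ValueError("ratio must be >= 0 (use inf for heavy-only)")
    n_k = p.sequence.count("K")
    if n_k == 0:
        warnings.warn("peptide contains no lysine; heavy and light channels coincide")

    light_pep = replace(p, heavy_labels={})
    light_mz = mz_from_neutral(peptide_neutral_mass(light_pep), charge)
    shift = n_k * LYS8_DELTA / charge
    iso_rel = (1.0, 0.5, 0.2)  # simplified 3-peak envelope
    rng = noise.rng()

    def cluster(start_mz: float, total: float) -> np.ndarray:
        if total <= 0:
            return np.empty((0, 2))
        rel = np.asarray(iso_rel)
        ints = base_intensity * total * rel / rel.sum()
        mzs = start_mz + np.arange(3) * C13_C12 / charge
        if noise.mz_jitter_ppm > 0:
            mzs = mzs * (1.0 + rng.normal(0.0, noise.mz_jitter_ppm, 3) * 1e-6)
        if noise.intensity_cv > 0:
            ints = ints * np.maximum(rng.normal(1.0, noise.intensity_cv, 3), 0.05)
        return np.column_stack([mzs, ints])

    if math.isinf(true_ratio_H_over_L):
        light = cluster(light_mz, 0.0)
        heavy = cluster(light_mz + shift, 1.0)
    else:
        light = cluster(light_mz, 1.0)
        heavy = cluster(light_mz + shift, true_ratio_H_over_L)
    return light, heavy
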