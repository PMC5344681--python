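"""Peptide-spectrum matching for ADP-ribosylated peptides.

Two search modes are provided.  *Localization-free* search treats the
modifier as an entirely labile C-terminal mass tag: every candidate peptide
generates exactly two hypotheses (with and without the tag), the tag shifts
the precursor mass but never the fragment masses.  This is the cheap,
sensitive mode used to ask "is this spectrum an ADPr peptide at all?".
*Variable-modification* search enumerates placements of the modification on
allowed residues and scores each placement's full fragment hypothesis —
HCD hypotheses include the staged neutral-loss states, ETD hypotheses are
intact-only.

The PSM score follows the Morpheus convention: number of matched theoretical
products plus the fraction of total spectrum intensity they carry.  Absolute
score values are engine-specific; only rankings and in-repo calibrated
thresholds are ever interpreted.

This module also models the acquisition logic: an HCD survey scan is
screened for the protonated-adenine diagnostic ion (m/z 136.0618) and a
multiply-charged precursor showing an intense diagnostic peak triggers ETD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .digestion import DigestParams, MAXQUANT_STYLE, MORPHEUS_STYLE, digest
from .masses import (
    ADENINE_ION_MZ,
    C13_C12,
    PROTON,
    FragmentIon,
    ModificationSpecies,
    ModifiedPeptide,
    get_species,
    peptide_neutral_mass,
    theoretical_fragments,
)
from .spectra import Spectrum

__all__ = [
    "SearchParams",
    "PSM",
    "SearchResult",
    "preprocess_spectrum",
    "detect_diagnostic_ion",
    "acquisition_decision",
    "match_fragments",
    "score_psm",
    "enumerate_placements",
    "search_localization_free",
    "search_variable_mod",
]


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances and hypothesis-space limits.

    Defaults mirror the localization-search settings (4.5 ppm precursor,
    20 ppm fragment, top 20 peaks per 100 Da, ADPr allowed on DEKRSTCYNQHM);
    :meth:`localization_free` gives the Morpheus-style settings (10/10 ppm,
    precursor isotope assignment off by up to 3).
    """

    precursor_tol_ppm: float = 4.5
    fragment_tol_ppm: float = 20.0
    isotope_offset_max: int = 3
    max_charge: int = 7
    top_peaks_per_100da: int = 20
    mode: Literal["localization_free", "variable_mod"] = "variable_mod"
    allowed_mod_residues: str = "DEKRSTCYNQHM"
    max_var_mods_per_peptide: int = 1
    max_hypotheses_per_peptide: int = 5000

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("mass tolerances must be > 0")
        if self.isotope_offset_max < 0:
            raise ValueError("isotope_offset_max must be >= 0")
        if self.top_peaks_per_100da < 1:
            raise ValueError("top_peaks_per_100da must be >= 1")

    @classmethod
    def localization_free(cls) -> "SearchParams":
        return cls(
            precursor_tol_ppm=10.0,
            fragment_tol_ppm=10.0,
            isotope_offset_max=3,
            mode="localization_free",
        )


@dataclass
class PSM:
    """A scored peptide-spectrum match."""

    spectrum_title: str
    peptide: ModifiedPeptide
    score: float
    matched_peak_count: int
    matched_intensity_fraction: float
    precursor_error_ppm: float
    isotope_offset: int
    is_adpr_hypothesis: bool
    protein: str | None = None
    start: int | None = None
    rank: int = 0
    spectrum: Spectrum | None = None


class SearchResult(list):
    """A list of PSMs carrying search bookkeeping in ``stats``.

    ``stats['hypotheses_generated']`` counts every hypothesis considered
    (scored or rejected at the precursor stage); in localization-free mode
    this is exactly two per candidate peptide per spectrum.
    """

    def __init__(self, psms: Iterable[PSM] = (), stats: dict | None = None):
        super().__init__(psms)
        self.stats: dict = stats or {}


def preprocess_spectrum(s: Spectrum, top_n: int) -> Spectrum:
    """Keep only the ``top_n`` most intense peaks per 100-Da window.

    Windows are consecutive 100-Da intervals starting at the spectrum's
    lowest m/z; each window is filtered independently and m/z order is
    preserved.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(s) == 0:
        return s
    lo = s.mz[0]
    window = np.floor((s.mz - lo) / 100.0).astype(int)
    keep = np.zeros(len(s), dtype=bool)
    for w in np.unique(window):
        idx = np.flatnonzero(window == w)
        if len(idx) <= top_n:
            keep[idx] = True
        else:
            # strongest first; ties broken toward lower m/z for determinism
            order = sorted(idx, key=lambda i: (-s.intensity[i], s.mz[i]))
            keep[np.asarray(order[:top_n])] = True
    return Spectrum(s.title, s.precursor_mz, s.precursor_charge, s.mode,
                    mz=s.mz[keep], intensity=s.intensity[keep])


def detect_diagnostic_ion(
    s: Spectrum,
    tol_ppm: float = 10.0,
    min_relative_intensity: float = 0.05,
) -> tuple[bool, int | None]:
    """Screen an HCD spectrum for the protonated-adenine diagnostic ion.

    Returns ``(present, intensity_rank)`` where rank is 1-based among all
    peaks ordered by decreasing intensity.  ETD spectra are rejected: the
    ETD reaction does not generate ADP-ribose diagnostic ions, so they are
    not available as a screening criterion there.
    """
    if s.mode == "ETD":
        raise ValueError("diagnostic-ion screening applies to HCD spectra only")
    if len(s) == 0:
        return False, None
    tol = ADENINE_ION_MZ * tol_ppm * 1e-6
    in_window = np.abs(s.mz - ADENINE_ION_MZ) <= tol
    if not np.any(in_window):
        return False, None
    best = np.flatnonzero(in_window)[np.argmax(s.intensity[in_window])]
    rank = int(np.sum(s.intensity > s.intensity[best])) + 1
    present = s.intensity[best] >= min_relative_intensity * s.base_peak_intensity
    return bool(present), rank


def acquisition_decision(
    hcd: Spectrum,
    tol_ppm: float = 10.0,
    min_relative_intensity: float = 0.05,
) -> bool:
    """Would this HCD survey scan trigger an ETD acquisition?

    True iff the diagnostic adenine ion is present at sufficient relative
    intensity and the precursor is multiply charged (only multiply-charged
    precursors are re-isolated for ETD).
    """
    present, _ = detect_diagnostic_ion(hcd, tol_ppm, min_relative_intensity)
    return present and hcd.precursor_charge >= 2


def match_fragments(
    s: Spectrum,
    theo_mz: Sequence[float],
    tol_ppm: float,
) -> list[int]:
    """Assign theoretical m/z values to spectrum peaks.

    Each theoretical ion takes at most one peak (the nearest within
    tolerance) and each peak is used at most once.  Theoretical ions are
    processed in ascending m/z order for determinism.  Returns, per
    theoretical ion (input order), the matched peak index or -1.
    """
    assignment = [-1] * len(theo_mz)
    if len(s) == 0 or not len(theo_mz):
        return assignment
    used = np.zeros(len(s), dtype=bool)
    order = sorted(range(len(theo_mz)), key=lambda k: theo_mz[k])
    for k in order:
        mz = theo_mz[k]
        tol = mz * tol_ppm * 1e-6
        lo = np.searchsorted(s.mz, mz - tol, side="left")
        hi = np.searchsorted(s.mz, mz + tol, side="right")
        best, best_d = -1, tol + 1.0
        for i in range(lo, hi):
            if used[i]:
                continue
            d = abs(s.mz[i] - mz)
            if d < best_d:
                best, best_d = i, d
        if best >= 0:
            assignment[k] = best
            used[best] = True
    return assignment


def score_psm(
    s: Spectrum,
    fragments: Sequence[FragmentIon] | Sequence[float],
    fragment_tol_ppm: float,
) -> tuple[float, int, float]:
    """Morpheus-style PSM score for one fragment hypothesis.

    Returns ``(score, matched_peak_count, matched_intensity_fraction)`` with
    ``score = matched_peak_count + matched_intensity_fraction``.  Adding a
    matched peak therefore always increases the score by at least 1, so the
    integer part dominates and the intensity fraction breaks ties.
    """
    if not len(fragments):
        raise ValueError("fragment hypothesis is empty")
    theo = [f.mz if isinstance(f, FragmentIon) else float(f) for f in fragments]
    assignment = match_fragments(s, theo, fragment_tol_ppm)
    matched = [i for i in assignment if i >= 0]
    count = len(matched)
    total = float(s.intensity.sum())
    frac = float(s.intensity[matched].sum()) / total if total > 0 and count else 0.0
    return count + frac, count, frac


def _fragment_charges(precursor_charge: int) -> int:
    return 2 if precursor_charge >= 3 else 1


def _precursor_fit(
    observed_neutral: float, hypothesis_mass: float, params: SearchParams
) -> tuple[int, float] | None:
    """Best isotope offset and residual ppm error, or None if out of tolerance.

    The precursor isotopic assignment may be off by up to
    ``isotope_offset_max`` 13C spacings; the smallest residual wins.
    """
    best: tuple[int, float] | None = None
    for k in range(params.isotope_offset_max + 1):
        err_ppm = (observed_neutral - k * C13_C12 - hypothesis_mass) / hypothesis_mass * 1e6
        if abs(err_ppm) <= params.precursor_tol_ppm:
            if best is None or abs(err_ppm) < abs(best[1]):
                best = (k, err_ppm)
    return best


def _rank_and_collect(psms: list[PSM]) -> list[PSM]:
    """Deterministic ordering: score desc, then |ppm|, mod count, sequence."""
    psms.sort(
        key=lambda m: (
            -m.score,
            abs(m.precursor_error_ppm),
            len(m.peptide.placements) + (m.peptide.c_term_labile_mod is not None),
            m.peptide.sequence,
        )
    )
    for r, m in enumerate(psms, start=1):
        m.rank = r
    return psms


def _candidates(
    proteins: Sequence[tuple[str, str, str]], digest_params: DigestParams
) -> list[tuple[str, str, int]]:
    out = []
    seen = set()
    for acc, _desc, seq in proteins:
        for pep, start in digest(seq, digest_params):
            key = (pep, acc, start)
            if key not in seen:
                seen.add(key)
                out.append((pep, acc, start))
    return out


def search_localization_free(
    spectra: Iterable[Spectrum],
    proteins: Sequence[tuple[str, str, str]],
    params: SearchParams | None = None,
    digest_params: DigestParams = MORPHEUS_STYLE,
    species: ModificationSpecies | None = None,
) -> SearchResult:
    """Localization-free search: two hypotheses per candidate peptide.

    For every tryptic candidate the spectrum is scored against (1) the plain
    peptide and (2) the peptide carrying the modifier as an entirely labile
    C-terminal mass tag.  The tag contributes to the precursor mass only;
    the fragment hypothesis is that of the stripped peptide (complete loss
    during fragmentation), plus the species' diagnostic reporter ions for
    HCD spectra.  PSMs for each spectrum are returned ranked, best first.
    """
    params = params or SearchParams.localization_free()
    species = species or get_species("ADPr")
    cands = _candidates(proteins, digest_params)
    result = SearchResult(stats={"hypotheses_generated": 0, "candidates": len(cands)})

    for spec in spectra:
        spec_p = preprocess_spectrum(spec, params.top_peaks_per_100da)
        obs_neutral = spec.precursor_mz * spec.precursor_charge - spec.precursor_charge * PROTON
        nch = _fragment_charges(spec.precursor_charge)
        matches: list[PSM] = []
        for pep_seq, acc, start in cands:
            plain = ModifiedPeptide(pep_seq)
            tagged = ModifiedPeptide(pep_seq, c_term_labile_mod=species)
            for hypothesis, is_adpr in ((plain, False), (tagged, True)):
                result.stats["hypotheses_generated"] += 1
                fit = _precursor_fit(obs_neutral, peptide_neutral_mass(hypothesis), params)
                if fit is None:
                    continue
                # labile tag: fragments are those of the stripped peptide
                frags: list = list(theoretical_fragments(plain, spec.mode, nch))
                if is_adpr and spec.mode == "HCD":
                    frags.extend(
                        FragmentIon("diag", 0, 1, "intact", mz)
                        for mz in species.diagnostic_ions
                    )
                score, count, frac = score_psm(spec_p, frags, params.fragment_tol_ppm)
                if count == 0:
                    continue
                matches.append(
                    PSM(spec.title, hypothesis, score, count, frac, fit[1], fit[0],
                        is_adpr, protein=acc, start=start, spectrum=spec)
                )
        result.extend(_rank_and_collect(matches))
    return result


def enumerate_placements(
    peptide: ModifiedPeptide | str,
    species: ModificationSpecies,
    allowed_residues: str,
    max_mods: int,
) -> list[ModifiedPeptide]:
    """All placement hypotheses of ``species`` on allowed residues.

    Includes the unmodified peptide and every combination of 1 to
    ``max_mods`` placements.  A peptide with one allowed residue and one
    permitted modification therefore yields exactly two hypotheses.
    """
    base = ModifiedPeptide(peptide) if isinstance(peptide, str) else peptide
    sites = [i + 1 for i, aa in enumerate(base.sequence) if aa in allowed_residues]
    out = [replace(base, placements={})]
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(sites, k):
            out.append(replace(base, placements={i: species for i in combo}))
    return out


def search_variable_mod(
    spectra: Iterable[Spectrum],
    proteins: Sequence[tuple[str, str, str]],
    params: SearchParams | None = None,
    digest_params: DigestParams = MAXQUANT_STYLE,
    species: ModificationSpecies | None = None,
) -> SearchResult:
    """Variable-modification search over explicit placement hypotheses.

    Placements of the modification species are enumerated on the allowed
    residues up to ``max_var_mods_per_peptide``.  HCD hypotheses carry the
    neutral-loss fragment states and diagnostic ions; ETD hypotheses are
    intact-only.  Peptides whose hypothesis count exceeds the configured
    cap are skipped with a warning.
    """
    params = params or SearchParams()
    species = species or get_species("ADPr")
    cands = _candidates(proteins, digest_params)
    result = SearchResult(stats={"hypotheses_generated": 0, "candidates": len(cands)})

    for spec in spectra:
        spec_p = preprocess_spectrum(spec, params.top_peaks_per_100da)
        obs_neutral = spec.precursor_mz * spec.precursor_charge - spec.precursor_charge * PROTON
        nch = _fragment_charges(spec.precursor_charge)
        matches: list[PSM] = []
        for pep_seq, acc, start in cands:
            n_sites = sum(aa in params.allowed_mod_residues for aa in pep_seq)
            n_hyp = sum(
                _ncomb(n_sites, k) for k in range(0, params.max_var_mods_per_peptide + 1)
            )
            if n_hyp > params.max_hypotheses_per_peptide:
                warnings.warn(
                    f"skipping {pep_seq}: {n_hyp} placement hypotheses exceed cap"
                )
                continue
            for hypothesis in enumerate_placements(
                pep_seq, species, params.allowed_mod_residues,
                params.max_var_mods_per_peptide,
            ):
                result.stats["hypotheses_generated"] += 1
                fit = _precursor_fit(obs_neutral, peptide_neutral_mass(hypothesis), params)
                if fit is None:
                    continue
                frags = theoretical_fragments(hypothesis, spec.mode, nch)
                score, count, frac = score_psm(spec_p, frags, params.fragment_tol_ppm)
                if count == 0:
                    continue
                matches.append(
                    PSM(spec.title, hypothesis, score, count, frac, fit[1], fit[0],
                        bool(hypothesis.placements), protein=acc, start=start,
                        spectrum=spec)
                )
        result.extend(_rank_and_collect(matches))
    return result


def _ncomb(n: int, k: int) -> int:
    import math

    return math.comb(n, k) if 0 <= k <= n else 0
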