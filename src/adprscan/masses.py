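"""Monoisotopic mass arithmetic for ADP-ribosylated peptides.

This module is the single source of truth for atomic masses, amino-acid
residue compositions, the ADP-ribose modification species table (the five
staged neutral losses observed in HCD plus the adenine diagnostic ion), and
theoretical fragment-ion generation for HCD (b/y) and ETD (c/z).

The chemistry in one paragraph: ADP-ribose transferred from NAD+ adds
C15H21N5O13P2 (+541.06111 Da) to an acceptor residue.  The ester linkage to
serine is labile under collisional activation, so HCD spectra show staged
neutral losses of adenine, adenosine-minus-water, AMP, ADP and the entire
ADP-ribose, together with a protonated-adenine diagnostic ion at m/z
136.0618.  Electron-transfer dissociation leaves the linkage intact, which
is what makes residue-level localization possible: every c/z ion of an ETD
spectrum is generated here exclusively in the ``intact`` modification state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "ELEMENT_MASS",
    "PROTON",
    "C13_C12",
    "N15_N14",
    "LYS8_DELTA",
    "WATER",
    "AMMONIA",
    "ACETYL",
    "AMIDE",
    "RESIDUE_FORMULA",
    "RESIDUE_MASS",
    "ADENINE_ION_MZ",
    "parse_formula",
    "monoisotopic_mass",
    "LossEvent",
    "ModificationSpecies",
    "adpr_species_table",
    "get_species",
    "ModifiedPeptide",
    "FragmentIon",
    "peptide_neutral_mass",
    "theoretical_fragments",
    "mz_from_neutral",
]

# Monoisotopic atomic masses (NIST/CODATA), pinned here and nowhere else.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON = 1.00727646688
#: 13C - 12C, the spacing between adjacent isotopologue peaks (per charge).
C13_C12 = 13.00335483507 - 12.0
N15_N14 = 15.00010889888 - ELEMENT_MASS["N"]
#: SILAC Lys8 label: six 13C plus two 15N, computed, not hard-coded.
LYS8_DELTA = 6 * C13_C12 + 2 * N15_N14

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string such as ``'C5H5N5'`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        if not match.group(0):
            break
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of an elemental formula.

    Accepts either a mapping of element symbol to count or a formula string.
    The empty formula has mass 0.  Unknown element symbols raise ``KeyError``
    naming the offending symbol.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for element, count in formula.items():
        if count < 0:
            raise ValueError(f"negative count for element {element}")
        if element not in ELEMENT_MASS:
            raise KeyError(f"unknown element symbol: {element!r}")
        total += ELEMENT_MASS[element] * count
    return total


WATER = monoisotopic_mass("H2O")
AMMONIA = monoisotopic_mass("NH3")
#: N-terminal acetylation delta (C2H2O).
ACETYL = monoisotopic_mass("C2H2O")
#: C-terminal amidation delta (-OH +NH2).
AMIDE = monoisotopic_mass("NH2") - monoisotopic_mass("OH")

# Residue (i.e. dehydrated amino-acid) compositions, 20 canonical residues.
RESIDUE_FORMULA: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

RESIDUE_MASS: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_FORMULA.items()
}


@dataclass(frozen=True)
class LossEvent:
    """A neutral loss from a modified ion: the species lost and what remains."""

    name: str
    neutral_loss: float  # Da, mass of the ejected neutral
    remainder: float  # Da, modification mass left on the fragment


@dataclass(frozen=True)
class ModificationSpecies:
    """A covalent modification with its gas-phase loss behaviour.

    ``delta_mass`` is added to the residue.  ``loss_events`` enumerate the
    neutral species this modification can eject under collisional activation;
    for each, ``remainder == delta_mass - neutral_loss`` within 1e-4 Da.
    ``diagnostic_ions`` are standalone reporter m/z values expected in HCD.
    """

    name: str
    delta_mass: float
    loss_events: tuple[LossEvent, ...] = ()
    diagnostic_ions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for ev in self.loss_events:
            if abs((self.delta_mass - ev.neutral_loss) - ev.remainder) > 1e-4:
                raise ValueError(
                    f"{self.name}: loss event {ev.name} remainder inconsistent"
                )

    @property
    def phosphoribose_remainder(self) -> float | None:
        """Remainder mass after AMP loss (the phosphoribose tag), if defined."""
        for ev in self.loss_events:
            if ev.name == "AMP":
                return ev.remainder
        return None


# Neutral compositions of the lost species.  The instrument reports these as
# protonated ions; the neutral loss applied to a fragment is the neutral mass.
_ADENINE = monoisotopic_mass("C5H5N5")
_ADENOSINE_MINUS_H2O = monoisotopic_mass("C10H11N5O3")
_AMP = monoisotopic_mass("C10H14N5O7P")
_ADP = monoisotopic_mass("C10H15N5O10P2")
_ADPR = monoisotopic_mass("C15H21N5O13P2")  # = the full modification delta

#: Protonated adenine, the HCD diagnostic ion (m/z 136.0618).
ADENINE_ION_MZ = _ADENINE + PROTON

#: Gas-phase phosphoribose remainder after AMP loss (C5H7O6P).
PHOSPHORIBOSE_GAS = _ADPR - _AMP
#: Phosphoribose left by Nudix hydrolase treatment in solution; hydrolysis
#: adds water relative to the gas-phase remainder (C5H9O7P).
PHOSPHORIBOSE_NUDIX = PHOSPHORIBOSE_GAS + WATER


def adpr_species_table() -> list[ModificationSpecies]:
    """The modification species this pipeline understands.

    Returns ADP-ribose (+541.06111 Da) with its five staged neutral losses —
    adenine, adenosine minus water, AMP, ADP and the complete ADP-ribose —
    plus the two phosphoribose species: the gas-phase AMP-loss remainder
    (+193.99802 Da) and the Nudix-hydrolysis product (+212.00859 Da).
    All masses derive from elemental compositions pinned in this module.
    """
    adpr = ModificationSpecies(
        name="ADPr",
        delta_mass=_ADPR,
        loss_events=(
            LossEvent("adenine", _ADENINE, _ADPR - _ADENINE),
            LossEvent("adenosine-H2O", _ADENOSINE_MINUS_H2O, _ADPR - _ADENOSINE_MINUS_H2O),
            LossEvent("AMP", _AMP, _ADPR - _AMP),
            LossEvent("ADP", _ADP, _ADPR - _ADP),
            LossEvent("ADP-ribose", _ADPR, 0.0),
        ),
        diagnostic_ions=(ADENINE_ION_MZ,),
    )
    phospho_gas = ModificationSpecies(
        name="phosphoribose_gas", delta_mass=PHOSPHORIBOSE_GAS
    )
    phospho_nudix = ModificationSpecies(
        name="phosphoribose_nudix", delta_mass=PHOSPHORIBOSE_NUDIX
    )
    return [adpr, phospho_gas, phospho_nudix]


def get_species(name: str) -> ModificationSpecies:
    """Look up a species from :func:`adpr_species_table` by name."""
    for sp in adpr_species_table():
        if sp.name == name:
            return sp
    raise KeyError(f"unknown modification species: {name!r}")


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with terminal groups and modification placements.

    ``placements`` maps 1-based residue index to a modification species.
    ``c_term_labile_mod`` is the localization-free alternative: the modifier
    is carried as a fully labile C-terminal mass tag (it shifts the precursor
    but not intact fragment masses).  A peptide has either placements or a
    labile tag, never both.  ``heavy_labels`` maps residue letters to SILAC
    mass deltas (e.g. ``{"K": LYS8_DELTA}``).
    """

    sequence: str
    n_term: Literal["free", "acetyl"] = "free"
    c_term: Literal["free", "amide"] = "free"
    placements: Mapping[int, ModificationSpecies] = field(default_factory=dict)
    c_term_labile_mod: ModificationSpecies | None = None
    heavy_labels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise ValueError(f"non-canonical residue(s): {sorted(bad)}")
        if self.n_term not in ("free", "acetyl"):
            raise ValueError(f"unknown n_term {self.n_term!r}")
        if self.c_term not in ("free", "amide"):
            raise ValueError(f"unknown c_term {self.c_term!r}")
        for idx in self.placements:
            if not 1 <= idx <= len(self.sequence):
                raise ValueError(f"placement index {idx} outside peptide")
        if self.placements and self.c_term_labile_mod is not None:
            raise ValueError("peptide cannot carry both placements and a labile tag")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_term_delta(self) -> float:
        return ACETYL if self.n_term == "acetyl" else 0.0

    @property
    def c_term_delta(self) -> float:
        return AMIDE if self.c_term == "amide" else 0.0

    def residue_mass(self, i: int) -> float:
        """Mass of residue ``i`` (1-based) including heavy label, excluding mods."""
        aa = self.sequence[i - 1]
        return RESIDUE_MASS[aa] + self.heavy_labels.get(aa, 0.0)

    def with_placement(self, index: int, species: ModificationSpecies) -> "ModifiedPeptide":
        """A copy carrying a single placed modification at ``index``."""
        return ModifiedPeptide(
            sequence=self.sequence,
            n_term=self.n_term,
            c_term=self.c_term,
            placements={index: species},
            heavy_labels=dict(self.heavy_labels),
        )


ModState = Literal["intact", "phosphoribose_remainder", "full_loss", "unmodified"]


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical product ion.

    ``series`` is b/y (HCD), c/z (ETD) or ``diag`` for standalone diagnostic
    reporter ions.  ``index`` counts residues from the respective terminus.
    ``mod_state`` records what happened to a spanned modification: intact,
    reduced to phosphoribose (AMP loss), fully lost, or not spanned at all.
    """

    series: str
    index: int
    charge: int
    mod_state: ModState
    mz: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")


def peptide_neutral_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass of a (modified) peptide.

    Residue masses + H2O + terminal-group deltas + placed-modification deltas
    + the labile C-terminal tag (if any) + heavy-label deltas.
    """
    mass = WATER + p.n_term_delta + p.c_term_delta
    for i in range(1, len(p) + 1):
        mass += p.residue_mass(i)
    for sp in p.placements.values():
        mass += sp.delta_mass
    if p.c_term_labile_mod is not None:
        mass += p.c_term_labile_mod.delta_mass
    return mass


def mz_from_neutral(neutral: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons."""
    return (neutral + charge * PROTON) / charge


def _prefix_masses(p: ModifiedPeptide) -> list[float]:
    """prefix[i] = mass of residues 1..i (heavy labels included, no mods)."""
    out = [0.0]
    for i in range(1, len(p) + 1):
        out.append(out[-1] + p.residue_mass(i))
    return out


def theoretical_fragments(
    p: ModifiedPeptide,
    mode: Literal["HCD", "ETD"],
    max_charge: int = 1,
) -> list[FragmentIon]:
    """Theoretical fragment ions of a modified peptide.

    ETD yields c and z(dot) ions only; fragments spanning a placed
    modification appear exclusively in the ``intact`` state because ETD
    preserves the ADP-ribose linkage.  HCD yields b and y ions; each
    modification-spanning fragment appears in three states (intact,
    phosphoribose remainder after AMP loss, full loss), and the species'
    diagnostic reporter ions are appended as standalone singly-charged
    entries.  Offsets: c = b + NH3; z = y - NH2 (z-dot radical convention).
    """
    n = len(p)
    if n < 2:
        raise ValueError("peptide must have length >= 2 to fragment")
    if mode not in ("HCD", "ETD"):
        raise ValueError(f"unknown fragmentation mode {mode!r}")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")

    prefix = _prefix_masses(p)
    total_modless = prefix[n]
    mod_indices = sorted(p.placements)
    z_offset = AMMONIA - ELEMENT_MASS["H"]  # z-dot: y - 16.01872

    out: list[FragmentIon] = []
    for i in range(1, n):
        j = n - i  # complementary suffix length
        b_neutral = prefix[i] + p.n_term_delta
        y_neutral = (total_modless - prefix[i]) + WATER + p.c_term_delta

        # modification mass spanned by the prefix / suffix fragment
        nterm_mods = [p.placements[k] for k in mod_indices if k <= i]
        cterm_mods = [p.placements[k] for k in mod_indices if k > i]

        if mode == "ETD":
            pairs = (
                ("c", i, b_neutral + AMMONIA, nterm_mods),
                ("z", j, y_neutral - z_offset, cterm_mods),
            )
        else:
            pairs = (
                ("b", i, b_neutral, nterm_mods),
                ("y", j, y_neutral, cterm_mods),
            )

        for series, index, base_neutral, spanned in pairs:
            states: list[tuple[ModState, float]]
            if not spanned:
                states = [("unmodified", 0.0)]
            else:
                full = sum(sp.delta_mass for sp in spanned)
                states = [("intact", full)]
                if mode == "HCD":
                    remainders = [sp.phosphoribose_remainder for sp in spanned]
                    if all(r is not None for r in remainders):
                        states.append(("phosphoribose_remainder", sum(remainders)))
                    states.append(("full_loss", 0.0))
            for state, delta in states:
                neutral = base_neutral + delta
                for charge in range(1, max_charge + 1):
                    out.append(
                        FragmentIon(series, index, charge, state,
                                    mz_from_neutral(neutral, charge))
                    )

    if mode == "HCD":
        seen: set[str] = set()
        for sp in p.placements.values():
            if sp.name in seen:
                continue
            seen.add(sp.name)
            for diag_mz in sp.diagnostic_ions:
                out.append(FragmentIon("diag", 0, 1, "intact", diag_mz))
    return out
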