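"""In-silico tryptic digestion.

Two parameterizations matter downstream: a MaxQuant-style digest (up to 5
missed cleavages, minimum length 6, proline rule on) used for localization
searches of partial-FASP samples, and a Morpheus-style digest (3 missed
cleavages, no proline rule) used for localization-free searching.  Both are
expressed through :class:`DigestParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .masses import RESIDUE_MASS

__all__ = ["DigestParams", "MAXQUANT_STYLE", "MORPHEUS_STYLE", "digest"]


@dataclass(frozen=True)
class DigestParams:
    """Trypsin digestion parameters.

    ``proline_rule`` suppresses cleavage after K/R when the next residue is
    proline.  ``clip_nterm_met`` optionally also emits products with the
    protein's initiator methionine removed; off by default.
    """

    max_missed_cleavages: int = 5
    min_length: int = 6
    proline_rule: bool = True
    enzyme: str = "trypsin"
    clip_nterm_met: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.enzyme != "trypsin":
            raise ValueError(f"unsupported enzyme {self.enzyme!r}")


#: Digest used for site-localization searches (long peptides from partial FASP).
MAXQUANT_STYLE = DigestParams(max_missed_cleavages=5, min_length=6, proline_rule=True)
#: Digest used for localization-free searches.
MORPHEUS_STYLE = DigestParams(max_missed_cleavages=3, min_length=6, proline_rule=False)


def cleavage_sites(protein: str, proline_rule: bool) -> list[int]:
    """Positions (0-based, between residues i and i+1) where trypsin cuts."""
    sites = []
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and not (proline_rule and protein[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def digest(protein: str, params: DigestParams) -> list[tuple[str, int]]:
    """Tryptic peptides of a protein with their 1-based start coordinates.

    Cleaves after K or R (suppressed before P when the proline rule is on);
    returns every contiguous product with at most ``max_missed_cleavages``
    internal cleavage sites and length >= ``min_length``, de-duplicated by
    (sequence, start) and sorted by position.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - set(RESIDUE_MASS)
    if bad:
        raise ValueError(f"non-canonical residue(s) in protein: {sorted(bad)}")

    forms = [(protein, 0)]
    if params.clip_nterm_met and protein.startswith("M") and len(protein) > 1:
        forms.append((protein[1:], 1))

    out: set[tuple[str, int]] = set()
    for seq, offset in forms:
        bounds = [0] + cleavage_sites(seq, params.proline_rule) + [len(seq)]
        for a in range(len(bounds) - 1):
            for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(bounds))):
                pep = seq[bounds[a]:bounds[b]]
                if len(pep) >= params.min_length:
                    out.add((pep, bounds[a] + offset + 1))
    return sorted(out, key=lambda t: (t[1], len(t[0]), t[0]))
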