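"""Reference synthetic peptides used for validation experiments.

Both constructs carry an N-terminal acetyl and a C-terminal amide and end
in a GGA linker.  The histone H3 peptide covers H3 residues 1-21 with the
known serine acceptor at H3 position 10; the PARP-1 peptide covers residues
494-524 of the automodification region, containing the in vivo confirmed
acceptor serines S499, S507 and S519 (peptide positions 6, 14 and 26).  The
mutant variants replace the acceptor serines with alanine.
"""

from __future__ import annotations

from .masses import ModifiedPeptide, get_species

__all__ = [
    "H3_1_21_WT",
    "H3_1_21_S10A",
    "PARP1_494_524_WT",
    "PARP1_494_524_3SA",
    "PARP1_START",
    "h3_wt_peptide",
    "parp1_wt_peptide",
    "sequence_differences",
]

H3_1_21_WT = "ARTKQTARKSTGGKAPRKQLAGGA"
H3_1_21_S10A = "ARTKQTARKATGGKAPRKQLAGGA"
PARP1_494_524_WT = "APRGKSGAALSKKSKGQVKEEGINKSEKRMKGGA"
PARP1_494_524_3SA = "APRGKAGAALSKKAKGQVKEEGINKAEKRMKGGA"

#: Protein coordinate of the PARP-1 peptide's first residue.
PARP1_START = 494


def h3_wt_peptide(modified: bool = True) -> ModifiedPeptide:
    """The acetyl/amide H3(1-21) construct, optionally ADP-ribosylated on
    its single serine (H3 S10, peptide position 10)."""
    placements = {10: get_species("ADPr")} if modified else {}
    return ModifiedPeptide(H3_1_21_WT, n_term="acetyl", c_term="amide",
                           placements=placements)


def parp1_wt_peptide(site: int | None = None) -> ModifiedPeptide:
    """The acetyl/amide PARP-1(494-524) construct.

    ``site`` is a 1-based peptide position (6, 14 or 26 for the acceptor
    serines S499/S507/S519); None gives the unmodified construct.
    """
    placements = {site: get_species("ADPr")} if site else {}
    return ModifiedPeptide(PARP1_494_524_WT, n_term="acetyl", c_term="amide",
                           placements=placements)


def sequence_differences(a: str, b: str) -> list[int]:
    """1-based positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
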