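"""FASTA / MGF / TSV input and output.

FASTA parsing is delegated to Biopython after a light structural pre-check
that yields line-numbered errors; MGF reading and writing go through
pyteomics, with the fragmentation mode carried as a local ``FRAGMENTATION``
parameter in each block.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from pyteomics import mgf as _mgf

from .spectra import Spectrum

__all__ = ["read_fasta", "write_fasta", "read_mgf", "write_mgf", "write_tsv"]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a FASTA file into (accession, description, sequence) records.

    Sequences are upper-cased; stop-codon asterisks are stripped with a
    warning.  Structural problems (sequence data before the first header,
    a header with no sequence, an empty file) raise ``ValueError`` naming
    the offending line.
    """
    path = Path(path)
    _validate_fasta_structure(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"record {rec.id}: stripping '*' from sequence")
            seq = seq.replace("*", "")
        records.append((rec.id, rec.description, seq))
    return records


def _validate_fasta_structure(path: Path) -> None:
    n_headers = 0
    last_header_line = None
    has_seq_since_header = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if not has_seq_since_header:
                    raise ValueError(
                        f"{path}: header at line {last_header_line} has no sequence"
                    )
                n_headers += 1
                last_header_line = lineno
                has_seq_since_header = False
            else:
                if n_headers == 0:
                    raise ValueError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                has_seq_since_header = True
    if n_headers == 0:
        raise ValueError(f"{path}: no FASTA records found")
    if not has_seq_since_header:
        raise ValueError(f"{path}: header at line {last_header_line} has no sequence")


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, desc, seq in records:
            header = f">{desc}" if desc.startswith(acc) else f">{acc} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak-list file.

    Dialect: BEGIN IONS / END IONS blocks with TITLE, PEPMASS, signed
    CHARGE and "mz intensity" peak lines; a local FRAGMENTATION parameter
    (default HCD) selects the mode.  An unterminated block or a block
    without PEPMASS raises ``ValueError`` naming the spectrum.
    """
    spectra = []
    with _mgf.read(str(path), use_index=False) as reader:
        for n, entry in enumerate(reader):
            if entry is None:
                raise ValueError(f"{path}: spectrum block {n + 1} not terminated (missing END IONS?)")
            params = entry["params"]
            title = params.get("title", f"spectrum_{n + 1}")
            if "pepmass" not in params or params["pepmass"] is None:
                raise ValueError(f"{path}: spectrum {title!r} has no PEPMASS")
            charge = int(params["charge"][0]) if "charge" in params else 1
            mode = str(params.get("fragmentation", "HCD")).upper()
            spectra.append(
                Spectrum(
                    title=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    mode=mode,  # type: ignore[arg-type]
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips title, precursor, charge and peaks."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.round(s.mz, 6),
                "intensity array": np.round(s.intensity, 4),
                "params": {
                    "title": s.title,
                    "pepmass": (round(s.precursor_mz, 6), None),
                    "charge": s.precursor_charge,
                    "fragmentation": s.mode,
                },
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh)


def write_tsv(df, path: str | Path) -> None:
    """Uniform TSV convention: UTF-8, header row, '.' decimal, no index."""
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format="%.6g")
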