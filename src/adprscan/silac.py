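"""SILAC Lys8 pair handling: heavy/light ratios with explicit single-channel
states.

A heavy-lysine (13C6,15N2; +8.01420 Da per K) labelled channel shifts the
MS1 isotope cluster by ``#K * 8.01420 / z`` Th.  Where one channel gives no
signal at all — as for ADP-ribosylated peptides that vanish entirely in a
knockout background — no ratio is computed; such pairs are reported with a
sentinel state rather than a capped number, because a missing channel is a
finding, not a value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .masses import LYS8_DELTA, ModifiedPeptide

__all__ = [
    "IsotopePair",
    "RatioResult",
    "expected_heavy_shift",
    "pair_from_clusters",
    "compute_ratio",
    "ratio_intensity_table",
]

PairState = Literal["both", "heavy_only", "light_only", "neither"]


@dataclass(frozen=True)
class IsotopePair:
    """Summed light/heavy channel intensities for one peptide feature."""

    peptide: str
    light_intensity: float
    heavy_intensity: float

    def __post_init__(self) -> None:
        if self.light_intensity < 0 or self.heavy_intensity < 0:
            raise ValueError("channel intensities must be non-negative")

    @property
    def state(self) -> PairState:
        if self.light_intensity > 0 and self.heavy_intensity > 0:
            return "both"
        if self.heavy_intensity > 0:
            return "heavy_only"
        if self.light_intensity > 0:
            return "light_only"
        return "neither"


@dataclass(frozen=True)
class RatioResult:
    """H/L ratio of a pair, or the reason none exists."""

    ratio: float | None
    log2_ratio: float | None
    state: PairState

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def expected_heavy_shift(p: ModifiedPeptide | str, charge: int) -> float:
    """Expected light-to-heavy cluster spacing in Th: ``#K * 8.01420 / z``."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    seq = p if isinstance(p, str) else p.sequence
    n_k = seq.count("K")
    if n_k == 0:
        warnings.warn("peptide contains no lysine; heavy shift is zero")
    return n_k * LYS8_DELTA / charge


def pair_from_clusters(
    peptide: str, light_cluster: np.ndarray, heavy_cluster: np.ndarray
) -> IsotopePair:
    """Sum isotopologue intensities of simulated clusters into a pair.

    Summing over the cluster rather than reading a single isotopologue keeps
    the ratio robust to per-peak intensity noise.
    """
    light = float(np.asarray(light_cluster).reshape(-1, 2)[:, 1].sum()) \
        if len(light_cluster) else 0.0
    heavy = float(np.asarray(heavy_cluster).reshape(-1, 2)[:, 1].sum()) \
        if len(heavy_cluster) else 0.0
    return IsotopePair(peptide, light, heavy)


def compute_ratio(pair: IsotopePair) -> RatioResult:
    """H/L ratio of a pair, undefined when either channel is silent.

    Both channels present: returns heavy/light and its log2.  A silent
    channel propagates the pair state (``heavy_only`` / ``light_only`` /
    ``neither``) with no numeric ratio.
    """
    if pair.state != "both":
        return RatioResult(None, None, pair.state)
    ratio = pair.heavy_intensity / pair.light_intensity
    return RatioResult(ratio, math.log2(ratio), "both")


def ratio_intensity_table(pairs: Iterable[IsotopePair]) -> pd.DataFrame:
    """Ratio-versus-intensity table, one row per pair.

    Single-channel pairs are flagged by their state and never dropped;
    ``total_intensity`` is the light + heavy sum used for ratio-vs-intensity
    scatterplots.
    """
    rows = []
    for pair in pairs:
        res = compute_ratio(pair)
        rows.append(
            {
                "peptide": pair.peptide,
                "state": res.state,
                "ratio_h_over_l": res.ratio,
                "log2_ratio": res.log2_ratio,
                "light_intensity": pair.light_intensity,
                "heavy_intensity": pair.heavy_intensity,
                "total_intensity": pair.light_intensity + pair.heavy_intensity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peptide", "state", "ratio_h_over_l", "log2_ratio",
            "light_intensity", "heavy_intensity", "total_intensity",
        ],
    )


def filter_max_labeled(pairs: Iterable[IsotopePair], max_k: int = 7) -> list[IsotopePair]:
    """Drop pairs whose peptide exceeds the maximum labelled-residue count."""
    return [p for p in pairs if p.peptide.count("K") <= max_k]
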