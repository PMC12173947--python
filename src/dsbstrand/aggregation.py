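"""Anchor-centred profile matrices, windowed quantification and the
statistical conventions used throughout: trimmed-mean average profiles,
paired two-sided Wilcoxon signed-rank tests, and Tukey-style box
summaries (1.5*IQR whiskers, linear-interpolation quartiles)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coverage_io import StrandedTrack

__all__ = [
    "ProfileMatrix",
    "BoxSummary",
    "profile_matrix",
    "average_profile",
    "window_signal",
    "paired_wilcoxon",
    "box_stats",
]

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Anchors x fixed-width-bins mean-signal matrix.

    Columns span [anchor - halfwidth, anchor + halfwidth) and the anchor
    bin index is halfwidth // bin_size.
    """

    values: np.ndarray
    anchor_ids: list[str]
    halfwidth: int
    bin_size: int
    strand: str = "both"
    condition: str = ""

    @property
    def anchor_col(self) -> int:
        return self.halfwidth // self.bin_size


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def profile_matrix(
    track: StrandedTrack,
    anchors,
    halfwidth: int,
    bin_size: int | None = None,
    strand: str = "both",
    condition: str = "",
) -> ProfileMatrix:
    """Build an anchors x bins matrix of per-bin mean signal.

    ``anchors`` is a sequence of objects with .dsb_id/.chrom/.cut (or
    (id, chrom, pos) tuples).  Anchors whose window would cross a
    chromosome edge are dropped with a warning.
    """
    bin_size = bin_size or track.bin_size
    if halfwidth % bin_size:
        raise ValueError("halfwidth must be a multiple of bin_size")
    if bin_size % track.bin_size:
        raise ValueError("bin_size must be a multiple of the track bin size")
    agg = bin_size // track.bin_size
    nb = 2 * halfwidth // bin_size

    rows, ids = [], []
    for a in anchors:
        if hasattr(a, "dsb_id"):
            aid, chrom, pos = a.dsb_id, a.chrom, a.cut
        else:
            aid, chrom, pos = a
        c = pos // track.bin_size
        lo = c - halfwidth // track.bin_size
        hi = c + halfwidth // track.bin_size
        if lo < 0 or hi > track.n_bins(chrom):
            logger.warning("anchor %s too close to chromosome edge, dropped", aid)
            continue
        if strand == "both":
            vec = track.watson[chrom][lo:hi] + track.crick[chrom][lo:hi]
        else:
            vec = track.strand(strand)[chrom][lo:hi]
        rows.append(vec.reshape(nb, agg).mean(axis=1))
        ids.append(aid)
    values = np.array(rows) if rows else np.empty((0, nb))
    return ProfileMatrix(values, ids, halfwidth, bin_size, strand, condition)


def average_profile(matrix: ProfileMatrix | np.ndarray, trim_fraction: float = 0.0) -> np.ndarray:
    """Per-column trimmed mean across anchors (trim applied to both tails)."""
    values = matrix.values if isinstance(matrix, ProfileMatrix) else np.asarray(matrix)
    if values.size == 0:
        raise ValueError("empty profile matrix")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    if trim_fraction == 0.0:
        return values.mean(axis=0)
    return sps.trim_mean(values, proportiontocut=trim_fraction, axis=0)


def window_signal(
    track: StrandedTrack,
    anchors,
    halfwidth: int,
    strands: str = "both",
    how: str = "sum",
) -> dict[str, float]:
    """Per-anchor signal over [anchor - halfwidth, anchor + halfwidth).

    Summed by default (means differ only by the constant bin count); the
    selected strands are added together.
    """
    pm = profile_matrix(track, anchors, halfwidth, strand=strands)
    n_track_bins = pm.bin_size // track.bin_size
    out = {}
    for aid, row in zip(pm.anchor_ids, pm.values):
        total = float(row.sum()) * n_track_bins
        out[aid] = total if how == "sum" else total / (len(row) * n_track_bins)
    return out


def paired_wilcoxon(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p value.

    Zero differences are dropped (classic signed-rank); the exact null
    distribution is used for n <= 25 when the non-zero |differences| are
    tie-free, otherwise the normal approximation with tie and continuity
    correction.  All differences zero returns p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("a and b must be equal-length 1-D arrays, n >= 1")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = np.abs(d)
    exact = d.size <= 25 and np.unique(ranks).size == ranks.size
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=not exact, zero_method="wilcox")
    return float(res.pvalue)


def box_stats(values) -> BoxSummary:
    """Tukey box summary: interpolated quartiles, 1.5*IQR whisker fences.

    Whiskers are the most extreme observations inside
    [q1 - 1.5*IQR, q3 + 1.5*IQR]; points strictly outside are outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in outliers),
    )
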