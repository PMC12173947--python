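"""Damage-aware normalization.

DNA damage represses transcription globally, so naive total-count scaling
of RNAPII (or similar) coverage hides the genome-wide signal loss.  The
TSS-metagene scale factor quantifies that global change on a fixed
180-bin metagene layout — 40 upstream 50-bp flank bins, 100
length-proportional gene-body bins, 40 downstream 50-bp flank bins — as
the ratio of mean damaged/undamaged signal over the bins straddling the
TSS (bins 30–50, 1-based).  Dividing the damaged track by the factor
equalizes genome-wide TSS occupancy so break-local changes stand out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coverage_io import StrandedTrack

__all__ = [
    "MetageneMatrix",
    "ScaleFactor",
    "metagene_matrix",
    "tss_scale_factor",
    "apply_scale",
    "log2_ratio",
    "N_FLANK_BINS",
    "N_BODY_BINS",
    "FLANK_BIN_BP",
]

logger = logging.getLogger(__name__)

N_FLANK_BINS = 40
N_BODY_BINS = 100
FLANK_BIN_BP = 50
N_TOTAL_BINS = 2 * N_FLANK_BINS + N_BODY_BINS  # 180


class CoordinateError(ValueError):
    pass


@dataclass
class MetageneMatrix:
    """Genes x 180 bins mean-signal matrix on the fixed metagene layout."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_TOTAL_BINS:
            raise ValueError(f"metagene matrix must have {N_TOTAL_BINS} columns")


@dataclass(frozen=True)
class ScaleFactor:
    value: float
    kind: str  # tss_metagene | spike_in | total_count
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("scale factor must be > 0")


def _mean_over(vec: np.ndarray, start: float, end: float, bin_size: int) -> float:
    """Base-weighted mean of a binned vector over genomic [start, end)."""
    if end <= start:
        return 0.0
    first = int(start // bin_size)
    last = int(np.ceil(end / bin_size))
    total = 0.0
    for b in range(first, last):
        lo = max(start, b * bin_size)
        hi = min(end, (b + 1) * bin_size)
        if hi > lo:
            total += vec[b] * (hi - lo)
    return total / (end - start)


def metagene_matrix(track: StrandedTrack, genes, strand: str = "both") -> MetageneMatrix:
    """Per-gene metagene profile on the 180-bin layout.

    Bin 1 is always the most-upstream flank bin: rows of '-' genes are
    computed right-to-left so the layout reads 5'->3' along each gene.
    Genes shorter than 100 bases are skipped with a warning (their body
    bins would be sub-base).  ``strand`` selects watson, crick or their sum.
    """
    rows, ids = [], []
    for g in genes:
        if g.length < N_BODY_BINS:
            logger.warning("gene %s shorter than %d bp, skipped", g.gene_id, N_BODY_BINS)
            continue
        if strand == "both":
            vec = track.watson[g.chrom] + track.crick[g.chrom]
        else:
            vec = track.strand(strand)[g.chrom]
        chrom_len = len(vec) * track.bin_size
        lo, hi = g.span
        if lo - 2000 < 0 or hi + 2000 > chrom_len:
            raise CoordinateError(f"gene {g.gene_id} flanks extend beyond chromosome")

        row = np.empty(N_TOTAL_BINS)
        body_w = g.length / N_BODY_BINS
        if g.strand == "+":
            edges_up = [lo - 2000 + i * FLANK_BIN_BP for i in range(N_FLANK_BINS + 1)]
            edges_body = [lo + i * body_w for i in range(N_BODY_BINS + 1)]
            edges_dn = [hi + i * FLANK_BIN_BP for i in range(N_FLANK_BINS + 1)]
            edges = edges_up[:-1] + edges_body[:-1] + edges_dn
            for j in range(N_TOTAL_BINS):
                row[j] = _mean_over(vec, edges[j], edges[j + 1], track.bin_size)
        else:
            # '-' gene: walk the genome right-to-left
            edges_up = [hi + 2000 - i * FLANK_BIN_BP for i in range(N_FLANK_BINS + 1)]
            edges_body = [hi - i * body_w for i in range(N_BODY_BINS + 1)]
            edges_dn = [lo - i * FLANK_BIN_BP for i in range(N_FLANK_BINS + 1)]
            edges = edges_up[:-1] + edges_body[:-1] + edges_dn
            for j in range(N_TOTAL_BINS):
                row[j] = _mean_over(vec, edges[j + 1], edges[j], track.bin_size)
        rows.append(row)
        ids.append(g.gene_id)
    return MetageneMatrix(np.array(rows) if rows else np.empty((0, N_TOTAL_BINS)), ids)


def tss_scale_factor(
    matrix_plus: MetageneMatrix,
    matrix_minus: MetageneMatrix,
    tss_bins: tuple[int, int] = (30, 50),
) -> ScaleFactor:
    """Global-repression scale factor from TSS-proximal metagene bins.

    Mean signal over genes and 1-based bins ``tss_bins`` (inclusive) in the
    damaged condition divided by the same mean in the undamaged condition.
    Bins 30–50 of the 180-bin layout cover −550 bp to +10% of gene body
    around the TSS.
    """
    if matrix_plus.gene_ids != matrix_minus.gene_ids:
        raise ValueError("both matrices must cover the same gene set in order")
    lo, hi = tss_bins
    cols = slice(lo - 1, hi)  # 1-based inclusive
    num = float(matrix_plus.values[:, cols].mean())
    den = float(matrix_minus.values[:, cols].mean())
    if den == 0.0:
        raise ZeroDivisionError("undamaged TSS-window mean signal is zero")
    return ScaleFactor(
        num / den,
        kind="tss_metagene",
        provenance=f"mean(+DSB bins {lo}-{hi}) / mean(-DSB bins {lo}-{hi}); "
        "applied by dividing the +DSB track",
    )


def apply_scale(track: StrandedTrack, factor: ScaleFactor) -> StrandedTrack:
    """Divide every value by ``factor.value``; provenance is recorded.

    Division (rather than multiplication) means a tss_metagene factor < 1
    — global repression — lifts the damaged track back to the undamaged
    genome-wide baseline, leaving break-local changes visible.
    """
    out = track.copy()
    for vecs in (out.watson, out.crick):
        for chrom in vecs:
            vecs[chrom] = vecs[chrom] / factor.value
    out.norm = factor.kind
    out.norm_factor = factor.value
    return out


def log2_ratio(track_a: StrandedTrack, track_b: StrandedTrack,
               pseudocount: float = 1.0) -> StrandedTrack:
    """Per-bin, per-strand signed log2((a + pc) / (b + pc)) track."""
    if track_a.bin_size != track_b.bin_size:
        raise ValueError("tracks must share the binning")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = track_a.copy()
    for sname in ("watson", "crick"):
        va, vb = track_a.strand(sname), track_b.strand(sname)
        for chrom in va:
            a, b = va[chrom], vb[chrom]
            if (a < 0).any() or (b < 0).any():
                raise ValueError("log2_ratio requires non-negative inputs")
            out.strand(sname)[chrom] = np.log2((a + pseudocount) / (b + pseudocount))
    out.norm = "log2_ratio"
    out.norm_factor = pseudocount
    return out
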