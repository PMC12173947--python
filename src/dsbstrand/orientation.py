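"""Strand-orientation transforms around double-strand breaks.

Resection degrades the 5'-terminated strand at each DSB end, leaving a
3' single-stranded overhang.  Reading the reference left to right, the
right-hand fragment's Watson strand is 5'-terminated at the break (so it
is the resected strand there) and its Crick strand is the 3' overhang;
the assignment mirrors on the left fragment.  These transforms re-index
stranded signal into that break-centric frame, orient profile matrices by
gene direction (template vs nontemplate strand) or by which side of the
break carries the signal, and rank break sites by damage-induced gain.

All transforms only re-index values (they are involutive and
signal-conserving); none of them rescales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage_io import StrandedTrack

__all__ = [
    "SideProfilePair",
    "template_strand",
    "split_by_resection",
    "orient_by_gene",
    "orient_by_dominant_side",
    "rank_hybrid_sites",
]


class CoordinateError(ValueError):
    pass


@dataclass
class SideProfilePair:
    """Signal on both sides of a cut for one strand, bins ordered away
    from the break (bin 0 abuts the cut; the cut bin belongs to the right
    side under the half-open convention)."""

    left: np.ndarray
    right: np.ndarray
    strand: str
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right must have equal length")


def template_strand(gene_strand: str) -> str:
    """Template strand of a gene: Crick for '+' genes, Watson for '-'.

    The template is the strand complementary to the transcript, so R-loops
    formed by nascent (or pre-existing) RNA of a forward-orientation gene
    sit on the Crick strand.
    """
    if gene_strand == "+":
        return "crick"
    if gene_strand == "-":
        return "watson"
    raise ValueError(f"gene strand must be '+' or '-', got {gene_strand!r}")


def _side_vectors(track: StrandedTrack, chrom: str, cut: int, halfwidth: int):
    bs = track.bin_size
    if cut % bs or halfwidth % bs:
        raise ValueError("cut and halfwidth must be multiples of bin_size")
    nb = halfwidth // bs
    c = cut // bs
    if c - nb < 0 or c + nb > track.n_bins(chrom):
        raise CoordinateError(f"window ±{halfwidth} around {chrom}:{cut} exceeds chromosome")
    w, k = track.watson[chrom], track.crick[chrom]
    # left vectors mirrored so distance increases away from the break
    return (
        w[c - nb : c][::-1].copy(),
        w[c : c + nb].copy(),
        k[c - nb : c][::-1].copy(),
        k[c : c + nb].copy(),
    )


def split_by_resection(
    watson_left: np.ndarray,
    watson_right: np.ndarray,
    crick_left: np.ndarray,
    crick_right: np.ndarray,
    combine: str = "sum",
) -> dict[str, np.ndarray]:
    """Combine the two break sides into overhang-strand and resected-strand
    profiles indexed by distance from the cut.

    resected(d) = combine(crick_left(d), watson_right(d)) — the two
    5'-terminated strands; overhang(d) = combine(watson_left(d),
    crick_right(d)) — the two 3' overhangs.  Inputs are side vectors with
    d increasing away from the break (left already mirrored).
    """
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    op = np.add if combine == "sum" else lambda a, b: (a + b) / 2.0
    return {
        "resected": op(crick_left, watson_right),
        "overhang": op(watson_left, crick_right),
    }


def split_track_by_resection(
    track: StrandedTrack,
    chrom: str,
    cut: int,
    halfwidth: int,
    combine: str = "sum",
) -> dict[str, np.ndarray]:
    """:func:`split_by_resection` applied to a track window around a cut."""
    wl, wr, kl, kr = _side_vectors(track, chrom, cut, halfwidth)
    return split_by_resection(wl, wr, kl, kr, combine=combine)


def side_profiles(
    track: StrandedTrack, chrom: str, cut: int, halfwidth: int
) -> tuple[SideProfilePair, SideProfilePair]:
    """Extract (watson, crick) side-profile pairs around a cut."""
    wl, wr, kl, kr = _side_vectors(track, chrom, cut, halfwidth)
    bs = track.bin_size
    return (
        SideProfilePair(wl, wr, "watson", bs),
        SideProfilePair(kl, kr, "crick", bs),
    )


def orient_by_gene(
    matrix_watson: np.ndarray,
    matrix_crick: np.ndarray,
    gene_strands: list[str],
) -> dict[str, np.ndarray]:
    """Re-index per-gene profile rows into template/nontemplate matrices.

    Rows of '-' genes are reversed in bin order and their Watson/Crick
    labels swapped, so every row of the ``template`` matrix reads the
    gene's template strand 5'->3' along the gene.  Applying the transform
    twice returns the inputs (involution).
    """
    mw = np.asarray(matrix_watson, dtype=float)
    mc = np.asarray(matrix_crick, dtype=float)
    if mw.shape != mc.shape:
        raise ValueError("watson and crick matrices must have the same shape")
    if len(gene_strands) != mw.shape[0]:
        raise ValueError("one gene strand required per matrix row")
    template = np.empty_like(mc)
    nontemplate = np.empty_like(mw)
    for i, s in enumerate(gene_strands):
        if s == "+":
            template[i] = mc[i]
            nontemplate[i] = mw[i]
        elif s == "-":
            template[i] = mw[i, ::-1]
            nontemplate[i] = mc[i, ::-1]
        else:
            raise ValueError(f"bad strand {s!r} at row {i}")
    return {"template": template, "nontemplate": nontemplate}


def orient_by_dominant_side(
    pairs_by_dsb: dict[str, tuple[SideProfilePair, SideProfilePair]],
) -> tuple[dict[str, bool], np.ndarray]:
    """Flip each DSB profile so its signal-dominant side is on the right.

    For each DSB the summed signal over both strands on the right side
    (cut bin included) is compared to the left side; if the left wins the
    profile is flipped (ties: no flip).  Returns per-DSB flip flags and the
    oriented matrix whose rows run left flank -> cut -> right flank with
    both strands summed.
    """
    flips: dict[str, bool] = {}
    rows = []
    for dsb_id in sorted(pairs_by_dsb):
        pw, pc = pairs_by_dsb[dsb_id]
        left = float(pw.left.sum() + pc.left.sum())
        right = float(pw.right.sum() + pc.right.sum())
        flip = left > right
        flips[dsb_id] = flip
        l = pw.left + pc.left
        r = pw.right + pc.right
        if flip:
            l, r = r, l
        rows.append(np.concatenate([l[::-1], r]))
    return flips, np.array(rows) if rows else np.empty((0, 0))


def rank_hybrid_sites(
    track_plus: StrandedTrack,
    track_minus: StrandedTrack,
    sites,
    halfwidth: int,
    k: int,
) -> list[str]:
    """Rank DSBs by damage-induced signal gain and return the top k ids.

    Score = windowed (+DSB − −DSB) signal summed over both strands; ties
    broken by dsb_id for determinism.
    """
    if k > len(sites):
        raise ValueError(f"k={k} exceeds number of sites ({len(sites)})")
    if track_plus.bin_size != track_minus.bin_size:
        raise ValueError("both conditions must share the binning")
    scores = []
    for site in sites:
        gain = 0.0
        for track, sign in ((track_plus, +1.0), (track_minus, -1.0)):
            wl, wr, kl, kr = _side_vectors(track, site.chrom, site.cut, halfwidth)
            gain += sign * float(wl.sum() + wr.sum() + kl.sum() + kr.sum())
        scores.append((-gain, site.dsb_id))
    scores.sort()
    return [dsb_id for _, dsb_id in scores[:k]]
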