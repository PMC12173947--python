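"""Stranded coverage tracks: binning, bedGraph I/O, strand routing, spike-in.

The canonical in-memory object is :class:`StrandedTrack` — per-chromosome
binned coverage with separate Watson (reference/plus) and Crick (reverse
complement) vectors plus a normalization provenance tag.  bedGraph is the
canonical on-disk form (one file per strand); paired-end fragments are
routed to strands with the SAM-flag bitmask rule used for strand-specific
libraries (80/160 reverse, 96/144 forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "StrandedTrack",
    "FragmentRecord",
    "fragment_strand_from_flag",
    "bin_fragments",
    "spike_in_factor",
    "load_stranded_track",
    "write_stranded_track",
    "read_bedgraph",
    "write_bedgraph",
    "load_chrom_sizes",
]

REVERSE_MASKS = (80, 160)
FORWARD_MASKS = (96, 144)


class CoordinateError(ValueError):
    pass


class FormatError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    flag: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"fragment start must be < end ({self.start}, {self.end})")


@dataclass
class StrandedTrack:
    """Binned coverage with separate Watson and Crick vectors per chromosome.

    ``norm`` records what normalization has been applied: ``raw``,
    ``total_count``, ``spike_in`` or ``tss_scaled``, with the factor value
    in ``norm_factor``.
    """

    bin_size: int
    watson: dict[str, np.ndarray] = field(default_factory=dict)
    crick: dict[str, np.ndarray] = field(default_factory=dict)
    norm: str = "raw"
    norm_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        for chrom in self.watson:
            if chrom in self.crick and len(self.watson[chrom]) != len(self.crick[chrom]):
                raise ValueError(f"watson/crick length mismatch on {chrom}")

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], bin_size: int) -> "StrandedTrack":
        n = {c: -(-size // bin_size) for c, size in chrom_sizes.items()}
        return cls(
            bin_size=bin_size,
            watson={c: np.zeros(k) for c, k in n.items()},
            crick={c: np.zeros(k) for c, k in n.items()},
        )

    @property
    def chroms(self) -> list[str]:
        return list(self.watson)

    def n_bins(self, chrom: str) -> int:
        return len(self.watson[chrom])

    def strand(self, name: str) -> dict[str, np.ndarray]:
        if name == "watson":
            return self.watson
        if name == "crick":
            return self.crick
        raise ValueError(f"unknown strand {name!r}")

    def total(self, strand: str | None = None) -> float:
        tot = 0.0
        if strand in (None, "watson", "both"):
            tot += sum(float(v.sum()) for v in self.watson.values())
        if strand in (None, "crick", "both"):
            tot += sum(float(v.sum()) for v in self.crick.values())
        return tot

    def copy(self) -> "StrandedTrack":
        return StrandedTrack(
            bin_size=self.bin_size,
            watson={c: v.copy() for c, v in self.watson.items()},
            crick={c: v.copy() for c, v in self.crick.items()},
            norm=self.norm,
            norm_factor=self.norm_factor,
        )


def fragment_strand_from_flag(flag: int) -> str:
    """Assign a fragment strand from its SAM flag word by bitmask containment.

    Flags containing mask 80 or 160 are reverse fragments; flags containing
    96 or 144 are forward fragments; anything else is unassigned.  The
    reverse masks are tested first, mirroring strand-specific-library flag
    filtering where mate/orientation bit pairs identify the template strand.
    """
    if flag < 0:
        raise ValueError("flag must be >= 0")
    if any((flag & m) == m for m in REVERSE_MASKS):
        return "reverse"
    if any((flag & m) == m for m in FORWARD_MASKS):
        return "forward"
    return "unassigned"


def bin_fragments(
    fragments: list[FragmentRecord],
    chrom_sizes: dict[str, int],
    bin_size: int,
    strand_invert: bool = False,
) -> StrandedTrack:
    """Accumulate fragment overlap lengths into a stranded binned track.

    Each fragment adds its per-bin overlap (in bases) to the vector of its
    strand, so total binned signal equals total covered bases exactly.
    Forward fragments go to Watson and reverse to Crick unless
    ``strand_invert`` (the library-chemistry switch) flips the routing;
    unassigned fragments are dropped.
    """
    track = StrandedTrack.zeros(chrom_sizes, bin_size)
    for frag in fragments:
        if frag.chrom not in chrom_sizes:
            raise CoordinateError(f"fragment on undeclared chromosome {frag.chrom}")
        if frag.end > chrom_sizes[frag.chrom] or frag.start < 0:
            raise CoordinateError(
                f"fragment {frag.chrom}:{frag.start}-{frag.end} beyond chromosome"
            )
        orient = fragment_strand_from_flag(frag.flag)
        if orient == "unassigned":
            continue
        to_crick = (orient == "reverse") != strand_invert
        vec = (track.crick if to_crick else track.watson)[frag.chrom]
        first, last = frag.start // bin_size, (frag.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(frag.start, b * bin_size)
            hi = min(frag.end, (b + 1) * bin_size)
            vec[b] += hi - lo
    return track


def spike_in_factor(n_spike_reads: int) -> float:
    """Spike-in scaling factor: 1,000,000 / reads mapped to the spike genome."""
    if n_spike_reads <= 0:
        raise ValueError("spike-in read count must be > 0")
    return 1_000_000 / n_spike_reads


# ---------------------------------------------------------------------------
# bedGraph I/O


def load_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(r.chrom): int(r.size) for r in df.itertuples(index=False)}


def read_bedgraph(path, chrom_sizes: dict[str, int], bin_size: int) -> dict[str, np.ndarray]:
    """Read a 4-column bedGraph into per-chromosome bin vectors.

    Interval boundaries must align to ``bin_size``; overlapping intervals
    are a format error.
    """
    vecs = {c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()}
    seen_until: dict[str, int] = {c: 0 for c in chrom_sizes}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in vecs:
            raise CoordinateError(f"bedGraph chromosome {chrom} not in chrom.sizes")
        start, end = int(row.start), int(row.end)
        if start < seen_until[chrom]:
            raise FormatError(f"overlapping bedGraph intervals on {chrom} at {start}")
        seen_until[chrom] = end
        if start % bin_size or (end % bin_size and end != chrom_sizes[chrom]):
            raise FormatError(
                f"interval {chrom}:{start}-{end} not aligned to bin size {bin_size}"
            )
        vecs[chrom][start // bin_size : -(-end // bin_size)] = float(row.value)
    return vecs


def write_bedgraph(vecs: dict[str, np.ndarray], bin_size: int,
                   chrom_sizes: dict[str, int], path) -> None:
    """Write bin vectors as bedGraph, merging runs of equal value and
    omitting zero runs."""
    with open(path, "w") as fh:
        for chrom, vec in vecs.items():
            size = chrom_sizes[chrom]
            run_start = 0
            run_val = vec[0] if len(vec) else 0.0
            for i in range(1, len(vec) + 1):
                v = vec[i] if i < len(vec) else None
                if v is None or v != run_val:
                    if run_val != 0.0:
                        s = run_start * bin_size
                        e = min(i * bin_size, size)
                        fh.write(f"{chrom}\t{s}\t{e}\t{run_val:g}\n")
                    run_start, run_val = i, v
            _ = run_val


def load_stranded_track(
    watson_path, crick_path, bin_size: int, chrom_sizes: dict[str, int],
    norm: str = "raw", norm_factor: float = 1.0,
) -> StrandedTrack:
    return StrandedTrack(
        bin_size=bin_size,
        watson=read_bedgraph(watson_path, chrom_sizes, bin_size),
        crick=read_bedgraph(crick_path, chrom_sizes, bin_size),
        norm=norm,
        norm_factor=norm_factor,
    )


def write_stranded_track(track: StrandedTrack, prefix,
                         chrom_sizes: dict[str, int]) -> tuple[str, str]:
    """Write one bedGraph per strand; returns the two file paths."""
    wpath = f"{prefix}.watson.bedgraph"
    cpath = f"{prefix}.crick.bedgraph"
    write_bedgraph(track.watson, track.bin_size, chrom_sizes, wpath)
    write_bedgraph(track.crick, track.bin_size, chrom_sizes, cpath)
    return wpath, cpath
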