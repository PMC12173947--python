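"""DSB site annotation against a gene model.

Double-strand breaks induced at sequence-specific sites (e.g. AsiSI
restriction sites) are classified by their transcriptional context:
transcription-coupled DSBs (TC-DSBs) fall within an actively transcribed
gene body or within 1 kb upstream of its TSS, everything else is a silent
DSB.  TC-DSBs are further split into promoter, 5' region and gene-body
breaks, and intragenic breaks into exonic and intronic.  A break that
qualifies against two genes (overlapping genes, or one gene body plus a
neighbouring promoter) keeps both annotations.

Coordinates are 0-based half-open throughout; a DSB ``cut`` at position p
denotes the phosphodiester bond between p-1 and p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "DSBSite",
    "DSBAnnotation",
    "CategoryCounts",
    "classify_dsb",
    "classify_all",
    "summarize_categories",
    "select_control_genes",
    "load_gene_table",
    "load_dsb_bed",
    "write_annotations",
    "load_annotations",
]


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene: genomic span, strand, exon chain and expression.

    ``tss``/``tes`` are stored in transcription order: for a '+' gene
    tss < tes, for a '-' gene tss > tes.  ``expression`` is an arbitrary
    non-negative activity measure; 0 means transcriptionally silent.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...] = ()
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"'+' gene {self.gene_id}: tss must be < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"'-' gene {self.gene_id}: tss must be > tes")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s < e <= hi):
                raise ValueError(
                    f"exon [{s},{e}) outside gene span [{lo},{hi}) of {self.gene_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (left, right) half-open span, strand-agnostic."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos < hi

    def tss_distance(self, pos: int) -> int:
        """Signed distance from TSS in transcription direction (downstream > 0)."""
        d = pos - self.tss
        return d if self.strand == "+" else -d

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass(frozen=True)
class DSBSite:
    """A cut coordinate with an optional cleavage efficiency in [0, 1]."""

    dsb_id: str
    chrom: str
    cut: int
    cleavage: float | None = None

    def __post_init__(self) -> None:
        if self.cleavage is not None and not 0.0 <= self.cleavage <= 1.0:
            raise ValueError("cleavage must be in [0, 1]")


POSITION_CLASSES = ("promoter", "five_prime", "gene_body", "intergenic")
EXON_CLASSES = ("exonic", "intronic", "not_applicable")


@dataclass(frozen=True)
class DSBAnnotation:
    dsb_id: str
    gene_id: str | None
    tc: bool
    position_class: str
    exon_class: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.position_class not in POSITION_CLASSES:
            raise ValueError(f"bad position_class {self.position_class!r}")
        if self.exon_class not in EXON_CLASSES:
            raise ValueError(f"bad exon_class {self.exon_class!r}")


@dataclass
class CategoryCounts:
    n_total: int = 0
    n_tc: int = 0
    n_silent: int = 0
    n_promoter: int = 0
    n_five_prime: int = 0
    n_gene_body: int = 0
    n_exonic: int = 0
    n_intronic: int = 0
    n_dual: int = 0
    n_within_gene: int = 0
    pct_within_1kb_tss: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def classify_dsb(
    dsb: DSBSite,
    genes: list[GeneModel],
    window: int = 1000,
    expression_threshold: float = 0.0,
    chrom_sizes: dict[str, int] | None = None,
) -> list[DSBAnnotation]:
    """Classify one DSB against a gene set.

    A gene qualifies when it is expressed (expression > threshold) and the
    cut either lies inside its body or within ``window`` bp upstream of its
    TSS.  Qualifying annotations are ranked by distance to the TSS and at
    most two are kept (a break between two genes is associated with both).
    Classes:

    * ``promoter`` — within ``window`` bp upstream of the TSS, outside the body
    * ``five_prime`` — inside the body, within ``window`` bp downstream of the TSS
    * ``gene_body`` — inside the body, more than ``window`` bp from the TSS
    * ``intergenic`` — no qualifying gene (also covers silent-gene breaks)

    Exon/intron labels are assigned only to intragenic annotations.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if chrom_sizes is not None:
        size = chrom_sizes.get(dsb.chrom)
        if size is None or not 0 <= dsb.cut < size:
            raise CoordinateError(
                f"cut {dsb.chrom}:{dsb.cut} outside declared chromosomes"
            )

    hits: list[tuple[int, DSBAnnotation]] = []
    for g in genes:
        if g.chrom != dsb.chrom or g.expression <= expression_threshold:
            continue
        d = g.tss_distance(dsb.cut)
        inside = g.contains(dsb.cut)
        if inside and d >= 0:
            if d < window:
                pos_class = "five_prime"
            else:
                pos_class = "gene_body"
            exon_class = "exonic" if g.in_exon(dsb.cut) else "intronic"
        elif -window < d < 0 and not inside:
            pos_class = "promoter"
            exon_class = "not_applicable"
        else:
            continue
        hits.append(
            (
                abs(d),
                DSBAnnotation(dsb.dsb_id, g.gene_id, True, pos_class, exon_class),
            )
        )

    if not hits:
        return [DSBAnnotation(dsb.dsb_id, None, False, "intergenic")]
    hits.sort(key=lambda t: (t[0], t[1].gene_id))
    return [ann for _, ann in hits[:2]]


def classify_all(
    dsbs: list[DSBSite],
    genes: list[GeneModel],
    window: int = 1000,
    **kwargs,
) -> list[DSBAnnotation]:
    out: list[DSBAnnotation] = []
    for dsb in dsbs:
        out.extend(classify_dsb(dsb, genes, window=window, **kwargs))
    return out


class CoordinateError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def summarize_categories(annotations: list[DSBAnnotation]) -> CategoryCounts:
    """Tally annotation categories over DSB sites.

    Site-level counts (``n_total``, ``n_tc``, ``n_silent``, ``n_dual``)
    count distinct DSBs; positional and exon/intron counts tally
    annotations, so a dual-annotated site contributes twice there.
    ``pct_within_1kb_tss`` is the integer-rounded percentage of TC
    annotations lying within the TSS window (promoter or 5') among all
    positionally classified TC annotations.
    """
    seen: set[tuple[str, str | None]] = set()
    for a in annotations:
        key = (a.dsb_id, a.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate annotation for {key}")
        seen.add(key)

    c = CategoryCounts()
    by_site: dict[str, list[DSBAnnotation]] = {}
    for a in annotations:
        by_site.setdefault(a.dsb_id, []).append(a)

    c.n_total = len(by_site)
    for anns in by_site.values():
        if any(a.tc for a in anns):
            c.n_tc += 1
        else:
            c.n_silent += 1
        if len(anns) > 1:
            c.n_dual += 1

    for a in annotations:
        if a.position_class == "promoter":
            c.n_promoter += 1
        elif a.position_class == "five_prime":
            c.n_five_prime += 1
        elif a.position_class == "gene_body":
            c.n_gene_body += 1
        if a.exon_class == "exonic":
            c.n_exonic += 1
        elif a.exon_class == "intronic":
            c.n_intronic += 1
    c.n_within_gene = c.n_exonic + c.n_intronic

    denom = c.n_promoter + c.n_five_prime + c.n_gene_body
    if denom:
        c.pct_within_1kb_tss = round(100.0 * (c.n_promoter + c.n_five_prime) / denom)
    return c


class QuintileShortfallError(RuntimeError):
    """Raised when an expression quintile cannot be filled from the pool."""


def select_control_genes(
    damaged: list[GeneModel],
    pool: list[GeneModel],
    cut_sites: list[DSBSite],
    excluded_ids: set[str] = frozenset(),
    exclusion_radius: int = 1_000_000,
    n_bins: int = 5,
    seed: int = 0,
) -> list[str]:
    """Expression-matched control-gene selection.

    Damaged genes are binned into ``n_bins`` expression groups at their own
    empirical quantile edges, and the same number of controls per bin is
    sampled (without replacement) from the pool after removing genes within
    ``exclusion_radius`` of any cut site and genes in ``excluded_ids``
    (e.g. damage-responsive differentially expressed genes).
    """
    if not damaged:
        return []
    rng = np.random.default_rng(seed)

    damaged_ids = {g.gene_id for g in damaged}
    eligible = []
    for g in sorted(pool, key=lambda g: g.gene_id):
        if g.gene_id in excluded_ids or g.gene_id in damaged_ids:
            continue
        lo, hi = g.span
        near = any(
            s.chrom == g.chrom and (lo - exclusion_radius) <= s.cut < (hi + exclusion_radius)
            for s in cut_sites
        )
        if not near:
            eligible.append(g)

    dmg_expr = np.array([g.expression for g in damaged], dtype=float)
    edges = np.quantile(dmg_expr, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf

    def bin_of(x: float) -> int:
        # right-closed bins except the first; ties resolve to the lower bin
        return int(np.searchsorted(edges, x, side="left")) - 1

    demand = np.zeros(n_bins, dtype=int)
    for g in sorted(damaged, key=lambda g: g.gene_id):
        demand[bin_of(g.expression)] += 1

    chosen: list[str] = []
    for b in range(n_bins):
        candidates = [g.gene_id for g in eligible if bin_of(g.expression) == b]
        if len(candidates) < demand[b]:
            raise QuintileShortfallError(
                f"expression bin {b + 1}/{n_bins}: need {demand[b]} controls, "
                f"only {len(candidates)} eligible pool genes"
            )
        take = rng.choice(len(candidates), size=demand[b], replace=False)
        chosen.extend(candidates[i] for i in sorted(take))
    return chosen


# ---------------------------------------------------------------------------
# tabular I/O

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes", "exons", "expression"]


def load_gene_table(path) -> list[GeneModel]:
    """Read a tab-separated gene table.

    Columns: gene_id, chrom, strand, tss, tes, exons, expression.  ``exons``
    is a comma-separated list of ``start-end`` half-open intervals, or ``.``
    for none.
    """
    df = pd.read_csv(path, sep="\t", dtype={"exons": str})
    genes = []
    for row in df.itertuples(index=False):
        exons: tuple[tuple[int, int], ...] = ()
        if isinstance(row.exons, str) and row.exons not in (".", ""):
            exons = tuple(
                (int(s), int(e))
                for s, e in (iv.split("-") for iv in row.exons.split(","))
            )
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=int(row.tss),
                tes=int(row.tes),
                exons=exons,
                expression=float(row.expression),
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        exons = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
        rows.append((g.gene_id, g.chrom, g.strand, g.tss, g.tes, exons, g.expression))
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_dsb_bed(path) -> list[DSBSite]:
    """Read DSB sites from 6-column BED (name=dsb_id, score=cleavage*1000)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        comment="#",
    )
    sites = []
    for row in df.itertuples(index=False):
        cleavage = None
        if not pd.isna(row.score) and row.score != ".":
            cleavage = float(row.score) / 1000.0
        sites.append(DSBSite(str(row.name), str(row.chrom), int(row.start), cleavage))
    return sites


def write_dsb_bed(sites: list[DSBSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            score = "." if s.cleavage is None else f"{s.cleavage * 1000:.0f}"
            fh.write(f"{s.chrom}\t{s.cut}\t{s.cut + 1}\t{s.dsb_id}\t{score}\t.\n")


ANNOTATION_COLUMNS = ["dsb_id", "gene_id", "tc", "position_class", "exon_class"]


def write_annotations(annotations: list[DSBAnnotation], path) -> None:
    rows = [
        (a.dsb_id, a.gene_id if a.gene_id is not None else ".",
         str(a.tc).lower(), a.position_class, a.exon_class)
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def load_annotations(path) -> list[DSBAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DSBAnnotation(
                dsb_id=str(row.dsb_id),
                gene_id=None if row.gene_id in (".", "", None) else str(row.gene_id),
                tc=str(row.tc).lower() in ("true", "1", "yes"),
                position_class=str(row.position_class),
                exon_class=str(row.exon_class),
            )
        )
    return out
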