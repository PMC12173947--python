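"""Seeded synthetic-data generator for the whole pipeline.

Generates a toy genome (non-overlapping genes with exon chains, strands
and expression levels), places double-strand breaks in requested
transcriptional contexts, and writes stranded coverage tracks whose
statistical structure mirrors the assays the pipeline analyses:

* qDRIP-seq — strand-specific R-loop signal: a 5' baseline on each
  expressed gene's template strand, plus a damage-induced exponential
  hybrid at TC-DSBs placed on the template strand on the side where the
  template strand is the 3' overhang (gene-downstream side for '+'
  genes, mirrored for '-' genes); this single geometric rule yields the
  three observables at once: template-strand, overhang-strand, and
  one-sided asymmetry.
* END-seq — bidirectional resection boundaries whose exponential extent
  grows between 4 h and 24 h, on each side's overhang strand.
* RPA ChIP-seq — ssDNA plateau over the resected span with a
  break-proximal boost on the hybrid side.
* RNAPII ChIP-seq — Gaussian TSS peaks plus body plateaus, globally
  repressed by factor g after damage and additionally evicted (factor e)
  at damaged genes.
* TT-seq — nascent-transcription body coverage, attenuated downstream of
  the cut at damaged genes after damage.
* DRB/TT-seq — synchronized transcription waves advancing at a
  configured rate v (kb/min) with a Gaussian crest at the front.

All per-bin expectations are Poisson-sampled at a configurable depth.
Every source of randomness flows from one seed through a fixed named
stream per stage/track, so adding a track never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import DSBSite, GeneModel, classify_dsb
from .coverage_io import StrandedTrack

__all__ = [
    "SimulationConfig",
    "TrackBundle",
    "simulate_genome",
    "simulate_dsbs",
    "simulate_tracks",
    "simulate_drb_timecourse",
    "extract_timecourses",
    "simulate_all",
]


class CapacityError(RuntimeError):
    pass


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneParams:
    n_genes: int = 200
    length_min: int = 5_000
    length_max: int = 30_000
    fraction_silent: float = 0.2
    expr_mu: float = 1.0        # log-normal location of expression
    expr_sigma: float = 0.75
    gap_min: int = 4_000
    gap_max: int = 12_000
    exon_min: int = 150
    exon_max: int = 400
    intron_min: int = 800
    intron_max: int = 3_000


@dataclass
class DSBParams:
    # context -> requested count
    contexts: dict = field(default_factory=lambda: {
        "promoter": 12,
        "five_prime_exon": 9,
        "intron": 9,
        "gene_body": 3,
        "intergenic": 4,
        "silent_gene": 3,
    })
    cleavage_min: float = 0.10
    cleavage_max: float = 0.40


@dataclass
class QdripParams:
    background: float = 0.5      # nonspecific per-bin level, both strands
    baseline_amp: float = 0.3    # 5' R-loop per expression unit
    baseline_span: int = 1_500   # bp of gene 5' end carrying the baseline
    hybrid_gain: float = 10.0    # hybrid amplitude per expression*cleavage
    decay_bp: float = 800.0      # exponential decay length lambda


@dataclass
class EndseqParams:
    amplitude: float = 5.0
    mean_length_4h: float = 1_000.0   # exponential resection-length mean L(4h)
    mean_length_24h: float = 3_000.0


@dataclass
class RpaParams:
    amplitude: float = 2.0
    span_factor: float = 2.0     # plateau span = span_factor * L(t)
    beta: float = 1.0            # proximal boost within 500 bp on hybrid side
    boost_span: int = 500


@dataclass
class RnapiiParams:
    background: float = 0.2
    tss_amp: float = 5.0         # Gaussian TSS peak height per expression unit
    tss_sigma: float = 150.0
    body_amp: float = 0.5
    repression_g: float = 0.7    # global post-damage factor, 0 < g <= 1
    eviction_e: float = 0.5      # extra factor at damaged genes, 0 < e <= 1


@dataclass
class TtseqParams:
    background: float = 0.1
    body_amp: float = 1.0
    attenuation: float = 0.3     # downstream-of-cut factor at damaged genes


@dataclass
class DrbParams:
    rate_kb_min: float = 2.0     # true elongation rate v
    rate_sd: float = 0.25        # gene-to-gene spread around v
    times_min: tuple = (5.0, 10.0, 20.0, 30.0, 40.0)
    plateau: float = 20.0        # expected counts per bin behind the front
    crest_amp: float = 40.0      # extra counts at the wave crest
    crest_sigma: float = 1_500.0
    bin_size: int = 100


@dataclass
class NoiseParams:
    enabled: bool = True
    depth: float = 20.0          # Poisson counts per signal unit


@dataclass
class SpikeParams:
    mean_reads: int = 1_000_000


@dataclass
class SimulationConfig:
    seed: int = 0
    bin_size: int = 50
    chrom: str = "chrS"
    margin: int = 20_000         # signal-free chromosome ends
    genes: GeneParams = field(default_factory=GeneParams)
    dsbs: DSBParams = field(default_factory=DSBParams)
    qdrip: QdripParams = field(default_factory=QdripParams)
    endseq: EndseqParams = field(default_factory=EndseqParams)
    rpa: RpaParams = field(default_factory=RpaParams)
    rnapii: RnapiiParams = field(default_factory=RnapiiParams)
    ttseq: TtseqParams = field(default_factory=TtseqParams)
    drb: DrbParams = field(default_factory=DrbParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    spike: SpikeParams = field(default_factory=SpikeParams)

    def __post_init__(self) -> None:
        if not 0 < self.rnapii.repression_g <= 1:
            raise ValueError("repression g must be in (0, 1]")
        if not 0 < self.rnapii.eviction_e <= 1:
            raise ValueError("eviction e must be in (0, 1]")
        if self.qdrip.decay_bp <= 0 or self.drb.rate_kb_min <= 0:
            raise ValueError("decay length and elongation rate must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return _dataclass_from_dict(cls, d, path="config")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _dataclass_from_dict(cls, d: dict, path: str):
    """Strict dataclass construction: unknown keys raise SchemaError."""
    if not isinstance(d, dict):
        raise SchemaError(f"{path}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(d) - set(known)
    if unknown:
        raise SchemaError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        sub = _FIELD_DATACLASSES.get((cls, name))
        if sub is not None:
            kwargs[name] = _dataclass_from_dict(sub, value, f"{path}.{name}")
        elif name == "times_min" and isinstance(value, list):
            kwargs[name] = tuple(float(t) for t in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_FIELD_DATACLASSES = {
    (SimulationConfig, "genes"): GeneParams,
    (SimulationConfig, "dsbs"): DSBParams,
    (SimulationConfig, "qdrip"): QdripParams,
    (SimulationConfig, "endseq"): EndseqParams,
    (SimulationConfig, "rpa"): RpaParams,
    (SimulationConfig, "rnapii"): RnapiiParams,
    (SimulationConfig, "ttseq"): TtseqParams,
    (SimulationConfig, "drb"): DrbParams,
    (SimulationConfig, "noise"): NoiseParams,
    (SimulationConfig, "spike"): SpikeParams,
}


# fixed stream ids: adding a stream never renumbers existing ones
_STREAMS = {
    "genome": 1,
    "dsbs": 2,
    "qdrip_minusDSB": 10,
    "qdrip_plusDSB": 11,
    "endseq_4h": 12,
    "endseq_24h": 13,
    "rpa_4h": 14,
    "rpa_24h": 15,
    "rnapii_minusDSB": 16,
    "rnapii_plusDSB": 17,
    "ttseq_minusDSB": 18,
    "ttseq_plusDSB": 19,
    "drb": 30,
    "spike": 40,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# genome and DSB placement


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Place non-overlapping genes with exon chains along one chromosome.

    Deterministic for a fixed seed.  The chromosome is sized to fit the
    requested genes plus margins; exceeding a 500 Mb cap raises a
    capacity error.
    """
    p = config.genes
    if p.n_genes < 1:
        raise CapacityError("need at least one gene")
    rng = _rng(config.seed, "genome")
    genes: list[GeneModel] = []
    cursor = config.margin
    for i in range(p.n_genes):
        cursor += int(rng.integers(p.gap_min, p.gap_max + 1))
        length = int(rng.integers(p.length_min, p.length_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        silent = rng.random() < p.fraction_silent
        expression = 0.0 if silent else float(rng.lognormal(p.expr_mu, p.expr_sigma))
        start, end = cursor, cursor + length

        # exon chain from the 5' end
        rel_exons: list[tuple[int, int]] = []
        pos = 0
        while pos < length:
            ex = int(rng.integers(p.exon_min, p.exon_max + 1))
            ex_end = min(pos + ex, length)
            rel_exons.append((pos, ex_end))
            pos = ex_end + int(rng.integers(p.intron_min, p.intron_max + 1))
        if strand == "+":
            exons = tuple((start + s, start + e) for s, e in rel_exons)
            tss, tes = start, end
        else:
            exons = tuple(sorted((end - e, end - s) for s, e in rel_exons))
            tss, tes = end, start
        genes.append(GeneModel(f"G{i + 1:04d}", config.chrom, strand, tss, tes,
                               exons, expression))
        cursor = end
    total = cursor + config.margin
    if total > 500_000_000:
        raise CapacityError("genome too large for requested genes")
    # round up to a whole number of bins
    bs = config.bin_size
    total = ((total + bs - 1) // bs) * bs
    return genes, {config.chrom: total}


def _downstream_pos(gene: GeneModel, d: int) -> int:
    """Genomic coordinate d bp downstream of the TSS (transcription sense)."""
    return gene.tss + d if gene.strand == "+" else gene.tss - d


_CONTEXT_EXPECTED = {
    "promoter": ("promoter", "not_applicable", True),
    "five_prime_exon": ("five_prime", "exonic", True),
    "intron": ("five_prime", "intronic", True),
    "gene_body": ("gene_body", None, True),
    "intergenic": ("intergenic", "not_applicable", False),
    "silent_gene": ("intergenic", "not_applicable", False),
}


def simulate_dsbs(
    config: SimulationConfig,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int] | None = None,
) -> tuple[list[DSBSite], pd.DataFrame]:
    """Place DSBs in the requested transcriptional contexts.

    Each placement is verified by round-tripping through
    :func:`dsbstrand.annotate.classify_dsb`; a context that cannot be
    realized with the given genes raises a capacity error.  Returns the
    sites plus a truth table (dsb_id, context, gene_id, tc,
    position_class, exon_class, cleavage, hybrid_side).
    """
    rng = _rng(config.seed, "dsbs")
    p = config.dsbs
    expressed = [g for g in genes if g.expression > 0]
    silent = [g for g in genes if g.expression == 0]
    order_expr = list(rng.permutation(len(expressed)))
    order_sil = list(rng.permutation(len(silent)))
    used: set[str] = set()

    sites: list[DSBSite] = []
    truth_rows = []
    counter = 0

    def placements(context):
        if context == "promoter":
            def place(g):
                off = int(rng.integers(200, 901))
                return _downstream_pos(g, -off)
            return expressed, order_expr, place
        if context == "five_prime_exon":
            def place(g):
                # relative coordinates: the 5'-most exon starts at d=0
                ex_len = (g.exons[0][1] - g.exons[0][0]) if g.strand == "+" else (g.exons[-1][1] - g.exons[-1][0])
                hi = min(900, ex_len - 20)
                if hi <= 30:
                    return None
                return _downstream_pos(g, int(rng.integers(30, hi)))
            return expressed, order_expr, place
        if context == "intron":
            def place(g):
                ex_len = (g.exons[0][1] - g.exons[0][0]) if g.strand == "+" else (g.exons[-1][1] - g.exons[-1][0])
                lo = ex_len + 20
                if lo >= 930:
                    return None
                return _downstream_pos(g, int(rng.integers(lo, 950)))
            return expressed, order_expr, place
        if context == "gene_body":
            def place(g):
                if g.length < 1_600:
                    return None
                return _downstream_pos(g, int(rng.integers(1_100, g.length - 200)))
            return expressed, order_expr, place
        if context == "silent_gene":
            def place(g):
                if g.length < 2_000:
                    return None
                return _downstream_pos(g, int(rng.integers(1_100, g.length - 200)))
            return silent, order_sil, place
        raise ValueError(context)

    for context, count in p.contexts.items():
        for _ in range(int(count)):
            counter += 1
            dsb_id = f"DSB{counter:03d}"
            cleavage = float(rng.uniform(p.cleavage_min, p.cleavage_max))
            if context == "intergenic":
                cut = _place_intergenic(genes, rng)
                gene = None
            else:
                pool, order, place = placements(context)
                found = None
                for idx in order:
                    g = pool[idx]
                    if g.gene_id in used:
                        continue
                    cut = place(g)
                    if cut is None:
                        continue
                    anns = classify_dsb(DSBSite(dsb_id, config.chrom, cut), genes)
                    exp_pos, exp_exon, exp_tc = _CONTEXT_EXPECTED[context]
                    primary = anns[0]
                    ok = (
                        len(anns) == 1
                        and primary.tc == exp_tc
                        and primary.position_class == exp_pos
                        and (exp_exon is None or primary.exon_class == exp_exon)
                        and (context == "silent_gene") == (primary.gene_id is None and g.expression == 0)
                    )
                    if context == "silent_gene":
                        ok = len(anns) == 1 and not primary.tc
                    if ok:
                        found = (g, cut)
                        break
                if found is None:
                    raise CapacityError(
                        f"cannot realize DSB context {context!r} with the simulated genes"
                    )
                gene, cut = found
                used.add(gene.gene_id)

            site = DSBSite(dsb_id, config.chrom, int(cut), cleavage)
            sites.append(site)
            anns = classify_dsb(site, genes)
            a = anns[0]
            tc = a.tc
            if tc:
                hybrid_side = "right" if gene.strand == "+" else "left"
            else:
                hybrid_side = "."
            truth_rows.append({
                "dsb_id": dsb_id,
                "context": context,
                "gene_id": gene.gene_id if gene is not None else ".",
                "gene_strand": gene.strand if gene is not None else ".",
                "tc": tc,
                "position_class": a.position_class,
                "exon_class": a.exon_class,
                "cleavage": cleavage,
                "expression": gene.expression if gene is not None else 0.0,
                "hybrid_side": hybrid_side,
            })
    truth = pd.DataFrame(truth_rows)
    return sites, truth


def _place_intergenic(genes: list[GeneModel], rng: np.random.Generator) -> int:
    """Pick a gap midpoint at least 1.5 kb from every gene span and TSS window."""
    spans = sorted(g.span for g in genes)
    gaps = []
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 - e1 >= 4_000:
            gaps.append((e1 + 1_800, s2 - 1_800))
    if not gaps:
        raise CapacityError("no intergenic gap wide enough for an intergenic DSB")
    lo, hi = gaps[int(rng.integers(0, len(gaps)))]
    return int(rng.integers(lo, hi))


# ---------------------------------------------------------------------------
# track synthesis


@dataclass
class TrackBundle:
    bin_size: int
    chrom_sizes: dict[str, int]
    tracks: dict[str, StrandedTrack]
    truth: dict[str, pd.DataFrame]
    spike_reads: dict[str, int]
    config: SimulationConfig


def _poissonize(track: StrandedTrack, rng: np.random.Generator,
                noise: NoiseParams) -> None:
    if not noise.enabled:
        return
    d = noise.depth
    for vecs in (track.watson, track.crick):
        for chrom in vecs:
            vecs[chrom] = rng.poisson(vecs[chrom] * d) / d


def _add_exponential_side(vec: np.ndarray, cut_bin: int, side: str,
                          amp: float, decay_bp: float, bin_size: int,
                          span_bins: int) -> None:
    d = (np.arange(span_bins) + 0.5) * bin_size
    profile = amp * np.exp(-d / decay_bp)
    if side == "right":
        hi = min(cut_bin + span_bins, len(vec))
        vec[cut_bin:hi] += profile[: hi - cut_bin]
    else:
        lo = max(cut_bin - span_bins, 0)
        vec[lo:cut_bin] += profile[: cut_bin - lo][::-1]


def _add_plateau_side(vec: np.ndarray, cut_bin: int, side: str,
                      amp: float | np.ndarray, span_bins: int) -> None:
    prof = np.broadcast_to(np.asarray(amp, dtype=float), (span_bins,))
    if side == "right":
        hi = min(cut_bin + span_bins, len(vec))
        vec[cut_bin:hi] += prof[: hi - cut_bin]
    else:
        lo = max(cut_bin - span_bins, 0)
        vec[lo:cut_bin] += prof[: cut_bin - lo][::-1]


def _qdrip_expectation(config, genes, chrom_sizes, plus_dsb: bool,
                       dsb_truth: pd.DataFrame | None,
                       sites_by_id: dict[str, DSBSite]) -> StrandedTrack:
    q = config.qdrip
    bs = config.bin_size
    track = StrandedTrack.zeros(chrom_sizes, bs)
    for vecs in (track.watson, track.crick):
        for chrom in vecs:
            vecs[chrom] += q.background
    # baseline 5' R-loop on the template strand of every expressed gene
    for g in genes:
        if g.expression == 0:
            continue
        strand_vecs = track.crick if g.strand == "+" else track.watson
        vec = strand_vecs[g.chrom]
        if g.strand == "+":
            lo, hi = g.tss, min(g.tss + q.baseline_span, g.span[1])
        else:
            lo, hi = max(g.tss - q.baseline_span, g.span[0]), g.tss
        vec[lo // bs : -(-hi // bs)] += q.baseline_amp * g.expression
    if plus_dsb and dsb_truth is not None:
        span_bins = int(8 * q.decay_bp // bs)
        for row in dsb_truth.itertuples(index=False):
            if not row.tc:
                continue
            site = sites_by_id[row.dsb_id]
            amp = q.hybrid_gain * row.expression * row.cleavage
            strand = "crick" if row.gene_strand == "+" else "watson"
            vec = track.strand(strand)[site.chrom]
            _add_exponential_side(vec, site.cut // bs, row.hybrid_side, amp,
                                  q.decay_bp, bs, span_bins)
    return track


def _endseq_expectation(config, sites, chrom_sizes, mean_length: float) -> StrandedTrack:
    e = config.endseq
    bs = config.bin_size
    track = StrandedTrack.zeros(chrom_sizes, bs)
    span_bins = int(8 * mean_length // bs)
    for site in sites:
        cut_bin = site.cut // bs
        # right-side overhang strand is Crick, left-side is Watson
        _add_exponential_side(track.crick[site.chrom], cut_bin, "right",
                              e.amplitude, mean_length, bs, span_bins)
        _add_exponential_side(track.watson[site.chrom], cut_bin, "left",
                              e.amplitude, mean_length, bs, span_bins)
    return track


def _rpa_expectation(config, sites, chrom_sizes, mean_length: float,
                     dsb_truth: pd.DataFrame) -> StrandedTrack:
    r = config.rpa
    bs = config.bin_size
    track = StrandedTrack.zeros(chrom_sizes, bs)
    span_bins = max(1, int(r.span_factor * mean_length // bs))
    boost_bins = max(1, r.boost_span // bs)
    truth_by_id = {row.dsb_id: row for row in dsb_truth.itertuples(index=False)}
    for site in sites:
        cut_bin = site.cut // bs
        row = truth_by_id[site.dsb_id]
        for side, strand in (("right", "crick"), ("left", "watson")):
            vec = track.strand(strand)[site.chrom]
            prof = np.full(span_bins, r.amplitude)
            if row.tc and row.hybrid_side == side:
                prof[:boost_bins] *= 1.0 + r.beta
            _add_plateau_side(vec, cut_bin, side, prof, span_bins)
    return track


def _rnapii_expectation(config, genes, chrom_sizes, plus_dsb: bool,
                        damaged_ids: set[str]) -> StrandedTrack:
    r = config.rnapii
    bs = config.bin_size
    track = StrandedTrack.zeros(chrom_sizes, bs)
    for vecs in (track.watson, track.crick):
        for chrom in vecs:
            vecs[chrom] += r.background / 2.0
    for g in genes:
        if g.expression == 0:
            continue
        factor = 1.0
        if plus_dsb:
            factor *= r.repression_g
            if g.gene_id in damaged_ids:
                factor *= r.eviction_e
        lo, hi = g.span
        n = len(track.watson[g.chrom])
        centers = (np.arange(lo // bs - 20, -(-hi // bs) + 20).clip(0, n - 1))
        centers = np.unique(centers)
        x = (centers + 0.5) * bs
        peak = r.tss_amp * g.expression * np.exp(-0.5 * ((x - g.tss) / r.tss_sigma) ** 2)
        body = np.where((x >= lo) & (x < hi), r.body_amp * g.expression, 0.0)
        contrib = factor * (peak + body) / 2.0  # unstranded assay: half per strand
        track.watson[g.chrom][centers] += contrib
        track.crick[g.chrom][centers] += contrib
    return track


def _ttseq_expectation(config, genes, chrom_sizes, plus_dsb: bool,
                       cut_by_gene: dict[str, int]) -> StrandedTrack:
    t = config.ttseq
    bs = config.bin_size
    track = StrandedTrack.zeros(chrom_sizes, bs)
    for vecs in (track.watson, track.crick):
        for chrom in vecs:
            vecs[chrom] += t.background / 2.0
    for g in genes:
        if g.expression == 0:
            continue
        vecs = track.watson if g.strand == "+" else track.crick
        vec = vecs[g.chrom]
        lo, hi = g.span
        sl = slice(lo // bs, -(-hi // bs))
        body = np.full(sl.stop - sl.start, t.body_amp * g.expression)
        if plus_dsb and g.gene_id in cut_by_gene:
            cut_bin = cut_by_gene[g.gene_id] // bs - sl.start
            if g.strand == "+":
                body[max(cut_bin, 0):] *= t.attenuation
            else:
                body[: max(cut_bin, 0)] *= t.attenuation
        vec[sl] += body
    return track


def simulate_tracks(
    config: SimulationConfig,
    genes: list[GeneModel],
    sites: list[DSBSite],
    dsb_truth: pd.DataFrame,
    chrom_sizes: dict[str, int],
) -> TrackBundle:
    """Synthesize the full stranded track bundle for one configuration."""
    sites_by_id = {s.dsb_id: s for s in sites}
    damaged_ids = {row.gene_id for row in dsb_truth.itertuples(index=False)
                   if row.tc and row.gene_id != "."}
    cut_by_gene = {row.gene_id: sites_by_id[row.dsb_id].cut
                   for row in dsb_truth.itertuples(index=False)
                   if row.tc and row.gene_id != "."}

    e4, e24 = config.endseq.mean_length_4h, config.endseq.mean_length_24h
    tracks = {
        "qdrip_minusDSB": _qdrip_expectation(config, genes, chrom_sizes, False, None, sites_by_id),
        "qdrip_plusDSB": _qdrip_expectation(config, genes, chrom_sizes, True, dsb_truth, sites_by_id),
        "endseq_4h": _endseq_expectation(config, sites, chrom_sizes, e4),
        "endseq_24h": _endseq_expectation(config, sites, chrom_sizes, e24),
        "rpa_4h": _rpa_expectation(config, sites, chrom_sizes, e4, dsb_truth),
        "rpa_24h": _rpa_expectation(config, sites, chrom_sizes, e24, dsb_truth),
        "rnapii_minusDSB": _rnapii_expectation(config, genes, chrom_sizes, False, damaged_ids),
        "rnapii_plusDSB": _rnapii_expectation(config, genes, chrom_sizes, True, damaged_ids),
        "ttseq_minusDSB": _ttseq_expectation(config, genes, chrom_sizes, False, cut_by_gene),
        "ttseq_plusDSB": _ttseq_expectation(config, genes, chrom_sizes, True, cut_by_gene),
    }
    spike_rng = _rng(config.seed, "spike")
    spike_reads = {}
    for name, track in tracks.items():
        _poissonize(track, _rng(config.seed, name), config.noise)
        spike_reads[name] = int(spike_rng.poisson(config.spike.mean_reads))

    gene_truth = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes, g.expression,
          g.gene_id in damaged_ids)
         for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "tes", "expression", "damaged"],
    )
    globals_truth = pd.DataFrame([{
        "repression_g": config.rnapii.repression_g,
        "eviction_e": config.rnapii.eviction_e,
        "hybrid_decay_bp": config.qdrip.decay_bp,
        "endseq_L4h": e4,
        "endseq_L24h": e24,
        "drb_rate_kb_min": config.drb.rate_kb_min,
    }])
    return TrackBundle(
        bin_size=config.bin_size,
        chrom_sizes=chrom_sizes,
        tracks=tracks,
        truth={"dsbs": dsb_truth, "genes": gene_truth, "globals": globals_truth},
        spike_reads=spike_reads,
        config=config,
    )


# ---------------------------------------------------------------------------
# DRB/TT-seq time courses


def simulate_drb_timecourse(
    config: SimulationConfig,
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
) -> tuple[dict[str, StrandedTrack], pd.DataFrame]:
    """Per-time-point wave tracks for long genes plus per-gene truth rates.

    Coverage at time t is a plateau from the TSS to the front at v*t kb
    downstream plus a Gaussian crest centred on the front, Poisson-sampled.
    Signal is written on the gene's sense strand (Watson for '+').
    A front running past the gene end at the last time point emits a
    truncation warning.
    """
    import warnings

    d = config.drb
    bs = d.bin_size
    rng = _rng(config.seed, "drb")
    long_genes = [g for g in genes if g.length > 60_000]
    truth_rows = []
    rates = {}
    for g in long_genes:
        v = max(0.5, float(rng.normal(d.rate_kb_min, d.rate_sd)))
        rates[g.gene_id] = v
        truth_rows.append({"gene_id": g.gene_id, "true_rate_kb_min": v})
        if v * max(d.times_min) * 1_000 > g.length:
            warnings.warn(f"wave front exceeds gene end for {g.gene_id}", stacklevel=2)

    n_bins = {c: -(-size // bs) for c, size in chrom_sizes.items()}
    tracks: dict[str, StrandedTrack] = {}
    for t in d.times_min:
        track = StrandedTrack(
            bin_size=bs,
            watson={c: np.zeros(k) for c, k in n_bins.items()},
            crick={c: np.zeros(k) for c, k in n_bins.items()},
        )
        for g in long_genes:
            front = rates[g.gene_id] * t * 1_000.0  # bp downstream of TSS
            span = 122_000
            dist = (np.arange(span // bs) + 0.5) * bs
            prof = np.where(dist <= front, d.plateau, 0.0)
            prof = prof + d.crest_amp * np.exp(-0.5 * ((dist - front) / d.crest_sigma) ** 2)
            vecs = track.watson if g.strand == "+" else track.crick
            vec = vecs[g.chrom]
            if g.strand == "+":
                start_bin = g.tss // bs
                hi = min(start_bin + len(prof), len(vec))
                vec[start_bin:hi] += prof[: hi - start_bin]
            else:
                end_bin = -(-g.tss // bs)
                lo = max(end_bin - len(prof), 0)
                vec[lo:end_bin] += prof[: end_bin - lo][::-1]
        _poissonize(track, rng, config.noise)
        tracks[f"drb_t{t:g}"] = track
    return tracks, pd.DataFrame(truth_rows)


def extract_timecourses(
    tracks: dict[str, StrandedTrack],
    genes: list[GeneModel],
    times=None,
):
    """Build :class:`~dsbstrand.elongation.GeneTimecourse` objects from
    DRB tracks: per long gene, both-strand coverage over −2 kb…+120 kb
    around the TSS, oriented 5'->3'."""
    from .elongation import BIN_SIZE, WINDOW_END, WINDOW_START, GeneTimecourse

    if times is None:
        times = sorted(float(k.split("_t")[1]) for k in tracks)
    out = []
    for g in genes:
        if g.length <= 60_000:
            continue
        vectors = []
        valid = True
        for t in times:
            track = tracks[f"drb_t{t:g}"]
            bs = track.bin_size
            vec = track.watson[g.chrom] + track.crick[g.chrom]
            if g.strand == "+":
                lo = (g.tss + WINDOW_START) // bs
                hi = (g.tss + WINDOW_END) // bs
                if lo < 0 or hi > len(vec):
                    valid = False
                    break
                win = vec[lo:hi]
            else:
                lo = (g.tss - WINDOW_END) // bs
                hi = (g.tss - WINDOW_START) // bs
                if lo < 0 or hi > len(vec):
                    valid = False
                    break
                win = vec[lo:hi][::-1]
            agg = BIN_SIZE // bs
            if agg > 1:
                win = win[: (len(win) // agg) * agg].reshape(-1, agg).mean(axis=1)
            vectors.append(win)
        if valid:
            out.append(GeneTimecourse(g.gene_id, tuple(times), vectors))
    return out


def write_bundle(bundle: TrackBundle, outdir) -> list[str]:
    """Write a bundle as bedGraph pairs, BED/TSV tables, truth/ directory
    and a config echo; returns the list of files written."""
    from .annotate import write_dsb_bed, write_gene_table
    from .coverage_io import write_stranded_track

    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, track in bundle.tracks.items():
        w, c = write_stranded_track(track, outdir / name, bundle.chrom_sizes)
        written += [str(w), str(c)]
    for name, df in bundle.truth.items():
        path = outdir / "truth" / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written.append(str(path))
    spike = outdir / "truth" / "spike_reads.tsv"
    pd.Series(bundle.spike_reads, name="reads").rename_axis("library").to_csv(spike, sep="\t")
    written.append(str(spike))
    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, size in bundle.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    written.append(str(sizes))
    echo = outdir / "config_echo.yaml"
    bundle.config.to_yaml(echo)
    written.append(str(echo))
    return written


def simulate_all(config: SimulationConfig, with_drb: bool = False):
    """Convenience wrapper: genome -> DSBs -> track bundle (-> DRB tracks)."""
    genes, chrom_sizes = simulate_genome(config)
    sites, truth = simulate_dsbs(config, genes, chrom_sizes)
    bundle = simulate_tracks(config, genes, sites, truth, chrom_sizes)
    if with_drb:
        drb_tracks, drb_truth = simulate_drb_timecourse(config, genes, chrom_sizes)
        bundle.tracks.update(drb_tracks)
        bundle.truth["drb_rates"] = drb_truth
    return genes, sites, bundle
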