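"""DSB classification, category accounting and control-gene matching."""

import numpy as np
import pytest

from dsbstrand.annotate import (
    DSBAnnotation,
    DSBSite,
    GeneModel,
    QuintileShortfallError,
    ValidationError,
    classify_dsb,
    select_control_genes,
    summarize_categories,
)


def make_gene(gene_id="G", strand="+", start=10_000, end=60_000,
              exons=(), expression=5.0, chrom="chr1"):
    tss, tes = (start, end) if strand == "+" else (end, start)
    return GeneModel(gene_id, chrom, strand, tss, tes, tuple(exons), expression)


class TestClassifyDsb:
    def test_promoter_upstream_cut(self):
        g = make_gene()
        anns = classify_dsb(DSBSite("d", "chr1", 9_500), [g])
        assert anns == [DSBAnnotation("d", "G", True, "promoter", "not_applicable")]

    def test_five_prime_intronic_cut(self):
        g = make_gene(exons=[(10_000, 10_200)])
        anns = classify_dsb(DSBSite("d", "chr1", 10_500), [g])
        assert anns == [DSBAnnotation("d", "G", True, "five_prime", "intronic")]

    def test_no_gene_in_reach_is_intergenic(self):
        g = make_gene()
        anns = classify_dsb(DSBSite("d", "chr1", 200_000), [g])
        assert anns == [DSBAnnotation("d", None, False, "intergenic", "not_applicable")]

    def test_silent_gene_body_is_not_tc(self):
        g = make_gene(expression=0.0)
        anns = classify_dsb(DSBSite("d", "chr1", 30_000), [g])
        assert not anns[0].tc and anns[0].position_class == "intergenic"

    def test_gene_body_exonic(self):
        g = make_gene(exons=[(29_900, 30_200)])
        (ann,) = classify_dsb(DSBSite("d", "chr1", 30_000), [g])
        assert (ann.position_class, ann.exon_class) == ("gene_body", "exonic")

    def test_minus_strand_promoter_is_genomic_downstream(self):
        g = make_gene(strand="-")
        (ann,) = classify_dsb(DSBSite("d", "chr1", 60_400), [g])
        assert ann.position_class == "promoter"

    def test_at_most_two_annotations_nearest_tss_first(self):
        genes = [
            make_gene("A", start=10_000, end=20_000),
            make_gene("B", strand="-", start=9_000, end=9_600),  # TSS at 9600
            make_gene("C", start=9_100, end=9_550),
        ]
        anns = classify_dsb(DSBSite("d", "chr1", 9_500), genes)
        assert len(anns) == 2
        assert {a.gene_id for a in anns} <= {"A", "B", "C"}

    def test_brute_force_oracle_random_cuts(self, rng):
        """Labels match an exhaustive interval-membership oracle."""
        genes = []
        pos = 1_000
        for i in range(12):
            length = int(rng.integers(2_000, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            expr = float(rng.choice([0.0, 1.0, 4.0]))
            exons = []
            p = 0
            while p < length:
                e = min(p + int(rng.integers(100, 400)), length)
                exons.append((pos + p, pos + e))
                p = e + int(rng.integers(300, 1_200))
            g = make_gene(f"G{i}", strand, pos, pos + length,
                          exons=exons, expression=expr)
            genes.append(g)
            pos += length + int(rng.integers(500, 3_000))

        window = 1_000
        for cut in rng.integers(0, pos + 2_000, size=1_000):
            cut = int(cut)
            # oracle: exhaustive per-gene interval check
            expected = []
            for g in genes:
                if g.expression <= 0:
                    continue
                d = g.tss_distance(cut)
                if g.contains(cut) and d >= 0:
                    pc = "five_prime" if d < window else "gene_body"
                    ec = "exonic" if any(s <= cut < e for s, e in g.exons) else "intronic"
                    expected.append((abs(d), g.gene_id, pc, ec))
                elif -window < d < 0 and not g.contains(cut):
                    expected.append((abs(d), g.gene_id, "promoter", "not_applicable"))
            expected.sort()
            got = classify_dsb(DSBSite("d", "chr1", cut), genes, window=window)
            if not expected:
                assert got[0].position_class == "intergenic"
            else:
                assert [(a.gene_id, a.position_class, a.exon_class) for a in got] == [
                    (g_id, pc, ec) for _, g_id, pc, ec in expected[:2]
                ]

    def test_cut_outside_chromosome_raises(self):
        with pytest.raises(ValueError):
            classify_dsb(DSBSite("d", "chr1", 999_999), [make_gene()],
                         chrom_sizes={"chr1": 100_000})


class TestSummarize:
    def test_empty(self):
        c = summarize_categories([])
        assert c.n_total == c.n_tc == c.n_silent == 0

    def test_hand_tally(self):
        anns = [
            DSBAnnotation("d1", "A", True, "promoter"),
            DSBAnnotation("d1", "B", True, "five_prime", "exonic"),
            DSBAnnotation("d2", None, False, "intergenic"),
            DSBAnnotation("d3", "C", True, "gene_body", "intronic"),
        ]
        c = summarize_categories(anns)
        assert (c.n_total, c.n_tc, c.n_silent, c.n_dual) == (3, 2, 1, 1)
        assert (c.n_promoter, c.n_five_prime, c.n_gene_body) == (1, 1, 1)
        assert (c.n_exonic, c.n_intronic, c.n_within_gene) == (1, 1, 2)
        assert c.pct_within_1kb_tss == round(100 * 2 / 3)

    def test_totals_conserved_on_fixture(self):
        from dsbstrand.fixtures import load_dsb_annotations

        anns = load_dsb_annotations()
        c = summarize_categories(anns)
        assert c.n_tc + c.n_silent == c.n_total == len({a.dsb_id for a in anns})
        assert c.n_exonic + c.n_intronic == c.n_within_gene

    def test_duplicate_pair_rejected(self):
        a = DSBAnnotation("d1", "A", True, "promoter")
        with pytest.raises(ValidationError):
            summarize_categories([a, a])


class TestControlGenes:
    @staticmethod
    def build(rng, n_damaged=10, n_pool=100):
        damaged = [make_gene(f"D{i}", expression=float(i + 1), start=10_000 + 5_000_000 * i,
                             end=12_000 + 5_000_000 * i) for i in range(n_damaged)]
        pool = [make_gene(f"P{i:03d}", expression=float(rng.uniform(0.5, n_damaged + 1)),
                          start=200_000_000 + 10_000 * i, end=203_000 + 200_000_000 + 10_000 * i)
                for i in range(n_pool)]
        cuts = [DSBSite(f"c{i}", "chr1", 11_000 + 5_000_000 * i) for i in range(n_damaged)]
        return damaged, pool, cuts

    def test_quintile_histogram_matches(self, rng):
        damaged, pool, cuts = self.build(rng)
        ids = select_control_genes(damaged, pool, cuts, seed=1)
        assert len(ids) == len(set(ids)) == 10
        by_id = {g.gene_id: g for g in pool}
        dmg_expr = np.array([g.expression for g in damaged])
        edges = np.quantile(dmg_expr, np.linspace(0, 1, 6))
        edges[0], edges[-1] = -np.inf, np.inf

        def hist(values):
            bins = np.searchsorted(edges, values, side="left") - 1
            return np.bincount(bins, minlength=5)

        ctrl_expr = [by_id[i].expression for i in ids]
        assert (hist(ctrl_expr) == hist(dmg_expr)).all()
        for i in ids:
            g = by_id[i]
            assert all(abs(c.cut - g.span[0]) > 1_000_000 for c in cuts)

    def test_deterministic_for_seed(self, rng):
        damaged, pool, cuts = self.build(rng)
        assert select_control_genes(damaged, pool, cuts, seed=7) == \
            select_control_genes(damaged, pool, cuts, seed=7)

    def test_shortfall_names_the_bin(self, rng):
        damaged, _, cuts = self.build(rng)
        with pytest.raises(QuintileShortfallError, match="bin"):
            select_control_genes(damaged, damaged, cuts, seed=1)

    def test_excluded_ids_respected(self, rng):
        damaged, pool, cuts = self.build(rng)
        banned = {g.gene_id for g in pool[:50]}
        ids = select_control_genes(damaged, pool, cuts, excluded_ids=banned, seed=3)
        assert not set(ids) & banned
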