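"""Synthetic-data generator: determinism, placement validity, truth
round-trips and the signal rules the tracks encode."""

import numpy as np
import pandas as pd
import pytest

from dsbstrand.annotate import classify_all, classify_dsb, summarize_categories
from dsbstrand.orientation import split_track_by_resection
from dsbstrand.simulate import (
    CapacityError,
    DSBParams,
    GeneParams,
    SchemaError,
    SimulationConfig,
    extract_timecourses,
    simulate_all,
    simulate_drb_timecourse,
    simulate_dsbs,
    simulate_genome,
    simulate_tracks,
)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back.to_dict() == cfg.to_dict()

    def test_unknown_keys_rejected(self):
        with pytest.raises(SchemaError, match="typo"):
            SimulationConfig.from_dict({"typo": 1})

    def test_invalid_repression_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError):
            SimulationConfig.from_dict({**cfg.to_dict(),
                                        "rnapii": {**cfg.to_dict()["rnapii"],
                                                   "repression_g": 0.0}})


class TestGenome:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=5)
        g1, s1 = simulate_genome(cfg)
        g2, s2 = simulate_genome(cfg)
        assert s1 == s2 and g1 == g2

    def test_all_silent_when_fraction_one(self):
        cfg = SimulationConfig(seed=5)
        cfg.genes.fraction_silent = 1.0
        genes, _ = simulate_genome(cfg)
        assert all(g.expression == 0 for g in genes)

    def test_placement_validity_brute_force(self):
        """Genes do not overlap and exon chains lie inside their genes."""
        genes, sizes = simulate_genome(SimulationConfig(seed=3))
        spans = sorted(g.span for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for g in genes:
            lo, hi = g.span
            assert 0 <= lo < hi <= sizes[g.chrom]
            for s, e in g.exons:
                assert lo <= s < e <= hi


class TestDsbPlacement:
    def test_round_trip_matches_requested_contexts(self):
        cfg = SimulationConfig(seed=4)
        cfg.dsbs = DSBParams(contexts={"promoter": 2, "intron": 2, "intergenic": 1})
        genes, sizes = simulate_genome(cfg)
        sites, truth = simulate_dsbs(cfg, genes, sizes)
        anns = classify_all(sites, genes)
        by_id = {a.dsb_id: a for a in anns}
        for row in truth.itertuples(index=False):
            a = by_id[row.dsb_id]
            expected = {"promoter": ("promoter", True),
                        "intron": ("five_prime", True),
                        "intergenic": ("intergenic", False)}[row.context]
            assert (a.position_class, a.tc) == expected
            if row.context == "intron":
                assert a.exon_class == "intronic"

    def test_truth_labels_agree_with_classifier_on_default(self, default_bundle):
        cfg, genes, sites, bundle = default_bundle
        truth = bundle.truth["dsbs"]
        for site, row in zip(sites, truth.itertuples(index=False)):
            anns = classify_dsb(site, genes)
            assert anns[0].tc == row.tc
            assert anns[0].position_class == row.position_class

    def test_zero_dsbs(self):
        cfg = SimulationConfig(seed=4)
        cfg.dsbs = DSBParams(contexts={})
        genes, sizes = simulate_genome(cfg)
        sites, truth = simulate_dsbs(cfg, genes, sizes)
        assert sites == [] and truth.empty

    def test_unrealizable_context_raises(self):
        cfg = SimulationConfig(seed=4)
        cfg.genes = GeneParams(n_genes=3, fraction_silent=0.0)
        cfg.dsbs = DSBParams(contexts={"silent_gene": 1})
        genes, sizes = simulate_genome(cfg)
        with pytest.raises(CapacityError):
            simulate_dsbs(cfg, genes, sizes)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=6)
        genes, sizes = simulate_genome(cfg)
        s1, t1 = simulate_dsbs(cfg, genes, sizes)
        s2, t2 = simulate_dsbs(cfg, genes, sizes)
        assert s1 == s2
        pd.testing.assert_frame_equal(t1, t2)


class TestTrackRules:
    def test_silent_dsb_adds_no_qdrip_signal(self, default_bundle):
        """+DSB − −DSB at silent sites is pure noise (zero mean)."""
        cfg, genes, sites, bundle = default_bundle
        truth = bundle.truth["dsbs"].set_index("dsb_id")
        plus, minus = bundle.tracks["qdrip_plusDSB"], bundle.tracks["qdrip_minusDSB"]
        diffs = []
        for s in sites:
            if truth.loc[s.dsb_id, "tc"]:
                continue
            cut = (s.cut // cfg.bin_size) * cfg.bin_size
            for track, sign in ((plus, 1), (minus, -1)):
                parts = split_track_by_resection(track, s.chrom, cut, 2_000)
                diffs.append(sign * (parts["overhang"].sum() + parts["resected"].sum()))
        induced = np.add.reduceat(diffs, np.arange(0, len(diffs), 2))
        # mean induced signal per silent site is ~0 relative to background
        background = cfg.qdrip.background * (4_000 / cfg.bin_size) * 2
        assert abs(induced.mean()) < 0.1 * background

    def test_beta_zero_gives_flat_rpa_plateau(self):
        cfg = SimulationConfig(seed=8)
        cfg.noise.enabled = False
        cfg.rpa.beta = 0.0
        cfg.dsbs = DSBParams(contexts={"promoter": 1})
        genes, sites, bundle = simulate_all(cfg)
        s = sites[0]
        vec = bundle.tracks["rpa_4h"].crick[s.chrom]
        cut_bin = s.cut // cfg.bin_size
        span = int(cfg.rpa.span_factor * cfg.endseq.mean_length_4h // cfg.bin_size)
        plateau = vec[cut_bin: cut_bin + span]
        assert np.ptp(plateau) == 0.0 and plateau[0] == cfg.rpa.amplitude

    def test_noiseless_hybrid_entirely_on_template_overhang(self, tiny_noiseless_bundle):
        """Single TC-DSB in a '+' gene: induced hybrid sits 100% on the
        Crick strand right of the cut, i.e. entirely on the 3' overhang."""
        cfg, genes, sites, bundle = tiny_noiseless_bundle
        s = sites[0]
        row = bundle.truth["dsbs"].iloc[0]
        plus, minus = bundle.tracks["qdrip_plusDSB"], bundle.tracks["qdrip_minusDSB"]
        cut = (s.cut // cfg.bin_size) * cfg.bin_size
        dp = split_track_by_resection(plus, s.chrom, cut, 2_000)
        dm = split_track_by_resection(minus, s.chrom, cut, 2_000)
        ov = dp["overhang"].sum() - dm["overhang"].sum()
        rs = dp["resected"].sum() - dm["resected"].sum()
        assert ov > 0
        assert rs == pytest.approx(0.0, abs=1e-9)
        if row.gene_strand == "+":
            induced_watson = plus.watson[s.chrom] - minus.watson[s.chrom]
            assert np.abs(induced_watson).max() == 0.0
            induced_crick = plus.crick[s.chrom] - minus.crick[s.chrom]
            assert (induced_crick[: s.cut // cfg.bin_size] == 0.0).all()

    def test_endseq_extent_grows_with_time(self, default_bundle):
        """Smoothed END-seq extent (10% of max) is larger at 24 h for
        every DSB when L24h > L4h."""
        cfg, genes, sites, bundle = default_bundle

        def extent(track, site, side):
            vec = track.crick[site.chrom] if side == "right" else track.watson[site.chrom]
            cut_bin = site.cut // cfg.bin_size
            n = 8_000 // cfg.bin_size
            if side == "right":
                prof = vec[cut_bin:cut_bin + n]
            else:
                prof = vec[max(cut_bin - n, 0):cut_bin][::-1]
            k = 5
            sm = np.convolve(prof, np.ones(k) / k, mode="same")
            below = np.nonzero(sm < 0.1 * sm.max())[0]
            return below[0] if below.size else n

        wins = 0
        for s in sites:
            for side in ("right", "left"):
                wins += extent(bundle.tracks["endseq_24h"], s, side) > \
                    extent(bundle.tracks["endseq_4h"], s, side)
        assert wins == 2 * len(sites)


class TestDrb:
    def test_noiseless_crest_position(self):
        cfg = SimulationConfig.from_yaml(_drb_config_path())
        cfg.seed = 2
        cfg.noise.enabled = False
        cfg.drb.rate_sd = 0.0
        cfg.genes.n_genes = 3
        genes, sizes = simulate_genome(cfg)
        tracks, truth = simulate_drb_timecourse(cfg, genes, sizes)
        g = genes[0]
        track = tracks["drb_t10"]
        vec = (track.watson if g.strand == "+" else track.crick)[g.chrom]
        bs = cfg.drb.bin_size
        if g.strand == "+":
            win = vec[g.tss // bs:(g.tss + 120_000) // bs]
            peak = np.argmax(win) * bs
        else:
            win = vec[(g.tss - 120_000) // bs:g.tss // bs][::-1]
            peak = np.argmax(win) * bs
        assert peak == pytest.approx(20_000, abs=200)

    def test_cohort_recovery_within_ten_percent(self):
        from dsbstrand.elongation import cohort_rate

        cfg = SimulationConfig.from_yaml(_drb_config_path())
        cfg.seed = 3
        cfg.genes.n_genes = 25
        genes, sizes = simulate_genome(cfg)
        tracks, truth = simulate_drb_timecourse(cfg, genes, sizes)
        _, summary = cohort_rate(extract_timecourses(tracks, genes))
        assert summary.median_rate == pytest.approx(
            truth.true_rate_kb_min.median(), rel=0.10)

    def test_seed_determinism(self):
        cfg = SimulationConfig.from_yaml(_drb_config_path())
        cfg.seed = 4
        cfg.genes.n_genes = 3
        genes, sizes = simulate_genome(cfg)
        t1, r1 = simulate_drb_timecourse(cfg, genes, sizes)
        t2, r2 = simulate_drb_timecourse(cfg, genes, sizes)
        for name in t1:
            np.testing.assert_array_equal(t1[name].watson["chrS"],
                                          t2[name].watson["chrS"])
        pd.testing.assert_frame_equal(r1, r2)


def _drb_config_path():
    from importlib import resources

    return str(resources.files("dsbstrand") / "configs" / "default_drb.yaml")
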