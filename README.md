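# dsbstrand

Strand-resolved analysis of sequencing signal around DNA double-strand
breaks (DSBs), for genomicists studying transcription-coupled DNA repair
with site-specific break systems (AsiSI restriction-enzyme induction,
Cas9 cutting) and stranded assays: qDRIP-seq (RNA:DNA hybrids), END-seq
(resection endpoints), RPA ChIP-seq (ssDNA), RNAPII ChIP-seq and
(DRB/)TT-seq (nascent transcription).

## What it computes

**DSB classification.** A break is transcription-coupled (TC-DSB) when
it falls inside an expressed gene body or within 1 kb upstream of its
TSS; TC-DSBs subdivide into promoter, 5′ (≤1 kb downstream of the TSS)
and gene-body breaks, and intragenic breaks into exonic/intronic.
Expression-matched control genes are drawn by quintile matching outside
a ±1 Mb exclusion zone around every cut site.

**Break-centric strand geometry.** Resection removes the 5′-terminated
strand at each end, leaving 3′ overhangs. Reading the reference left to
right, the right-hand fragment's Watson strand is 5′-terminated (the
resected strand there) and its Crick strand is the 3′ overhang, mirrored
on the left. With `d` the distance from the cut:

    resected(d) = crick_left(d) + watson_right(d)
    overhang(d) = watson_left(d) + crick_right(d)

The template strand of a '+' gene is Crick (and Watson for '−'), so
hybrid signal formed by gene-template pairing can be tested for sitting
on the overhang, on the template, and on one side of the break — three
observables of a single geometric rule.

**Damage-aware normalization.** DNA damage represses transcription
globally; the TSS-metagene scale factor (mean damaged/undamaged signal
over bins 30–50 of a 40 + 100 + 40-bin metagene) quantifies that and is
divided out so break-local changes remain. Spike-in factors are
`1,000,000 / spike-mapped reads`.

**Profiles and statistics.** Anchor-centred profile matrices, trimmed-mean
average profiles, windowed per-site quantification, paired two-sided
Wilcoxon signed-rank tests and Tukey box summaries (1.5·IQR fences).

**Elongation rates.** After DRB release, per gene and time point the
transcription wave peak is the argmax of a cubic smoothing spline over
−2 kb…+120 kb of 100-bp binned coverage (genes >60 kb); series with
missing, static or non-advancing peaks are dropped, and OLS of peak
distance (kb) on time (min) gives the rate in kb/min.

**Synthetic data.** A seeded generator (`dsbstrand.simulate`) produces
every input — genome, DSB placements verified by round-trip through the
classifier, and Poisson-sampled stranded tracks for all five assays —
with truth tables for parameter-recovery testing.

## Worked example

```python
from dsbstrand.simulate import SimulationConfig, simulate_all
from dsbstrand.annotate import classify_all, summarize_categories
from dsbstrand.orientation import split_track_by_resection

cfg = SimulationConfig(seed=7)
genes, sites, bundle = simulate_all(cfg)
c = summarize_categories(classify_all(sites, genes))
print("sites:", c.n_total, "TC:", c.n_tc, "silent:", c.n_silent)

plus = bundle.tracks["qdrip_plusDSB"]
truth = bundle.truth["dsbs"].set_index("dsb_id")
agg = {True: [0.0, 0.0], False: [0.0, 0.0]}
for s in sites:
    parts = split_track_by_resection(plus, s.chrom, (s.cut // 50) * 50, 2_000)
    tc = bool(truth.loc[s.dsb_id, "tc"])
    agg[tc][0] += parts["overhang"].sum()
    agg[tc][1] += parts["resected"].sum()
print(f"overhang/resected  TC: {agg[True][0]/agg[True][1]:.2f}  "
      f"silent: {agg[False][0]/agg[False][1]:.2f}")
```

prints

```
sites: 40 TC: 33 silent: 7
overhang/resected  TC: 4.70  silent: 1.04
```

i.e. the damage-induced hybrid signal at transcription-coupled breaks
sits ~4.7× preferentially on the 3′-overhang strand, while silent breaks
show no strand preference (ratio ≈ 1) — the generator's geometry
recovered by the analysis stack.

The same pipeline is scriptable from the shell:

```
dsbstrand simulate --config src/dsbstrand/configs/default.yaml --seed 7 --out run/
dsbstrand classify --genes run/genes.tsv --dsbs run/dsbs.bed --out run/annotations.tsv
dsbstrand strandsplit --watson run/qdrip_plusDSB.watson.bedgraph \
    --crick run/qdrip_plusDSB.crick.bedgraph --chrom-sizes run/chrom.sizes \
    --bin-size 50 --dsbs run/dsbs.bed --out run/split.tsv
```

Each command writes a JSON run manifest (config echo, seed, input
digests, outputs) alongside its results.

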