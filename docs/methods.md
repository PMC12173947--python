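# Methods

## Coordinate and strand conventions

All coordinates are 0-based, half-open (BED convention). A DSB `cut` at
position *p* denotes the phosphodiester bond between *p*−1 and *p*; the
bin containing *p* belongs to the right-hand side of the break. Watson
is the reference (plus) strand, Crick its reverse complement. The
template strand of a gene — the strand complementary to its RNA — is
Crick for '+' genes and Watson for '−' genes.

## DSB classification

A gene qualifies for a break when it is expressed and the cut lies in
its body or within 1 kb upstream of its TSS. Classes: promoter
(upstream window, interval (TSS−1 kb, TSS]), five_prime (inside the
body, <1 kb downstream of the TSS), gene_body (inside the body,
further), intergenic otherwise. Exon/intron labels apply only to
intragenic annotations. A break qualifying against several genes keeps
the two nearest-TSS annotations (overlapping genes, or a body hit plus
a neighbouring promoter, are genuinely dual). "Expressed" is
`expression > 0` with a configurable threshold — expression is an
abstract non-negative activity level standing in for visual
nascent-RNA/RNA-seq evidence, which cannot be reproduced
programmatically.

Control genes are matched on expression by binning the damaged genes at
their own empirical quantile edges (ties broken by gene id for
reproducibility) and sampling the same per-bin counts from a pool that
excludes genes within ±1 Mb of any cut site and an externally supplied
exclusion list (e.g. damage-responsive differentially expressed genes —
that list is an input, not recomputed here).

## Break-centric strand geometry

Resection degrades the 5′-terminated strand of each end 5′→3′. On the
right-hand fragment the Watson strand terminates 5′ at the break, so it
is the resected strand there and Crick is the 3′ overhang; the mapping
mirrors on the left. `split_by_resection` therefore combines, at each
distance *d* from the cut, crick_left/watson_right into the *resected*
profile and watson_left/crick_right into the *overhang* profile. Sum
(default) and mean combination are both available; under sum the
transform conserves signal exactly (overhang + resected = two-strand
total at every *d*), which the property suite checks.

Orientation transforms (by gene direction, by dominant signal side)
only re-index values; they are involutive and signal-conserving. Ties
in the dominant-side rule (exactly symmetric signal) do not flip;
ranking ties order by site id — both choices are arbitrary but
deterministic.

## Damage-aware normalization

The metagene layout is fixed at 180 bins: 40 × 50 bp upstream flank,
100 length-proportional gene-body bins, 40 × 50 bp downstream flank.
Per-bin values are base-weighted means, so unequal body-bin widths are
handled exactly. The TSS scale factor is the mean over genes and
(1-based) bins 30–50 — roughly −550 bp to +10 % of gene body — of the
damaged condition divided by the undamaged condition. The factor is
applied by *dividing* the damaged track: a factor below 1 (global
repression) lifts the damaged track back to the undamaged genome-wide
baseline so that local, break-specific changes remain visible. Dividing
the numerator condition versus multiplying the reference is
mathematically equivalent for ratios but not for absolute displays;
this package fixes the former and records it in the factor's
provenance string.

Log2-ratio tracks use a pseudocount (default 1 signal unit) for bounded
behaviour at zero-coverage bins.

## Profile statistics

Quartiles use linear interpolation (the common "type 7" rule; the
convention is recorded because box whiskers and outliers — 1.5·IQR
fences — depend on it only negligibly but reproducibly). Per-site
window quantification reports sums; means differ by a constant factor.
The paired Wilcoxon signed-rank test drops zero differences, uses the
exact null for n ≤ 25 without ties and a tie- and continuity-corrected
normal approximation otherwise; with all differences zero it returns
p = 1 with a warning. The test suite checks the exact n = 6 case
against full enumeration of the 2⁶ sign assignments and calibrates the
empirical type-I error at n = 65 over 2,000 null replicates.

## Elongation rates

Per gene and DRB time point, coverage is binned at 100 bp over
−2 kb…+120 kb around the TSS (genes > 60 kb only). The wave peak is the
argmax of a cubic smoothing spline evaluated at bin centres, restricted
to positions downstream of the TSS so promoter-proximal signal cannot
win. Smoothing: a penalized regression spline with fixed penalty
λ = 10⁹ (x in bp). The equivalent smoothing kernel has bandwidth
≈ (λ·Δx)^(1/4) ≈ 560 bp at Δx = 100 bp — light smoothing, chosen to
correspond to the low-smoothing regime of classic `smooth.spline` fits
(spar ≈ 0.3) on profiles of this length; generalized cross-validation
(`smoothing="gcv"`) gives indistinguishable rate estimates on the
default synthetic cohort at ~35× the cost. Series are discarded if any
peak is missing, all peaks are identical, or any peak fails to advance
strictly past the previous time point ("advance" is read strictly; a
plateauing wave is not a usable clock). Rates are OLS slopes of peak
distance (kb) on time (min), needing ≥ 3 surviving time points. The
cohort "average" rate is reported as the median (mean alongside), the
median being robust to the heavy right tail of per-gene regression
slopes.

The wave plateau behind the crest biases the smoothed argmax slightly
toward the TSS; the bias is approximately constant across time points,
so it cancels in the slope (checked by a dedicated test).

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not read-level realism. One seed feeds a fixed named substream per
stage/track (`numpy` `SeedSequence` spawn keys), so adding a track
never perturbs existing ones and every stage is individually
reproducible.

*Genome*: non-overlapping genes with alternating exon/intron chains,
random strands, log-normal expression with a silent fraction (default
200 genes of 5–30 kb, 20 % silent). *DSBs*: placed in requested
contexts (promoter, 5′-exonic, 5′-intronic, gene-body, intergenic,
silent-gene) and verified by round-trip through the classifier; the
default mix (40 sites, 33 TC / 7 silent, most TC sites within 1 kb of a
TSS) mirrors the category proportions of the canonical 80-site set at
half scale. Cleavage fractions are uniform on 0.10–0.40.

*Signal rules*: qDRIP carries a uniform nonspecific background, a 5′
R-loop baseline on each expressed gene's template strand (first
1.5 kb, amplitude ∝ expression), and — after damage, at TC-DSBs only —
an exponentially decaying hybrid (λ = 800 bp; decay lengths are not a
measured quantity, the value is a free parameter of order the observed
±1–2 kb hybrid footprint) on the template strand on the side where the
template strand is the 3′ overhang: the gene-downstream side for '+'
genes, mirrored for '−'. This single rule simultaneously realizes
template-strand specificity, overhang-strand specificity and one-sided
asymmetry. Hybrid amplitude ∝ expression × cleavage. END-seq places the
survival function of an exponential resection-length law (means
L(4 h) = 1 kb, L(24 h) = 3 kb — order-of-magnitude defaults for
early-versus-late resection expansion) on each side's overhang strand.
RPA is a plateau over the resected span (2·L) with a (1+β) boost within
500 bp on the hybrid side. RNAPII has Gaussian TSS peaks (σ = 150 bp)
plus body plateaus ∝ expression; after damage everything is multiplied
by the global repression factor g (default 0.7) and damaged genes
additionally by the eviction factor e (default 0.5). TT-seq is
sense-strand body coverage, attenuated downstream of the cut at damaged
genes after damage. All per-bin expectations are Poisson-sampled at
depth 20 counts per signal unit.

*DRB time courses* (`configs/default_drb.yaml`): 60 genes of
90–110 kb spaced ≥ 40 kb so the ±(2,120) kb extraction windows do not
overlap; per gene a plateau (20 counts/bin) runs from the TSS to the
front at v·t and a Gaussian crest (amplitude 40, σ = 1.5 kb) sits on
the front; true rates are drawn per gene as Normal(2, 0.25) kb/min
truncated at 0.5, so the cohort median truth is the configured
2 kb/min while gene-to-gene variability is realistic.

What the generator does **not** emulate: mappability, GC and
sequence-composition effects, fragment-length variation, replication
timing, antibody efficiency differences, overlapping transcription
units, or any read-level error process. Passing recovery tests
therefore shows the estimators are correct for their stated models and
robust to shot noise — not that they are robust to every artefact of
real libraries.

## Scale choices

Problem sizes are the package defaults chosen for desk-scale
reproducibility: 200 genes / 40 DSBs for the track bundle, 60 genes for
the DRB cohort, 2,000 replicates for statistical calibration. The
scale-factor recovery scenario uses 4 damaged genes out of 200 (~2 %):
the TSS-metagene estimator is defined genome-wide, where damaged genes
are a vanishing fraction of all genes, and the default 40-sites-per-200
genes mix would over-represent damage ~40-fold relative to that regime.

## Known limitations

- The strand polarity of END-seq chemistry is a generator convention
  (overhang-strand assignment), adequate for extent and bidirectionality
  analyses only.
- `bin_fragments` is interval-based (no CIGAR awareness); aligned-read
  ingestion beyond flag routing is out of scope.
- The per-gene spline penalty is global; genes with strongly
  non-stationary coverage would benefit from per-gene selection, at
  substantial cost.
- Dual-annotated DSBs are capped at two annotations ranked by TSS
  distance.
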