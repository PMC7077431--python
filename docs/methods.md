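# Methods

## Scope and data model

`coldsig` analyses pooled diploid genome panels for signatures of selection
at candidate cold-hardiness genes, together with the physiological and
expression assays that accompany such a study.  The genomic unit of
analysis is a gene window (BED interval, 0-based half-open) crossed with a
species pool (a named set of diploid samples in the VCF).  Genotypes are
derived-allele dosages 0/1/2 with missing calls tracked explicitly; only
biallelic SNPs are considered.

## Synthetic panels: the coalescent generator

Downstream stages are exercised on panels produced by a Kingman coalescent
simulator with infinite-sites mutation.

* **Time scale.** Units of 2N generations: with k lineages the waiting time
  to the next coalescence is Exponential(k(k−1)/2), so E[pairwise
  coalescence time] = 1 and E[π per gene] = θ where θ = 4Nμ·L is the scaled
  mutation rate per gene per pool (default θ = 5).  No recombination within
  a gene: genes are a few kb, matching per-gene window analysis.
* **Mutation.** Each branch receives Poisson(θ/2 × length) mutations; each
  mutation is a new segregating column (no recurrent mutation), and site
  positions are drawn uniformly without replacement within the gene.
* **Diploids.** Haplotypes are paired into diploids by uniform random
  matching (no inbreeding structure; no mating model is asserted by the
  data being emulated).
* **Regimes.** Three per-gene-per-pool demographic regimes emulate the
  footprints a selection scan looks for:
  * *neutral* — the genealogy is untouched;
  * *sweep* — all internal coalescence times are collapsed to
    `sweep_scale` × the original tree height (default 0.1), i.e. a
    star-like genealogy.  All surviving mutations then sit on terminal
    branches as rare variants: diversity is purged and Tajima's D is
    strongly negative (mean ≈ −2 at θ=5, n=20).  A plain uniform rescaling
    of node times would *not* produce this footprint — it preserves the
    shape of the site-frequency spectrum, leaving E[D] ≈ 0 and merely
    thinning S — so the star construction is used deliberately.
  * *balancing* — the root age is multiplied by `balancing_boost`
    (default 5), deepening the basal split.  Mutations accumulating on the
    two basal branches segregate at intermediate frequencies, pushing D
    positive (mean ≈ +0.8 at the defaults).  This regime stands in for the
    excess intermediate-frequency heterozygosity of an interspecific F1
    hybrid pool; an explicitly admixed alternative (`hybrid_mode=
    "admixed"`: one haplotype from each of two populations diverged by
    `hybrid_divergence` coalescent units, plus fixed differences) is
    available when per-individual heterozygosity rather than a deep
    genealogy is the preferred mechanism.
* **Pool-private sites.** Each gene × pool is simulated independently and
  its variants are written as pool-private VCF records (other pools carry
  the ancestral genotype).  This is what differentiates pools and yields
  high per-gene F_ST, mimicking strongly structured species pools.
* **Determinism.** All randomness flows from one seed through
  `numpy.random.SeedSequence` spawns, one substream per gene × pool (plus
  one for site placement), so identical configurations give byte-identical
  VCF/BED/CSV outputs regardless of evaluation order.

The default demo panel mirrors a nine-pool walnut study: pools
JW/BW/BN/HY/AW/MW/PWA/PWU/NCB with 5/6/5/4/3/5/4/7/1 diploids (sample
sizes follow the per-species counts of a 38-genome panel; the published
description never states per-pool sizes directly, so these are
configurable defaults), 33 candidate genes labelled with
DREB/ERF/ICE1/ZAT/CBF-family annotations versus 200 random background
genes, sweep regimes at candidate genes in the two Persian-walnut pools,
and the balancing regime in the hybrid pool.

What the generator does **not** emulate: recombination and linkage between
genes, gene flow and realistic demography, sequencing/genotyping error,
alignment artefacts, and ascertainment bias.  Passing tests therefore
demonstrate correctness of the statistics and the qualitative behaviour of
the screen under idealized genealogies, not calibration against real
walnut data.

## Per-gene statistics

* **Counting rule.** A site is segregating if, among non-missing diploids,
  both alleles are present; it additionally passes the missingness filter
  when the missing-call fraction is ≤ `max_missing` (default 0.5, a common
  choice where the emulated study is silent).  All downstream statistics
  use the filtered site set.
* **π and heterozygosity denominators** are per bp of the full gene
  interval (invariant sites contribute zero).  This matches the magnitude
  of per-gene heterozygosity values quoted for such panels (0.007–0.03),
  which are far below per-variant-site scales.  Per site,
  π = 2j(m−j)/(m(m−1)) with j derived alleles among m non-missing alleles
  (the unbiased pairwise form).
* **Tajima's D** uses a single usable allele count per gene — the median
  across filtered sites of twice the non-missing diploid count — as
  windowed VCF implementations do.  D is NA with reason
  `insufficient_samples` when fewer than 4 usable alleles exist (serialized
  "NA") and `no_variation` when S = 0 (serialized "nan"); the two-symbol
  convention distinguishes structurally-undefined from merely-monomorphic
  cells in output tables.
* **F_ST** is the Weir & Cockerham (1984) variance-components estimator
  generalized to k populations, computed per site on the union of in-window
  positions and combined as the "weighted" ratio of summed a components to
  summed a+b+c (ratio of averages).  Negative estimates are reported
  unclamped.  Sites with fewer than two informative pools, mean sample
  size ≤ 1, or no overall polymorphism are skipped.  A Hudson-style
  pairwise estimator (`fst_hudson_pairwise`) provides an independent
  cross-check route.

Every statistic is tested to |Δ| < 1e-10 against literal-formula
brute-force oracles (explicit loops over expanded allele lists) on
random panels with missing data.

## Sweep screen

The screen operationalizes the qualitative rule "negative Tajima's D and
low diversity and heterozygosity" as: flag a candidate gene in a pool iff
D < `d_threshold` AND both π and Het are ≤ the `percentile_threshold`-th
percentile of the random-gene background in the same pool.  NA statistics
never flag.  Keyword matching on annotation labels is case-insensitive
substring search (default keyword set: DREB, DRE1, DRE2, ERF, EF1, EF2,
EF103, ICE1, ZAT, CBF); the upstream homology-search machinery that
produces the labels is out of scope — the screen starts from a labelled
table.

**Default thresholds.** D, π and Het are positively correlated under
neutrality (a low-diversity gene tends to have negative D), so the null
flag rate of a conjunction rule is much larger than the product of the
marginal rates: at d_threshold = 0 and the 25th percentile the measured
null flag rate is ≈ 0.21.  The defaults were therefore calibrated on
simulated panels (200 sweep genes vs 200 neutral genes, θ=5, n=20, ten
independent panels) to d_threshold = −0.5 and percentile_threshold = 7.5,
giving sensitivity 0.81–0.95 (mean 0.89) at a null flag rate of
0.02–0.095 (mean 0.045).  Both knobs are exposed in the API, the CLI and
the run config.  A defensible null bound is
flag rate ≤ percentile/100 + 0.05 (flagging requires diversity below the
empirical background percentile); product-form bounds assuming
independence of the three criteria do not hold.

The candidate-vs-background contrast (two-sided Mann–Whitney U per pool ×
statistic, Benjamini–Hochberg across all tests) is this package's own
convention — the emulated study reports no formal test for the contrast —
and is labelled as such in the output metadata.  Fully tied inputs are
reported at the U null mean with p = 1.

## Physiology

* **Damage index.** D_I = 100(R_t − R_o)/(1 − R_o) with R_t and R_o the
  means of per-replicate EC_i/EC_f ratios for frozen and control samples.
  Ratios, not conductivities, are averaged: the index is defined on
  per-sample ratios, and replicate-level conductivity scales are arbitrary
  (how real twig slices were aggregated is unknowable from the assay
  description; ratio averaging is the convention here).  R_o ≥ 1 is an
  error ("control fully leaked").  With noise D_I may leave [0, 100]; it is
  reported unclamped with a clamped companion column.
* **Winterkill bands** are left-closed right-open — [0,5)→1, [5,20)→2,
  [20,50)→3, [50,90)→4 — because the verbal band endpoints overlap
  ("5–20", "20–50") and a convention is required; in [90,100] the resprout
  flag separates severe damage (4) from mortal injury (5).
* **ANOVA + protected LSD.** One-way fixed-effects ANOVA; pairwise LSD
  comparisons run only when the omnibus p ≤ α (default 0.05).  The
  compact-letter display uses the insert-and-absorb algorithm, guaranteeing
  significant pairs share no letter and non-significant pairs share at
  least one.  Zero residual variance is handled degenerately: any mean
  difference is then significant.  Protection keeps the null probability
  of any letter split near α (measured ≈ 0.05 over 1000 null panels).

## Expression (comparative Ct)

Technical replicates are averaged within biological replicates first, then
ΔCt = Ct_target − Ct_reference per biological replicate, ΔΔCt between
condition and control (default control 4 °C within each sample — the assay
design gives no cross-sample calibrator), and fold = 2^(−ΔΔCt).
Amplification efficiency is fixed at 2.0 (no efficiency correction is
modelled).  The SE of ΔΔCt adds the biological-replicate variances of the
two conditions; SE(fold) = fold·ln2·SE(ΔΔCt).  The control condition's own
fold is identically 1 with SE √2 × the control ΔCt spread.

## Phylogenies

* **K-mer distance.** Taxa are reduced to canonical k-mer sets (k odd,
  default 25; k-mers containing non-ACGT characters are skipped);
  d = −(1/k)·ln(F) with F = |A∩B|/min(|A|,|B|).  F = 0 maps to a
  configurable cap (default 1.0); no other clamping, so a rate ladder maps
  to strictly increasing distances.
* **Neighbor joining** is the Saitou–Nei algorithm with a deterministic
  tie-break (ties in the Q criterion at 1e-12 resolved toward the
  lexicographically smallest pair of cluster labels, a cluster labelled by
  its smallest leaf).  Negative branch lengths are clamped to zero and
  counted on the tree object.  NJ is exact on additive matrices (verified
  on 100 random 6-taxon trees, topology and path lengths to 1e-9) and is
  used for all four dendrogram flavours; likelihood-based tree inference
  and bootstrap support are out of scope since the trees feed only
  clade-membership claims.
* **Similarity matrices** (e.g. averaged protein-alignment scores) convert
  to distances as d = 1 − s/max(s) with the diagonal forced to zero;
  asymmetry beyond 1e-6 is rejected.  How upstream alignment hits are
  averaged into similarities is the caller's concern; any symmetric
  non-negative matrix is accepted.
* **Clade queries** test whether some edge bisection of the unrooted tree
  isolates a focal taxon together with exactly a given group.  The demo
  bundle engineers a nuclear/organellar discordance: one taxon's nuclear
  sequences evolve inside the East-Asian clade while its organellar
  sequences evolve inside the North-American clade, and the two NJ trees
  recover the conflicting placements.
* **Sequence evolution** for fixtures is Jukes–Cantor-like: per-branch
  substitution probability in [0, 0.75), sites independent, substituted
  sites move to one of the other three bases uniformly.

## Numerical and edge-case choices

* VCF positions are 1-based and converted to 0-based half-open at the
  reader boundary; all internal coordinates are 0-based half-open.
* Genes with no VCF overlap yield S = 0 rows (not errors); empty keyword
  hits warn rather than fail; a pool of all-NA Tajima's D yields an NA
  summary mean with a logged warning.
* Simulated conductivity noise is multiplicative (relative s.d.), keeping
  conductivities positive and the recovered damage index unbiased for
  small noise; the EC_i ≤ EC_f constraint is enforced after noising.
* Problem sizes used by the test suite and acceptance script — 2000
  neutral replicates for coalescent calibration, 200 genes per regime for
  screen characteristics, 1000 null panels for LSD calibration, 100 random
  additive matrices for NJ — were chosen to give Monte-Carlo standard
  errors comfortably below the asserted margins.

## Known limitations

* Tajima's D has an intrinsically non-zero finite-sample mean under
  neutrality (≈ −0.07 at θ=5, n=20 alleles); calibration checks assert a
  band around zero rather than exact unbiasedness.
* The multi-population Weir–Cockerham estimator is undefined for sites
  where the mean per-pool sample size is ≤ 1; single-sample pools
  contribute only where other pools provide replication.
* The screen's background percentiles are estimated from the supplied
  random-gene set; with small backgrounds (< 20 genes the screen refuses
  to run) the cut is noisy and the null flag rate correspondingly
  variable.
* Phased haplotype statistics, LD, sliding windows, imputation, and
  composite-likelihood sweep statistics are deliberately not implemented.

## File formats

* **VCF v4.2** (biallelic SNPs, GT field, contigs Chr01..Chr14) and
  **BED 6+2**: chrom, start, end, gene id, score (0), strand (+),
  class ∈ {candidate, random}, annotation label.
* **Freeze-trial CSV**: genotype, species, temperature, replicate,
  ec_i_frozen, ec_f_frozen, ec_i_control, ec_f_control (conductivities in
  one consistent arbitrary unit; EC_i ≤ EC_f per pair).
* **Ct CSV**: sample, species, gene_role ∈ {target, reference}, gene,
  condition (°C), bio_rep, tech_rep, ct.
* **Stats CSV** (long): chrom, gene, label, class, pool, S, n_snps,
  pi_per_bp, theta_w_per_bp, tajima_d (with "nan"/"NA" NA symbols),
  tajima_d_na_reason, het_obs_per_bp; per-gene F_ST CSV alongside.
* **Distance/similarity CSV**: square matrix with a header row and index
  column of labels.  **Newick**: leaf names and branch lengths, no
  internal labels.
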