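# Methods

`migpipe` re-implements, as a tested pipeline on synthetic data, the
bioinformatic workflow used in museomics studies that genotype herbarium
and silica-dried plant specimens with MIGseq (multiplexed ISSR
genotyping by sequencing): short PCR amplicons anchored in simple
sequence repeats are assembled into orthologous loci, screened for
ancient-DNA-style damage, located on a reference genome, and used for
zone-based divergence statistics, presence–absence phylogenetics and
penalized-likelihood divergence dating.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with full truth tables, so every downstream stage can be scored without
any external data.

* **Species tree.** Pure-birth (Yule) process run forward from the root
  split until the target tip count, then rescaled so the root sits at a
  chosen age (default 45 Ma, an Eocene-scale crown age). Conditioning on
  both tip count and root age by rescaling is the simplest ultrametric
  generator with a controllable depth; it does not reproduce the exact
  Yule age distribution conditioned on n, which none of the tests
  require.
* **Loci.** 300–800 bp cores (uniform lengths) flanked by fixed SSR
  primer motifs, evolved site-independently under Jukes–Cantor at a
  default 1e-3 substitutions/site/Ma. JC was chosen because it gives
  closed-form expected p-distances, used as test oracles. Indels,
  selection and recombination are not simulated.
* **Reads.** Full-length amplicon copies at a configurable depth.
  `genomic` mode injects C→T at the 5′ end and G→A at the 3′ end with
  probability `p0 * exp(-decay * offset)` — the canonical terminal
  deamination profile; `amplicon` mode injects none, emulating
  PCR-amplified (damage-free) templates. Uniform per-base sequencing
  error applies in both modes. Default damage parameters p0 = 0.3,
  decay = 0.4/position are typical of heavily damaged historical
  material and give the detection tests a well-defined signal.
* **Dropout.** Each (sample, locus) cell survives with probability
  `logit^-1(intercept + age_coef*age_years + herb_coef*is_herbarium)`.
  The default is `age_coef = herb_coef = 0` — the no-age-effect null
  that matches the observation that locus recovery is not driven by
  specimen age — with non-null settings available for power studies.
* **Zones.** `clade-structured` assignment cuts the tree at its oldest
  internal nodes and gives whole clades one zone, so intra-zone
  divergences are stochastically smaller; `random` permutes those
  labels as a matched null.
* **Phylograms for dating.** Branch substitution counts are drawn
  Poisson(rate × duration × sites); rates are constant (clock), iid
  lognormal, a parent→child geometric random walk (autocorrelated), or
  carry a lineage rate shift (one basal clade uniformly faster, default
  4×). The autocorrelated walk is the regime penalized likelihood
  assumes; the clade shift is the classic strong-heterogeneity scenario
  that no amount of smoothing can fit; iid variation is deliberately
  mismatched and probes robustness. On small trees with a single root
  calibration window, leave-one-tip-out cross-validation can legitimately
  prefer heavy smoothing under iid or random-walk variation (free node
  ages absorb local rate variation), which is why the direction check
  clock-vs-heterogeneous uses the clade-shift regime.

What passing tests show about real data is limited by these choices: no
indel handling, no paralogy beyond what the allele filter sees, no
paired-end artifacts, uniform quality scores, and one sample per
species.

## Locus assembly

The assembler mirrors a reduced-representation pipeline run without a
restriction overhang: reads with more than 50 bases under Phred 20 are
discarded; reads are clustered greedily within samples at 85% 5′-
anchored identity (amplicons share their primer anchor, so ungapped
prefix comparison is appropriate); per-sample heterozygosity h and
sequencing error ε are estimated jointly by maximum likelihood under a
diploid site model (each site heterozygous with probability h, read
bases miscalled uniformly with probability ε; genotype priors uniform
within the homozygous and heterozygous classes); consensus bases are
maximum-posterior genotype calls, written as IUPAC codes for
heterozygotes and N when no genotype reaches half the posterior mass.
Consensus sequences are clustered across samples at 85% identity under
unit-cost global alignment and members are projected onto centroid
coordinates.

The filter cascade (defaults: depth ≥ 5; ≤ 2 alleles; ≤ 5 N and ≤ 8
heterozygous sites per consensus; ≤ 40 indels per locus; locus present
in ≥ 4 samples) operates at two levels, mirroring where each filter
acts in practice: depth/N/het failures drop the offending sample from
its locus; an allele-count or indel failure removes the locus; a locus
left under the taxon minimum is removed as `low_taxa`. A removed locus
can carry several reasons, so per-reason counts are deliberately
non-exclusive and the report flags this. Allele counting phases reads
across heterozygous sites and counts haplotypes supported by at least
max(2, 10% of depth) reads, treating rarer haplotypes as errors.

Group comparisons (herbarium vs silica) use two-sided Mann–Whitney U
by default (robust at n ≈ 20–40 per group; Welch's t available), with
raw p-values. The correlogram is plain Pearson correlation with NaN for
zero-variance statistics.

## Damage profiling

Reads are aligned back to their consensus (same-length fast path;
unit-cost global alignment otherwise; identity < 0.5 flags the read
unassigned) and C→T (5′) / G→A (3′) misincorporations are counted per
offset 1..25 from each end — the conventional window. The "no damage
pattern" claim is made testable by a terminal-vs-interior two-proportion
Fisher exact test: offsets 1–3 pooled against offsets ≥ 11, returning a
rate ratio and two-sided p. The thresholds (k = 3, interior from 11)
are configurable; at least 30 opportunities are required on each side.

## Genome context

Locus positions arrive as BED intervals (read mapping itself is out of
scope). Nearest-feature search follows bedtools-closest semantics:
distance 0 on overlap or book-ending, otherwise the gap between nearest
interval ends, signed negative when the feature lies 5′ of the locus;
ties break toward the smaller feature start, then the class order CDS,
TE, UTR5, UTR3. Density is loci per Mb per chromosome with the Pearson
correlation of count against length. "Random placement" is
operationalized as a homogeneous Poisson process: inter-midpoint gaps,
rescaled by each chromosome's own density so they are Exp(1) under the
null, are pooled and tested with Kolmogorov–Smirnov against the
standard exponential. Estimating the per-chromosome rate from the same
data makes the test mildly conservative, which only strengthens a null
retention.

## Zone divergence

Per-locus pairwise p-distances are computed over shared unambiguous
sites (gaps, N and IUPAC ambiguity codes are excluded so heterozygosity
is not counted as divergence) and pooled without per-pair averaging.
Under a zone configuration (2: continent/island; 4: I–IV; 6: I, II,
IIIa–c, IV) a pair is intra-zone if the species share any zone,
inter-zone if their zone sets are disjoint; species spanning several
zones are excluded under the 2-zone policy (configurable elsewhere).
For per-zone analysis each record enters the panel of every zone one of
its species occupies, intra if both do. The two-way ANOVA (distance ~
type * zone) uses type-II sums of squares for the unbalanced pooled
records and includes the interaction whenever every cell is occupied,
falling back to the additive model otherwise (a single-species zone has
no intra-zone pairs). Tukey HSD reports studentized-range adjusted
p-values with significance flagged at 0.01.

Pooled records are pseudo-replicated (the same species pair appears
once per locus), a property inherited from the original design; the
null calibration therefore permutes the intra/inter labels across
records — the exchangeable unit for this test — rather than permuting
species labels, which would leave the pair-level correlation intact and
no record-level F-test could hold its size against it.

## Presence–absence phylogenetics

Retained loci define the binary samples × loci matrix. The default
distance is the mismatch proportion (shared absence counts as
agreement; Jaccard available). Neighbor joining follows Saitou–Nei:
join the pair minimizing Q = (n−2)d_ij − r_i − r_j, two-point branch
lengths, negative lengths clamped to zero with the deficit moved to the
sister branch, ties broken to the lowest-index pair. Supports come from
resampling loci columns with replacement (default 1000 replicates) and
mapping bipartition frequencies onto the reference tree. Variable
alignment columns (≥ 2 distinct unambiguous states) are exported as a
concatenated SNP matrix in PHYLIP/FASTA for external ML; ML tree search
itself is out of scope.

## Penalized-likelihood dating

For a rooted binary phylogram with branch lengths b (subst/site), each
branch's substitution count x = b·n_sites is modeled Poisson with mean
r·t·n_sites (r the branch rate, t its duration from the node ages). The
objective is −log L + λ·Φ with Φ the sum of squared parent–child rate
differences plus the variance of the root's child rates, rates entering
Φ in units of their current mean. The normalization is deliberate: the
likelihood depends on ages and rates only through r·t, so it is exactly
invariant under (ages·c, rates/c); with raw rates the penalty's weight
would depend on the arbitrary rate scale (a grid value like λ = 1e5
enforces a clock at rates near 1 but not at realistic 1e-3
subst/site/Ma) and its absolute magnitude would bias the fit toward the
oldest permitted root. With the dimensionless penalty the λ grid
(1e5…1e-3) means the same thing on any dataset.

Ages are parameterized by proportional depths — each internal node's
age is its lower bound plus a fraction of the window below min(its
upper bound, parent age) — which keeps ordering and calibration boxes
feasible under simple box constraints. Optimization is multi-start
L-BFGS-B with an analytic gradient (forward accumulation through the
age recursion); the deterministic base start uses mid-window fractions
and the global rate implied by the data, with random restarts around
it; the best solution is kept, preferring the earlier start on ties.
Fractional substitution counts use the continuous (ln-Γ) Poisson
likelihood; terminal branches get a 1e-9 expected-substitution floor.

Because of the exact scale invariance, the absolute timescale is
identified only by the calibration boxes: the profile objective is flat
along the scale ridge, and the fit is reported at the midpoint of the
feasible scaling interval rather than wherever the optimizer stops.
A fixed age (min = max) pins the scale and the rescaling is a no-op.

Cross-validation is leave-one-tip-out over a log-spaced λ grid from 1e5
down to 1e-3: the pruned branch's count is predicted from the merged
branch's fitted rate and the attachment age interpolated on the merged
branch in proportion to the original branch lengths; the score is the
chi-square sum over tips, warm-starting each λ from the previous fit.
Tips attached directly to the root are not scored — pruning one leaves
no node carrying the root calibration at the original attachment age,
so their prediction is unidentifiable. The chosen λ is the argmin, ties
resolved toward heavier smoothing.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything on desk-scale
simulations chosen to make each statistical check well-powered:
100 random trees for NJ consistency; 20 ten-tip clock phylograms at
10,000 sites for dating recovery; 20 eight-tip paired phylograms
(clock vs 4× clade shift) for the CV direction; 500 depth-30 clusters for the (h, ε) estimator; 100/200
replicates for damage power and size; 100 zone replicates plus 500
label permutations; 100 seeded spacing replicates. The end-to-end
synthetic study uses 12 species × 60 loci at depth 10.

Other numerics: the (h, ε) likelihood collapses sites to sorted
base-count patterns and maximizes with bounded L-BFGS-B from three
fixed starts (a 2-D grid search is the test oracle); consensus calls
fall to N below 0.5 posterior; greedy clustering breaks ties by
abundance then lexicographic order; all random streams derive from
(master seed, stage name) so stage order never changes results.

## Known limitations

The assembler is not a byte-level reproduction of ipyrad (identity
thresholds are the upstream convention, 0.85, the paper not stating
them); per-reason filter counts are non-exclusive by design, so they
need not sum to input − retained (the original study's printed counts
are likewise non-additive); the dating CV concretizes a procedure the
original tool does not document; and amplicon-mode damage-freedom is an
assumption of the simulation, not evidence about any particular real
library.
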