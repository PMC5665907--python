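# Methods

## Model

The package studies one mechanism: A-to-I editing in a 3′ UTR stabilises
local RNA secondary structure, reduces the accessibility of nearby
AGO2-miRNA target sites, and thereby protects the edited transcript from
degradation. Because sequencing only sees the surviving pool, the mechanism
also distorts the measurement itself.

For one site in one individual, with true (pre-degradation) editing level
*e* ∈ [0,1] and survival probabilities *s*<sub>u</sub>, *s*<sub>e</sub> ∈
(0,1] for unedited and edited molecules:

- observed editing = *e s*<sub>e</sub> / (*e s*<sub>e</sub> + (1−*e*) *s*<sub>u</sub>)
- relative abundance = *e s*<sub>e</sub> + (1−*e*) *s*<sub>u</sub>

Both are exact consequences of thinning the two molecule classes
independently. When *s*<sub>e</sub> ≥ *s*<sub>u</sub>, observed ≥ *e*, and
for two sites sharing *s*<sub>u</sub> < *s*<sub>e</sub> = 1 the observed
ratio is strictly compressed relative to the true ratio — the buffering
property, asserted over a parameter grid in the tests.

Survival is linked to structure by *s* = exp(−k · *a* · *p*), where *a* is
the individual's AGO2-miRNA activity (AGO2 × miRNA expression, each
normalised to its cohort mean), *p* the 7mer accessibility of the target
site in the relevant variant, and *k* ≥ 0 a global degradation scale
(default 1). This is the simplest monotone link that keeps survival in
(0,1]; the analyses only use its direction and relative magnitude.

True editing follows a logistic link from log ADAR1 expression:
logit(*e*) = α (log ADAR1 − μ) + β<sub>site</sub> + ε. The slope α = 1.2
and centre μ = 2.25 put typical levels in the 0.1–0.4 range observed for
3′ UTR sites; site baselines β ~ N(−1.0, 0.8²) spread sites from rare to
prevalent. The per-cell noise ε ~ N(0, 1.8²) is the within-individual
variation of true editing — a quantity the source data do not constrain, so
it is an explicit free parameter. Its default is deliberately large: editing
at a given site varies strongly across individuals even at fixed ADAR1, and
this dispersion is what lets the same cohort exhibit both an AGO2-editing
correlation and editing-driven (rather than activity-driven) membership in
the edited/unedited comparison groups. With this value, the per-site
variance in editing explained by ADAR expression averages ≈ 7%, in the
single-digit-percent regime reported for population editomes.

## Synthetic cohort — what it emulates and what it does not

The packaged study conditions are 2 populations × 100 individuals and 50
genes: 30 edited genes with one miRNA target site at staggered distances
(6–93 nt, alternating A·C and A-U stem designs), 10 edited genes without
target sites (knockdown control group), and 10 unedited genes with target
sites (expression control group). The gene panel is generated once per study
seed and shared across cohort draws — same genome, different cohorts.
Expression profiles are log-normal: ADAR1 location 2.0/2.5 (the two
populations differ markedly in ADAR expression), σ = 0.30 within population;
AGO2 (1.5, 0.45) and miRNA (3.0, 0.40) are population-invariant. Read depth
is Poisson(60 × relative abundance); alt counts are binomial with a
sequencing error rate of 10⁻³ folded in; Phred qualities are clipped
N(35, 5²); non-A-to-G errors are spread uniformly over the other
substitution types.

Designed hairpins place the editable A at the midpoint of a GC-rich 10-bp
stem with a UUCG tetraloop; the 3′ arm pairs every position except the
editing site, which faces C (A·C mismatch → G-C pair upon editing) or U
(A-U pair → G·U wobble). Flanks are pyrimidine-biased and G-free so no
competing hairpin forms; the miRNA seed match (7mer-m8 for miR-24-3p by
default) is written into the 5′ flank at the requested edge-to-edge
distance.

One deliberate modelling split: the **target-site accessibilities driving
degradation are model-level quantities**, not folded ones. Folding
experiments on the designed UTRs show that a single A→G edit changes 7mer
accessibility strongly within about ±10 nt of the site and essentially not
at all at a seed site tens of nucleotides away — a single closed base pair
cannot melt or form a helix at that range. The population analyses, however,
require a graded distance-dependent effect over 6–93 nt (in real transcripts
this arises from long-range and ensemble effects over thousands of genes).
The generator therefore prescribes per-gene accessibilities
(*p*<sub>u</sub>, *p*<sub>e</sub>) = (0.7, 0.7 · 2^Δ(d)) with
Δ(d) = −2.5 exp(−d/40), a profile whose sign and spatial scale match the
folded near-site behaviour. All structural analyses (pairing of the editing
site, opposite-base spectra, accessibility profiles, paired-window counts)
use real folding; only the degradation input is prescribed. Consequently,
passing the end-to-end direction checks demonstrates that the degradation
mechanics produce the population signatures — not that folding alone
reproduces them at 50-gene scale.

Other simplifications: no read-level FASTQ/alignment simulation, no
hyper-edited clusters, one miRNA species, no linkage between sites within a
gene (each gene carries one site), and expression noise that is log-normal
and independent across genes.

## Statistical procedures

- **LLR error filter.** Per alt read with Phred *Q*, error probability
  *p* = 10^(−Q/10). Variant model: alt reads seen with probability
  *f*(1−*p*) + (1−*f*)*p*, reference reads with (1−*f*)(1−p̄) + *f*p̄
  (mean alt-read error probability standing in for unreported reference
  qualities). LLR = log₁₀ of the ratio of the likelihood maximised over
  *f* ∈ [0,1] (bounded scalar minimisation) to the errors-only model
  (*f* = 0); sites with LLR < 2 are removed. Whether the original filter
  used log₁₀ or ln, and how read position enters, is not recoverable; the
  base is configurable and an optional half-weight for mismatches within
  6 nt of read ends is provided but off by default.
- **Filter cascade.** Fixed evaluation order (coverage, edited reads,
  editing level, LLR, SNP, simple repeat, homopolymer, splice junction) for
  the "first failing rule" label only; every record carries its full failure
  set, so the surviving set is order-invariant. All thresholds are closed on
  the passing side (depth 10, alt 2, level 0.1, LLR 2 pass). "Homopolymer"
  means the site lies inside a run of more than 4 identical nucleotides.
- **Rank-sum test.** Exact permutation enumeration with midranks when both
  groups are ≤ 8 (two-sided p = share of permutations at least as deviant
  from the null mean); otherwise the normal approximation with continuity
  and tie correction (scipy). Differential editing additionally requires
  |Δ mean level| > 0.067 — one edited read at coverage 15, the smallest
  shift the data can represent there.
- **Editing index** = Σ edited reads / Σ reads over an individual's testable
  sites (depth-weighted level); equals the unweighted mean exactly when all
  depths are equal. Per-individual means average over the population site
  set by default (configurable), since the alternative — each individual's
  own called set — is not identifiable from the source description.
- **Variance explained.** Per site, ordinary least squares of level on the
  three ADAR expressions with intercept; eligible when > 10 testable
  individuals and ≥ 2 distinct levels; R² clipped to [0,1].
- **Stratifications.** Rank-based tertiles with deterministic tie-breaking
  by individual id; the compared high/low groups must not differ in any
  matched covariate (rank-sum p > 0.1) and must contain ≥ 3 individuals,
  otherwise the comparison is reported infeasible rather than skipped. The
  Fig-5-style contrast is read against the no-editing gene group (a paired
  contrast), which cancels the residual activity mismatch the matching
  tolerance admits.
- **AGO2-editing correlation** is computed within each population and
  averaged, since between-population ADAR differences would otherwise enter
  as noise in a pooled correlation.

## Structure computations

Folding uses the Vienna RNA scripting bindings: RNAfold MFE structures and
RNAplfold unpaired probabilities with u = 7, L = 300 (max pair span),
W = 400 (window), over a 1001-nt window centred on the site (truncated at
sequence ends; window bounds recorded). Inosine is represented as G. The
7mer is centred on the reported offset; offsets where a centred 7mer does
not fit are missing, not zero. Relative accessibility is
log₂(P_edited/P_unedited) with probabilities floored at 10⁻⁸ to keep the
profile finite inside tight helices. The opposite-nucleotide rule: partner
base if the site is paired; else the base adjacent (antiparallel geometry)
to the partner of a paired immediate neighbour, 5′ neighbour consulted
first (the tie is not specified anywhere; fixed for determinism); else 'N'.
A base-pair-maximisation engine exists solely so pair-table logic can be
unit-tested without the thermodynamic engine; it cannot produce
accessibilities.

Control adenosines are drawn uniformly among As in 3′ UTRs that are not
editing sites and lie within a configurable distance band of the nearest
site (300–500 nt for accessibility controls, 200–300 nt for the
paired-window comparison).

## Numerical and design choices

- Coordinates are 0-based half-open internally; BED output is 0-based
  half-open, the VCF-like site table 1-based. Minus-strand genomic T-to-C
  mismatches count as A-to-G.
- Seed-match classification: 8mer claims its locus first; overlapping 7mer
  calls at a claimed locus are suppressed, so no site is double-counted.
  Editing-to-target distance is edge-to-edge (0 when the site lies inside
  the seed; such designs require an explicit opt-in).
- The distance-windowed accessibility-expression analysis uses 10-nt
  windows sliding by 1 nt over gene-level pairs (accessibility change at the
  closest target site vs log₂ expression ratio of edited, level ≥ 0.3,
  over unedited, zero alt reads, individuals; ≥ 3 per side; gene mean
  expression ≥ 0.1); the correlation is reported as undefined with fewer
  than 3 non-empty windows or constant deltas.
- Determinism: every stochastic step takes a seed; the pipeline summary
  contains no timestamps and is byte-identical across reruns of the same
  configuration and seed.

## Problem sizes

The packaged scenario uses 2 × 100 individuals, 50 genes, 20 cohort seeds,
and 20 folded hairpin designs; these sizes keep the full test suite and the
reproduction script fast on a single CPU while leaving every direction
statistic far from its decision boundary. The same code paths accept larger
cohorts and panels unchanged.

## Known limitations

- The degradation link and the accessibility-distance profile are the
  package's own parameterisations of a mechanism for which the source
  evidence is directional; absolute effect sizes in the simulation are not
  calibrated to any real cohort.
- The LLR filter approximates reference-read qualities by the mean alt-read
  error probability, since pileup summaries do not carry them.
- The exact rank-sum enumeration is O(C(n₁+n₂, n₁)) and intended for the
  n ≤ 8 regime it is restricted to.
- `select_population_sites` treats the ≥ 10% coverage criterion as a real
  fraction of the population size (no rounding rule was stated).
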