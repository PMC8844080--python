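# Methods

## Weighted methylation levels and region aggregation

All levels are *weighted methylation levels*: for a region R and context
c ∈ {CG, CHG, CHH}, w = Σ methylated read counts / Σ total read counts
over every cytosine of context c whose 0-based position lies in
[start, end). Both strands are pooled; CpG dyads are not collapsed (each
strand's cytosine is its own record, as in the Bismark report). Internal
coordinates are 0-based half-open; CX-report positions (1-based) are
converted on read — one convention everywhere kills the off-by-one class
of bugs. Context is trusted from the report, never recomputed from a
reference sequence, so the package needs no FASTA.

A region with no covered cytosine of a context has an *undefined* level
(NaN), never 0 — zero and unobserved are biologically different states,
and the residual-mCG logic downstream depends on the distinction. Sites
with zero coverage are retained on read; under read-count weighting they
contribute nothing.

The wording "methylated cytosines over total cytosines" is ambiguous
between read-count pooling and per-site binary calls. Read-count pooling
is the default (the standard weighted-level definition);
`levels.per_site_call_level` (site called methylated when its level
≥ 0.5 at coverage ≥ 1) is provided for sensitivity analysis.

Replicates are combined by pooling counts, not averaging levels —
consistent with coverage weighting. A flag-level alternative is trivial to
compute from the per-replicate tables the pipeline writes.

## Metagene profiles

Each region body is divided into 20 near-equal half-open segments
(remainder bases assigned to the 5′-most segments — deterministic and
orientation-consistent) and each 2 kb flank into 10 segments of 200 bp.
Minus-strand regions are reversed so segment 1 is always the 5′ flank
end. Flank segments running past the chromosome start are truncated and
flagged rather than dropped (the choice is not observable in practice
because the generator leaves a margin; truncation preserves sample size
for real data). Regions shorter than 1 kb are excluded by the caller for
heatmap-style analyses, matching standard practice for TE-gene profiles.

## Recovery statistics

Recovery efficiency is the plain ratio F1/WT (or mF1/met1) of weighted
levels per TE gene. To avoid dividing by values near zero, only TE genes
with mCHG > 0.1 (or mCHH > 0.03) in *both* reference methylomes enter the
ratio; the thresholds are configuration-exposed with these defaults.
Ratios above 1 (over-recovery) are legitimate and occur for high-rank
regions in a globally hypomethylated genome.

Decile partitions are keyed by a genome's mCG, ascending, with ties broken
by region id (determinism); group sizes differ by at most one. Percentile
ranks use mid-ranks: (number strictly lower + 0.5 × tied) / n, invariant
under monotone transforms. Boxplot summaries report quartiles and
1.5 × IQR whiskers.

## Differential methylation test

Differential mCH between replicate groups (e.g. 2 F1 vs 4 mF1 replicates)
is tested per region with a beta-binomial likelihood-ratio test, a
self-contained replacement for negative-binomial count-model pipelines:
the null is equal mean proportion across groups with a common
intra-class correlation ρ. ρ is estimated per region by method of
moments from the within-group binomial chi-square and shrunk toward the
cross-region median with prior weight 20 (an empirical-Bayes compromise:
with 2–4 replicates the per-region estimate is very noisy, and unshrunken
estimates make the LRT anti-conservative). The statistic is twice the
profiled log-likelihood ratio at the shrunk ρ, referred to χ²(1);
q-values are Benjamini–Hochberg. With a single replicate per group the
dispersion is unidentifiable; the test then runs on the prior alone and
warns.

Calibration, measured by the acceptance suite: under a complete null with
2 vs 4 replicates and ρ = 0.05, the fraction of regions called at
q < 0.05 is ≈ 0. A caveat worth stating plainly: at ρ = 0.05 the
replicate-level variance floor (ρ·p(1−p) per replicate) makes a
proportion shift of 0.15 essentially undetectable at these replicate
numbers *for any test* — the per-region z is ≈ 1.7. Power is therefore
demonstrated at ρ = 0.005, the replicate-level correlation scale that the
package's own observation model induces for pooled per-gene counts at
~20× coverage (replicates share truth and differ by counting noise);
there the test reaches ≥ 95% sensitivity for Δ = 0.15 planted in 10% of
regions, with ≥ 90% precision after the Δ-filters.

Significant regions are then Δ-filtered: |level_mF1 − level_F1| must
exceed 0.1 (CHG) / 0.03 (CHH) while |level_WT − level_met1| stays below
the same bound, removing regions whose change merely reflects the met1
mutation.

## Rank tests

All location comparisons are two-sided Wilcoxon tests: rank-sum
(Mann–Whitney) for independent groups, signed-rank for paired series
(generation steps, mutant-vs-mutant gene pairs). Exact null distributions
are used for small samples and the normal approximation with continuity
correction otherwise (scipy's automatic switch; the crossover is at the
scale where the exact computation stops being cheap). "Significant" in the
package's summaries means p < 0.01. Identical paired inputs return p = 1
— evidence for the null, not an error.

## The synthetic methylome generator

The generator exists so that every claim the pipeline makes can be checked
against planted truth. Its feedback model is this package's own
construction — the biology it emulates is stated as phenomena, not
equations, so the functional forms below are stand-ins chosen for
monotonicity and interpretability, with every parameter exposed in
`FeedbackParams`.

**Wild-type layer.** TE genes: mCG ~ Beta(mean 0.85), mCHG ~ Beta(0.30),
mCHH ~ Beta(0.10). 20% of genes are gbM (mCG ~ Beta(0.40), mCH ≈ 0.01);
the rest sit at ≈ 0.02/0.01. 2% of "genes" receive TE-like truth
(mis-annotated TEs, exercising the WT-mCHG > 0.05 exclusion). Default
genome: 2000 genes + 500 TE genes (15% of them shorter than 1 kb, to
exercise the length filter) on 2 chromosomes, with CG/CHG/CHH site
densities 0.02/0.02/0.04 per bp — scaled-down but proportionate to a
plant gene space.

**met1 layer.** Each region's mCG is multiplied by a heritable retention
factor r: full loss (r ~ Beta(1, 60)) with probability 0.08, partial
retention r ~ Beta(2, 1.3) otherwise — the partial-function allele keeps
mCG in many but not all regions, with a wide spread so residual mCG spans
the decile range. r is drawn once per lineage and reused by every derived
genotype (heritable epialleles).

**Establishment (F1/mF1).** Recovered mCH = WT mCH × E(m) × G, where m is
the region's current absolute mCG,

E(m) = 0 for m < 0.05, otherwise clip((m − 0.05)/(0.9 − 0.05), 0, 1),

a hard-gated linear ramp. The hard gate encodes "no residual mCG, no
establishment"; the non-saturating ramp makes graded residual mCG produce
graded recovery across its whole range. A rank-based efficiency curve was
considered and rejected: ranks are scale-free, so a purely rank-driven
model could neither let the full-mCG F1 recover more efficiently than a
rank-uniform mF1 nor distinguish a genome-wide mCG change from no change —
the genome-wide dependence belongs to the gain term instead.

**Global gain.** G = (M_ref / M_genome)^γ with M_genome the
length-weighted mean true mCG over annotated regions and M_ref the same
quantity in the reference wild type; γ = 1 by default, γ = 0 switches the
negative feedback off (used by the negative-control contrasts). In the
default met1 background G ≈ 1.9, which is what produces over-recovery
(efficiency > 1) in high-mCG regions.

**ibm1 layer.** Genic mCH approaches A × drive(m) × (1 − e^(−t/τ)) × G
with drive(m) = clip(m/0.6, 0, 1) (ungated — genic targeting responds to
arbitrarily low mCG once the demethylase is gone), A = 0.3 (CHG) / 0.1
(CHH), and τ = 3 generations, slow enough that consecutive generations
differ detectably through generation 4. TE mCH is simultaneously depleted
by the factor (1 − β × mean genic mCHG), β = 6 — the gene/TE trade-off.
In `ddm1_ibm1`, TE methylation is first reduced to 10% and G is
recomputed from the depleted genome, amplifying the genic gain.

**Sibling epivariants (Mi).** Each gbM gene independently loses its
epiallele per individual with probability 0.25; a lost gene *reverts to
the unmethylated-gene state* — its mCG is redrawn from the non-gbM
baseline distribution rather than set to zero, so individual-specific
genes are statistically indistinguishable from commonly hypomethylated
genes in the individual that lost them (the null the rank-sum comparison
relies on).

**Observation model.** Per cytosine: coverage ~ Poisson(λ = 20);
methylated count ~ Binomial(cov, p_obs) with
p_obs = p(1 − ε_over) + (1 − p)ε_non, ε_non = 0.005 (bisulfite
non-conversion → false methylation), ε_over = 0.002. Replicates (2 F1,
4 mF1 by default) are independent draws from a shared truth. A small
log-normal jitter (σ = 0.1) is applied to established mCH truth so
regions are not deterministic functions of their covariates.

All randomness flows from a single seed; per-sample and per-layer
substreams are derived by hashing stable labels (CRC32), so outputs are
byte-identical across runs and insensitive to evaluation order.

**What the generator does not emulate.** Sequence context is a label, not
a trinucleotide derived from sequence; there is no read-level (FASTQ)
simulation, no mapping bias, no chromosomal position effects
(pericentromeric clustering), no partial-methylation mosaicism within a
region, and no siRNA/RdDM pathway. Passing tests therefore establish that
the *analysis* recovers the structure the model plants at realistic count
noise — not that the model is a faithful emulation of any real methylome.

## Numerical and design choices

* Binned-curve crossing points are read by first upward linear
  interpolation between adjacent 50-gene bin means — deterministic, and a
  warning is logged if the curve is locally non-monotone.
* Epiallele presence is strictly "> 0.05"; equality counts as absence
  (the boundary case never arises in continuous data).
* Decile/rank ties: mid-rank for percentiles, region-id order for decile
  splitting.
* Undefined levels propagate as NaN through every stage; summaries report
  the contributing n alongside.
* Problem sizes in the test and acceptance suites (e.g. 500-gene genomes
  replicated over 100 seeds for the correlation diagnostic, 800-gene
  genomes for the crossing-point contrasts) are scaled-down study
  conditions chosen to keep seed-replicated checks cheap while leaving
  every measured effect far from its decision boundary.

## Known limitations

* The beta-binomial LRT relies on the χ²(1) asymptotics of a profiled
  likelihood; with very low counts (< ~20 reads per region) it becomes
  conservative rather than anti-conservative.
* `exclude_misannotated` keeps genes whose WT mCHG is undefined; on very
  sparse data this admits unassessed regions.
* The correlation matrix restricts all cells to genes with complete
  levels in every sample (comparability over coverage), which can shrink
  the gene set at low coverage.
* The global gain is recomputed from each genome's *true* mean mCG inside
  the generator; an analyst-side estimate of G from observed levels is
  deliberately out of scope — the diagnostics only test its signatures.
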