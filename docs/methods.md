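# Methods

## Scope and data model

The pipeline operates on per-locus multiple alignments of phased haplotypes
(gene copies) with exactly one outgroup sequence per locus, plus a study
configuration assigning each gene copy to an evolutionary lineage. All
coordinates are 0-based and half-open; for coding loci `frame_offset` gives
the first column of a complete codon and the codon region is truncated to a
multiple of three.

**Missing data.** Gaps and all IUPAC ambiguity codes are treated as missing.
Before any statistic is computed, *complete deletion* removes every column in
which any haplotype or the outgroup is missing; on coding loci whole codons
are removed so that the frame survives. This single policy is applied
consistently across π, D, H, the MK table and HKA inputs, which keeps the
site denominators of all statistics mutually consistent. The retained-column
map is kept so positions can be traced back to input coordinates. Partial
ambiguity information (e.g. R = A/G) is deliberately discarded.

## Site classification and divergence

Synonymous/nonsynonymous site counting follows Nei & Gojobori (1986): the
synonymous fraction of a codon position is the share of its three possible
single-base changes that preserve the amino acid; mutations to stop codons
count as nonsynonymous. A segregating site is classified by evaluating the
amino-acid effect of its two alleles with the other two codon positions held
at their majority state; a site is `complex` — excluded from class-specific
statistics but retained in all-site statistics — when it has more than two
alleles, lies outside the codon region, or shares a codon with another
segregating site whose background allele flips the classification.

Pairwise dN/dS uses NG86 counting with pathway averaging over minimal
mutational paths (paths through stop codons excluded) and the Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3). This is a deliberate substitution for a
codon-model ML estimator: the published long-term dN/dS values are consumed
as printed inputs by the comparative layer, so the estimator here is used
only for synthetic data and new datasets. Saturation (p ≥ 3/4) raises an
error rather than returning a truncated value.

Per-class mutation rates are calibrated from outgroup divergence as
μ_class = d_class/(2T/g) per site per generation, with T the outgroup
divergence time in years (default 18.4 My for *L. helveticus*) and g the
generation time (default 6 years, a mid-range figure for small-bodied
newts). Scaled per-locus rates follow as θ = 4·Ne·μ·L and ρ = 4·Ne·r·L.

## Frequency-spectrum statistics

The unfolded SFS is polarized by the outgroup residue; sites where the
outgroup carries a third allele, or with more than two ingroup alleles, are
unpolarizable — they count toward S, π and D but not toward the SFS or H.
Tajima's D uses the 1989 constants computed from the number of sampled gene
copies, with the pairwise-difference *count* (not per site) as θ_π. Fay &
Wu's H is the unnormalized per-locus statistic θ_π − θ_H, matching the
magnitude conventions of the per-gene report tables (values like −16.66 are
per locus, not per site). Statistics that are undefined (S = 0, or no
polarizable site) propagate as NaN and print as `NA`, never as zeros.

## Coalescent engine

A Hudson-style backwards-in-time simulator over the continuous locus [0, 1):
lineages carry ancestral-material segments; recombination splits a lineage
uniformly within its ancestral extent at rate ρg/2; coalescence merges two
lineages and records parent–child edges over the overlap, retiring genomic
regions once their local MRCA is reached. Per-segment counts of subtended
samples per sampling group are carried through every merge, so simulated
derived-allele counts (overall and per lineage) are available without tree
traversal.

**Units.** Time is measured in units of 2·N0 generations: the expected
pairwise coalescence time in a population of relative size 1 is 1.0, the
pairwise coalescence rate in a population of relative size x is 1/x,
migration acts at rate M/2 per lineage (M = 4·N0·m) and mutations fall at
rate θ/2 per unit branch length, giving the standard E[S] = θ·Σ 1/i.
Demographic events (size changes, backwards joins, migration changes) use the
same clock.

**Sweep emulation.** Incomplete selective sweeps are emulated genealogically
by a `sweep_merge` event: at the sweep time each lineage of the focal
population is, independently with probability f (the frequency reached by the
swept haplotype), caught by the sweep, and all caught lineages coalesce
instantaneously. This star-like collapse yields the excess of high-frequency
derived alleles (strongly negative H) and negative-skewed D characteristic of
recent incomplete sweeps. A population-wide crash-and-recovery history —
also available as a model builder — does *not* produce this signature: in
direct measurement it generates an excess of rare variants (positive mean H)
across the whole parameter grid we scanned, which is why the sweep emulation
is a partial coalescence rather than a size change. With f = 1 (a completed
sweep) H returns to ≈ 0, as expected: all sampled lineages join the collapse
and post-sweep variation is singleton-dominated.

**Mutation classes.** Mutations are dropped per edge as Poisson draws at
total rate (θ_syn + θ_nonsyn)/2, each labeled synonymous with probability
θ_syn/θ_total, with uniform infinite-sites positions. Null distributions for
D and H compute the statistic from each replicate's class SFS; ancestral
states are exact by construction, which makes the simulated H test slightly
anticonservative relative to real-data polarization through a finite
outgroup.

**Empirical p-values** carry a +1 pseudocount: one-sided-low
p = (1 + #{sim ≤ obs})/(1 + m); two-sided p doubles the smaller tail and caps
at 1. Fewer than 100 defined simulated values is an error, not a warning.
The default replicate number is 100,000 (overridable); tests and the
acceptance script use 1,000–5,000. Report tables star significance at
p < 0.01, two-sided for D and one-sided low for H.

**Determinism.** All randomness flows through one numpy PCG64 generator;
identical seeds and configurations give bit-identical output. Independent
sub-experiments derive child seeds via `SeedSequence.spawn`.

## MK and HKA tests

The MK table counts a site as polymorphic when ≥ 2 alleles segregate in the
ingroup (even if the outgroup differs) and as fixed when the ingroup is
monomorphic and differs from the outgroup; each counted site is classified
as above, with complex sites excluded and reported. Fisher's exact test uses
the standard two-sided convention (sum of hypergeometric point probabilities
≤ the observed one, via scipy, cross-checked in tests against exhaustive
enumeration); a zero margin yields p = 1 flagged untestable. NI is undefined
when Ps, Dn or Ds is zero.

The multilocus HKA fit solves the moment system E[S_i] = θ_i·a(n_i),
E[D_i] = θ_i(T + 1) — D_i being the mean pairwise ingroup–outgroup difference
count, T the divergence time in 2N units, equal ancestral and current sizes
assumed — by reducing to a single monotone equation in T (solved with
Brent's method, tolerance 1e-12) and computing X² with the 1987 variances
Var[S] = a1·θ + a2·θ², Var[D] = E[D] + θ². Significance comes from
re-simulating every locus under the fitted (θ_i, T) with the coalescent
engine and refitting each replicate. In place of an ML per-locus selection
parameter, per-locus leave-one-out drops in X² flag outlier loci; they are a
diagnostic, not an identity (they need not sum to X²).

## Rejection ABC

Plain rejection, no regression adjustment (left as an extension point). The
summary vector over the neutral panel has a fixed order: mean and variance
across loci of π per lineage and Tajima's D per lineage, between-lineage
divergence d_xy, and mean counts of shared and fixed polymorphisms.
Undefined per-locus D values are imputed as 0 (the neutral expectation)
before averaging. Summaries are standardized by their median absolute
deviation across the simulated table (constant summaries get scale 1 and
thus carry no signal), simulations are ranked by Euclidean distance and the
stated quantile is accepted, with stable-order tie-breaking so results are
deterministic given the table. Fewer than 20 accepted draws raises a
warning in the result. Model choice pools equal-sized per-model tables and
reports acceptance fractions. The default model family is two ingroup
populations splitting from a common ancestor with piecewise-constant sizes
and optional symmetric migration, the outgroup split fixed by the
divergence-time calibration; priors, models and tolerances are entirely
configuration — nothing here reproduces unpublished fitted values.

## Synthetic data generator

The generator emulates the study *design*, not its data: 38 + 34 ingroup
gene copies and one outgroup copy; 62 non-coding 0.5-kb loci; 11 coding loci
of 500–800 codons mixing constraint levels (c = 0, 0.1, 0.25, 0.4) with two
sweep-like loci in lineage B. Default rates assume θ = 4N0μ = 0.005 per site
(matching per-lineage non-coding diversity near 0.005) with an equal per-site
recombination rate; the ingroup split sits at 4.67 and the outgroup split at
12.27 in 2N0-generation units (≈ 7 and 18.4 My at 6-year generations and
N0 = 125,000). Constraint scales the nonsynonymous rate:
θ_nonsyn,eff = c·θ_nonsyn, applied equally to polymorphism and divergence, so
the expected neutrality index is 1 at any c.

Coding loci use a placement scheme that makes classification exact and
stop-free by construction: ancestral codons have pyrimidine (T/C) third
positions — no stop codon has a pyrimidine third base, every first/second
position single-base change is then nonsynonymous, and T↔C at the third
position is synonymous in every codon family. Synonymous mutations are T↔C
swaps at third positions; nonsynonymous mutations go to first/second
positions; each column hosts at most one mutation (infinite sites). Hence
`classify_segregating_site` recovers the generator's labels at 100% and no
generated haplotype contains a stop codon.

What the generator does **not** emulate: sequencing or phasing error,
missing data (complete deletion is a no-op on generated data), indels,
recurrent mutation, codon usage bias, gene conversion, background selection,
and true selective trajectories (sweeps are the genealogical emulation
above). Tests passing on synthetic data therefore demonstrate the machinery
is calibrated and internally consistent, not that real newt data would meet
model assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script scale the experiments to: simulator
moment checks at n = 10, θ = 2, 20,000 replicates (3-SE bands); null-test
calibration at n = 20, θ = 5 with a 4,000-replicate null against 2,000
observed loci (KS uniformity plus a 3σ binomial band around the 1% flag
rate); Fisher-exact agreement with exhaustive enumeration for every table
with total count ≤ 22 plus 500 random larger tables; ABC recovery over 50
synthetic studies of 20 samples × 15 loci against a 4,000-draw reference
table at tolerance 0.025 (observed bias ≈ 2%, coverage ≈ 98%); and sweep
detection on 40 sweep vs 40 neutral 800-codon loci against a 1,000-replicate
null (detection ≈ 25–35% at p < 0.01 vs ≈ 0–3% for neutral loci). HKA
simulation p-values in tests use 200–300 replicates; the production default
is 10,000.

Known limitations: the HKA variance formulas assume no recombination within
loci (conservative when ρ > 0); the coalescent engine models only
piecewise-constant sizes (no continuous growth); H is offered only in its
unnormalized form; and the NG86/JC divergence estimator underestimates
dN/dS under strong rate heterogeneity relative to codon-model ML.
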