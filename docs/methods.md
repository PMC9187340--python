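# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `hyperld`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## LD statistics

Both sites of a pair are polarized to their minor alleles before any
statistic is computed; at MAF exactly 0.5 the alphabetically first
allele is declared major, which makes the polarization deterministic.
r² is the squared Pearson correlation of the minor-allele indicator
vectors, computed from the closed form

r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)).

The signed statistic D = p_AB − p_A p_B distinguishes attraction
(coupling) of minor alleles from repulsion; r² is sign-blind. Because a
0/1 relabel of one site is undone by re-polarization, D is invariant
under relabeling — the sign is a property of the minor-allele
configuration, not of an arbitrary allele coding.

Singletons (minor allele in exactly one genotype) are excluded at
extraction time by default: with a few dozen genotypes a singleton's
r² to any other site is dominated by sampling noise. Columns containing
a gap or N in any genotype are excluded whole; there is no
per-genotype masking, so every statistic sees a rectangular matrix.

SNPs are classified synonymous/nonsynonymous independently, each
against the major-allele (consensus) background codon; a codon carrying
two segregating sites is still classified per SNP against that
background. This is the simplest convention consistent with treating
each polymorphism as an independent observation, and it is wrong only
for the rare codons where the background itself segregates at another
position; such codons are a small minority at the SNP densities the
package targets. Stop-gained changes count as nonsynonymous. Site
counts for pn/ps use NG86-style fractional weighting: each codon's
nine single-nucleotide changes are enumerated and the synonymous
fraction per position (k/3) is accumulated.

## Distance profiles, gene statistics, correlations

Pair distance is the absolute difference of 0-based positions; pairs
never span contigs. "Same gene" means both SNPs share a gene id;
different gene ids within the distance cutoff count as "adjacent
genes". The profile's standard error is computed across contigs
(population SD of per-contig cell means / √contigs), skipping contigs
with fewer than 10 pairs in a cell — a cell needs at least two
eligible contigs to get an SE.

The MAF-matched contrast resamples synonymous pairs (with replacement,
1000 draws by default, seeded) to the joint 2-D MAF histogram of the
nonsynonymous pairs at 0.05 bin width; MAF cells with nonsynonymous
but no synonymous pairs are excluded from both classes.

Per-gene LD uses only pairs within 300 nt (controls for gene length)
and drops genes with fewer than 100 such pairs. Spearman p-values use
the t approximation at n ≥ 30 and a seeded two-sided permutation test
(10,000 permutations) below that. Controlled correlations are computed
within quantile strata of the control variable (5 by default) and
combined by pooling within-stratum normalized ranks.

## Haploblocks

Windows are 250 nt on a 20-nt grid; a window is valid with ≥ 10
non-singleton SNPs, and its statistic is the mean r² over all SNP pairs
fully inside the window (pairs crossing the window edge belong to other
windows; this keeps windows independent of outside context). The
threshold is set where the empirical window-LD distribution becomes
heavy-tailed relative to a lognormal matched to the raw-scale mean and
variance: the smallest grid value t above the median (grid = empirical
quantiles 0.50–0.999 in 0.001 steps) with S_emp(t) ≥ 2·S_ln(t),
required to persist at every larger grid value with nonzero empirical
survival. The ratio 2 and the persistence requirement are this
package's operationalization of "heavy tail"; both are configurable.

Two properties of this rule matter in practice. On a pure lognormal
sample it stays silent (the acceptance suite measures ≥ 95% silence
over 100 replicates). And it fires on haploblock-like contamination —
a mass of windows at r² ≈ 1 — but *not* on arbitrary diffuse
contamination: a spread-out contaminant inflates the moment-matched
variance until the fitted lognormal covers it. Two-haplotype blocks
produce exactly the concentrated near-1 mass the rule detects.

Qualifying windows are merged into blocks by span overlap, per the
merging rule for continuous sequences of overlapping windows; blocks
are therefore non-overlapping by construction. Genome summary
fractions (blocks / background / unscorable) are computed over total
assayed length and sum to 1 exactly. Per block, each genotype's
minor-allele fraction over contained SNPs is reported; genotypes at
fraction ≥ 0.5 are assigned to the minor haplotype. Assignment is
always two-way; bimodality of the fractions is diagnostic output, not
a gate. Cross-population overlap compares observed joint coverage with
the product of marginal coverages over positions scorable in both
populations.

## Structure–LD tests

Contacts come from a residue-pair distance table or from atomic
coordinates (minimum heavy-atom distance by default, Cα–Cα as an
option; the defining atoms are a documented choice, not a data-derived
one). A residue pair is "close" within 10 Å; pairs with unknown
distance are excluded from both close and far sets.

The genome-wide test controls for sequence proximity by amino-acid
separation: pairs closer than 5 aa are excluded, and the null permutes
close/far labels *within* separation strata (each replicate redraws
the observed number of close pairs per stratum from the pooled
close+far pairs at that separation, without replacement). A literal
"resample far pairs with replacement" null is anticonservative —
it ignores the sampling variance of the far-pool mean — and fails
calibration; the within-stratum label permutation is exact under
exchangeability, which the acceptance suite verifies (rejection rate
at α = 0.05 within the binomial envelope over 200 null datasets).
Strata whose close pairs have no far pair within ±2 aa are dropped
from both sides.

The per-gene test restricts to 30–100 aa separations, calls r² at or
above the per-gene 0.9 quantile "high", requires ≥ 5 close pairs, and
summarizes the close/far × high/low table by an odds ratio (Haldane
0.5 correction when a cell is zero; chi-square on the raw counts, no
Yates correction). Benjamini–Hochberg FDR is applied across all
eligible genes of one population.

## Wright–Fisher simulator

Individual-based, biallelic, L sites, reversible mutation at rate μ
per site per generation, fitness-proportional multinomial parent
sampling, optional recombination (at most one crossover per
recombining offspring; the recombination parameter is the expected
crossovers per offspring per generation). Site classes follow a codon
layout: every third site synonymous, giving the 2:1
nonsynonymous:synonymous ratio. Fitness combines additively across
loci — per deleterious site s (haploid/homozygote) or h·s
(heterozygote), per epistatic pair an increment ε when both mutations
sit on one haplotype (ε = −2s·α; α = 1 is full compensation, and a
"ridge" shape makes one pair member individually neutral so three of
four combinations are fit), an NFDS site contributing
s_max·(1 − 2p), and AOD sites (h = 0, weakly deleterious) — with a
positivity floor of 1e-6. Additive combination matches the small-s
regime where it is indistinguishable from multiplicative.

The neutral finite-sites expectation used for calibration comes from
the pairwise coalescent: two lineages coalesce after T ~ Exp(1/N_c)
generations and differ at a site with probability (1 − e^(−4μT))/2,
giving E[π] = 2N_cμ / (1 + 4N_cμ) for N_c chromosomes. The helper
`scaled_mutation_rate` exposes the simpler μ = π/2N targeting rule
used to match a diversity level.

### Desk-scale study conditions

The canonical experiments run at haploid N = 200, L = 99,
100N generations, sample 100 genotypes, MAF > 0.05 — a drift-scaled
shrink of the original diploid N = 1000 setting that preserves the
population-scaled parameters (per-site θ, N·s). Four frozen conditions
(builders in `hyperld.sim`):

* **neutral** — μ = 2.5e-4 (the π/2N rule at π = 0.1); calibrates π
  against the coalescent closed form.
* **Hill–Robertson** — additive s = −0.05 (N·s = −10, the scaled
  analogue of diploid 2N·h·s at s = −0.01, h = 0.5), recombination 0:
  interference among linked deleterious alleles drives the
  nonsynonymous LD excess negative.
* **compensation + NFDS** — paired full compensation at s = −0.1 with
  s_max = 0.05 and a small recombination map (0.05 crossovers per
  offspring). The stronger per-site purging keeps lone deleterious
  mutants below the 5% MAF filter, so the qualifying nonsynonymous
  variants are the mutually compensated pairs held at intermediate
  frequency by the balanced polymorphism; the light recombination is
  load-bearing — with zero recombination the two balanced classes are
  asexual subpopulations whose deleterious-load fluctuations exceed
  s_max and destroy the balanced polymorphism (a Muller's-ratchet
  effect), while r per pair ≪ s preserves the selected coupling. The
  LD excess is positive here and near zero or negative without the
  balancing term or with partial compensation.
* **diversity grid** — compensation + NFDS at recombination 0 across
  μ ∈ {5e-4, 1.5e-3, 4e-3}: the excess rises monotonically with
  diversity (the hyperpolymorphism effect).

Because a typical compensated run has very few qualifying
nonsynonymous SNPs, `ld_contrast_experiment` reports both the mean of
per-replicate excesses (undefined replicates dropped) and a pooled
statistic (mean r² over all qualifying same-class pairs pooled across
replicates); the pooled form is the better-behaved estimator in the
sparse regime and is what the grid experiment uses.

Replicate counts (20–60 per condition) were chosen so that the
directional effects exceed their replicate standard errors at these
problem sizes; the directional outcomes remain stochastic, and the
tests assert signs and orderings, not magnitudes.

## Synthetic data

The generator emulates the statistical structure of a hyperpolymorphic
haploid panel: n = 30 genotypes (between the two real panel sizes),
background per-site polymorphism probability 0.08, a folded
neutral-like MAF law P(k) ∝ 1/k + 1/(n−k) truncated at singletons,
codon-structured genes on alternating strands (stop-free sense
codons), planted two-haplotype blocks whose SNPs are fully coupled to
a carrier set (within-block divergence 0.08/nt by default — the
realistic within-haploblock density for a population whose overall SNP
density approaches 0.3), and planted nonsynonymous pairs hitting a
requested r² via the carrier-overlap arithmetic (infeasible targets
raise with the feasible bound). Contact maps place within-segment
pairs at 4–8 Å and cross-segment pairs at 14–30 Å; the mirrored
constructor converts planted block spans inside a gene into residue
segments. A two-population mode re-plants shared SNP positions (same
alleles, independent carriers) at a configurable sharing fraction
(default 0.25).

What the generator does *not* emulate: linkage between background
SNPs (they are independent given the planted features), realistic
recombination maps, coalescent genealogies (use `hyperld.sim` for
model-based data), indels, alignment error, or three-haplotype blocks.
Passing the planted-recovery tests therefore demonstrates correctness
of the detection machinery under the stated generative model, not
performance on real alignments with genealogical correlation.

## Degenerate inputs and tie-breaks

Monomorphic state vectors raise rather than silently returning 0; a
class with fewer than two qualifying SNPs yields NaN, and genes
without synonymous sites report pn/ps as NaN (never infinity).
Blocks with fewer than two SNPs carry NaN statistics. The window grid
starts at 0 on every contig; contigs shorter than one window yield no
windows. All stochastic operations take explicit seeds and are
byte-reproducible.

## Known limitations

* The heavy-tail rule can stay silent when high-LD windows are diffuse
  rather than concentrated near r² = 1 (see above); for data without
  two-haplotype structure this is the intended behaviour but it bounds
  sensitivity to weak blocks.
* Diploid simulation supports at most one crossover per meiosis, and
  epistasis is evaluated in cis only (per haplotype).
* The cross-population machinery assumes inputs are already projected
  onto one reference coordinate system; no projection or liftover is
  performed.
* Contact maps are consumed, not discovered: homology search and
  structure alignment are outside scope, and the codon→residue map is
  the caller's responsibility (an identity map helper covers the
  synthetic case).
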