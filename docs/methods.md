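# Methods

## The question

Two populations are sampled; a third — the ghost — is not, but has
exchanged migrants with them. Every statistic below is computed twice:
from the two sampled populations only ("2-pop") and from all three
("3-pop"). The object of study is the difference, `bias =
statistic(2) − statistic(3)`, and whether that difference is detectable
from replicate datasets.

## Closed-form theory (island model)

Allele-frequency layer. For a biallelic site with frequencies
p_A, p_B, p_C, subpopulation heterozygosity H_S is the average of
H(p) = 2p(1−p) over included demes and total heterozygosity H_T is H of
the mean frequency; F_ST = (H_T − H_S)/H_T. When H_T = 0 (every included
deme fixed for the same allele) F_ST is *undefined*, returned as the IEEE
NaN sentinel — deliberately distinct from 0, which means "no
differentiation". NaN propagates through arithmetic, so anything derived
from an undefined value is undefined too.

Equilibrium layer. At drift–migration equilibrium F_ST = 1/(1+4·Ne·m).
Observing only the sampled pair leaves the per-generation migration rate
at m; observing all three demes averages inflow and outflow over two of
three sources, giving an observable rate of (2/3)m and
F_ST(3) = 1/(1+(8/3)·Ne·m). The equilibrium bias
1/(1+4Nem) − 1/(1+(8/3)Nem) is ≤ 0 for all m > 0 and vanishes at both
migration extremes.

Diversity layer. Without migration the bias of π̂(2) = (π_A+π_B)/2
against π̂(3) = (π_A+π_B+π_C)/3 reduces to (π_A+π_B−2π_C)/6 — negative
exactly when the ghost is more diverse than the sampled average. With
migration the three-population truth is the pooled mean pairwise
diversity (1/9)Σ_{i,j∈{A,B,C}} π_ij over ordered deme pairs, computed
from the full symmetric pairwise-diversity matrix.

Bias scans. The frequency-grid scan (default step 0.01) evaluates the
no-migration bias over all (p_A, p_B, p_C) and reduces over p_C three
ways: max |bias|, mean |bias| and mean signed bias. The caption-level
claim that the bias is small when p_A ≈ p_B holds only for the *positive*
part: on the diagonal F_ST(2) = 0, so the signed bias is non-positive and
can reach −1/3 when the ghost is divergent. The scan reports what the
algebra gives; the tests pin the diagonal sign and the off-diagonal
maximum.

## Stochastic engines

Wright–Fisher forward simulator. Discrete generations; per generation:
deterministic migration mixing (entry (i,j) of the forward composition
matrix is the fraction of deme i's gene pool replaced by migrants from
deme j), optional symmetric mutation, then binomial resampling of 2Ne
gametes per deme. Infinite deme sizes switch drift off. Used for the
π-bias scans: 3 demes of Ne = 5,000, 400 independent sites starting from
shared standing variation (site frequencies uniform on [0.05, 0.95]),
2,000 generations of divergence while the sampled demes receive a
fraction m of their gene pool from the ghost each generation. These
choices give visible but unsaturated drift divergence (0.2 × 2Ne
generations) at negligible cost; the qualitative bias pattern is
insensitive to them.

Structured coalescent. Continuous-time Gillespie simulation backwards in
time: with k lineages in a deme of diploid size Ne, coalescence at rate
k(k−1)/(4Ne) per generation; lineage migration i→j at the backward rate
rate[i][j] (per lineage, per generation); at a split event all lineages
in the derived demes move to the ancestor. Rates are defined among the
three leaf-era demes only; after a split, migration involving retired
demes is switched off and ancestral demes do not migrate. The event loop
is numba-compiled because the high-gene-flow topologies generate ~10^5
migration events per 60-leaf genealogy. Exactness is checked against
first-step-analysis linear systems (pairwise coalescence times, including
an asymmetric-migration case) and distributionally against msprime.

Mutation overlay. Infinite sites (Poisson on total branch length, fresh
uniform positions — used for theory-facing tests) or binary finite sites
(per-branch Poisson placement on uniformly chosen sites with 0↔1 flips,
allowing recurrent hits — the default). At 1 kb and μ = 10⁻⁸ the two are
practically indistinguishable; finite sites is kept as the default
because it is the more honest model of a physical locus.

## The model grid

Five topologies share Ne = 5,000 everywhere, μ = 10⁻⁸/site/generation,
20 unlinked 1-kb loci, 10 diploid individuals (20 haplotypes) sampled per
population, and a sampled-pair migration composite of 0.05. They differ
in ghost gene flow: none (a); unidirectional out of the ghost at 0.05 (b)
or 0.5 (c); bidirectional everywhere at 0.05 (d); bidirectional
ghost↔sampled at 0.5 with the sampled pair at 0.05 (e). Divergence is
either recent — both splits at 1,850 generations, i.e. the ghost and the
sampled pair separate simultaneously (overrides exist for staggered
splits) — or deep, with the sampled pair
splitting 17,241 and the ghost 68,966 generations ago. A generation is
29 years.

Migration units. The values 0.05/0.5 are interpreted as 4Ne·m
composites: the backward per-generation per-lineage rate is m/(4Ne_src)
(`migration_units="coalescent_4N"` on the model). Read instead as raw
per-generation probabilities they correspond to Nm ≈ 250–2,500, which
makes every ghost-connected topology effectively panmictic and erases all
of the documented gradients (diversity rising a→c/e, three-population
F_ST falling a→e, the deep-divergence strategy contrast); the composite
reading produces them. Theory-facing scans that sweep m up to 0.1 as a
per-generation rate use `migration_units="per_generation"` explicitly.

## Estimators

All statistics are computed on phased haplotype matrices restricted by a
sampling strategy. S counts sites polymorphic *within the restriction*;
θ_W = S/a₁ with a₁ the harmonic number of n−1. π comes in the printed
frequency form Σ 2p(1−p) and the bias-corrected pairwise form (× n/(n−1));
Tajima's D uses the pairwise form, as its definition requires, normalised
by √(e₁S + e₂S(S−1)) with the standard constants, and is undefined (NaN)
at S = 0 — undefined loci are excluded from averages and counted. F_ST
is Weir & Cockerham's variance-components estimator in haploid form
(phased haplotypes carry no heterozygosity term), combined across sites
and loci as a ratio of summed components (the stable convention;
mean-of-ratios is available behind a flag). Negative estimates are
reported as-is. The four-gamete filter finds all site pairs showing all
four gametes and returns the longest contiguous violation-free block,
leftmost on ties.

## Experiments and the permutation test

The grid runner simulates every (model, divergence) cell with its own
counter-derived seed, summarises each replicate under both strategies and
emits a tidy table. The strategy contrast is a label permutation test on
per-replicate values of mean F_ST and mean π: statistic |mean(2-pop) −
mean(3-pop)|, 10,000 label shuffles, add-one p estimator
(1+#{null ≥ obs})/(n_perm+1), two-sided by construction. Values are
pooled over the ghost-gene-flow topologies b–e; model a is the no-ghost
control and per-model p-values are also emitted. Because the scheme
itself (what is permuted, how many shuffles, sidedness) is a design
choice, it is fixed here once: it is the simplest test consistent with
"difference of strategy means". When one headline number is wanted per
grid, the worst case for the claim is reported: the *larger* of the
FST/π p-values for the deep grid (both must be small) and the *smaller*
for the recent grid (both must be large).

## What the simulations do and do not show

The generator emulates neutral, constant-size, non-recombining loci with
known phase and known ancestral states, under exactly three demes and
piecewise-constant migration. Real data add recombination, selection,
size changes, phasing and polarisation error, and more complex topologies
— so a passing contrast here shows detectability *in the best case*; a
failure to detect (the recent grid) is therefore conservative evidence
that summary statistics cannot expose a recently diverged ghost. The
permutation p-values are stochastic at study scale (10 replicates per
model): the recent-grid p hovers well above the significance threshold on
most seeds but is not deterministic.

## Numerical choices

- Undefined statistics are NaN sentinels, never silent zeros; a helper
  `is_defined` makes the checks explicit.
- All stochastic entry points take one root seed; per-(replicate, locus)
  substreams are derived by counters (`SeedSequence([seed, rep, locus])`),
  so a run is reproducible and any locus can be regenerated alone.
  Kernel seeds are reduced below 2³¹.
- Coordinates are 0-based half-open internally, 1-based in VCF export.
- Ties in the four-gamete filter resolve to the leftmost block; ties in
  event times (the recent scenario's simultaneous splits) are processed
  in listed order, sampled-pair merge first.
- Grid cells that raise are recorded as failed rows and the grid
  continues; undefined statistic values are dropped from permutation
  groups.

## Known limitations

- No recombination within loci, no selection, no size changes other than
  instantaneous splits; ancestral demes exchange no migrants.
- The Wright–Fisher and coalescent engines are not coupled: the π scan's
  forward model and the D scan's coalescent model answer the same
  qualitative question with different machinery.
- IMa3 files are written, never read back or validated against IMa3
  itself; MCMC demographic inference is out of scope.
- The four-gamete filter treats recurrent mutation and recombination
  identically, as any four-gamete method must.
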