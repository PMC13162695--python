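# Methods

`suspop` re-creates, on synthetic data, the analysis chain used to study the
demographic origin of high-altitude Tibetan pigs relative to Asian wild
boars: coalescent simulation of competing origin scenarios, composite
likelihood comparison of those scenarios on the multidimensional site
frequency spectrum (SFS), allele-frequency introgression statistics, topology
weighting, and a three-statistic selective-sweep scan. This note records the
models, the numerical choices, and what the synthetic world does and does not
establish.

## Coalescent simulation (`simgen`)

Genotype data are generated with msprime under demographies composed of
population splits, instantaneous admixture pulses (backward-time lineage
reassignment with probability alpha) and stepwise size changes — the standard
continuous-time coalescent with rate k(k-1)/(4Ne) per population. Mutations
are infinite-sites and biallelic, dropped on branches in proportion to branch
length at rate mu per site per generation, with the ancestral state known by
construction. Genomes are built from independent non-recombining blocks laid
end to end on one synthetic chromosome: linkage exists within a block and not
between blocks. Recombination within blocks is deliberately not simulated —
SFS fitting needs only unlinked sites, and window statistics only need
block-scale linkage.

Two modes: `sequence` emits every mutation on every block (window statistics,
topology weighting); `snp` emits exactly one segregating site per block,
resampling blocks with no mutation (unlinked-SNP data for SFS work).

One property of snp mode deserves note: keeping a single site per block is an
ascertainment. When the per-block mutation supply theta x T is much below 1,
retention probability is proportional to total tree length and the scheme
reproduces the site-weighted (true) SFS; when theta x T is large, almost
every block is retained once regardless of its tree length, which
under-weights long genealogies and measurably inflates the singleton class
(detectable by chi-square around 5e4 SNPs). This is inherent to
one-SNP-per-locus simulation, not an implementation defect; neutrality
calibration therefore uses short blocks, while the model-comparison datasets
accept the mild, model-shared ascertainment (all candidate models face the
same data, and parameter recovery stays within the stated tolerances).

Scaling constants follow pig resequencing practice: mu = 3.6e-9 per site per
generation and a 3-year generation time (the latter is reporting-only).

### The fixture worlds

The study system is emulated with an outgroup (CEB, *S. cebifrons*-like), a
western Eurasian wild boar group (WEW), northern and southern Asian wild
boars (NAW, SAW), the focal Tibetan group (TT) and a derived Tibetan group
(X). No true parameter values exist for these scenarios (only topologies),
so the defaults below are stated once and recorded in every fixture's
metadata:

| parameter | value | rationale |
| --- | --- | --- |
| Ne (NAW, SAW, ancestral) | 10,000 | typical wild boar diversity scale |
| Ne (WEW, CEB) | 5,000 | lower western/outgroup diversity |
| Ne (TT, X) | 3,000 | founding bottleneck of domestic highland pigs |
| NAW/SAW divergence | 10,000 gen (~30 ky) | deep north/south split |
| WEW split | 25,000 gen | western Eurasian divergence |
| CEB (outgroup) split | 50,000 gen | compressed: see below |
| TT founding | 3,000 gen (~9 ky) | domestication era |
| X split from TT | 1,000 gen (~3 ky) | recent regional divergence |
| TT admixture fraction alpha (SAW share) | 0.5 | balanced mixed origin |

The true pig/*S. cebifrons* divergence is far older (millions of years); at
that depth nearly all synthetic SNPs would fall on the outgroup stalk and be
useless after polarization, so the outgroup split is compressed to 5e4
generations. This preserves the *mechanism* being tested (outgroup
polarization with flips and drops) while keeping a workable fraction
(~60%) of SNPs informative at desk scale.

The generic quartet used by the introgression and topology fixtures
(((P1,P2),P3),OUT) uses splits at 4e3 / 1.6e4 / 4e4 generations with
Ne = 7,500 and, where gene flow is present, a P3->P2 pulse at 400
generations. These values give distinct species structure: incomplete
lineage sorting is present but does not swamp a strong (alpha = 0.3) pulse.
The `introgressed_tract` fixture embeds blocks simulated with a strong pulse
(alpha = 0.6) inside a no-flow background; `hard_sweep` overwrites a 200-kb
focal region in the target population with one core haplotype at frequency
0.95 on a neutral two-population background (its genealogies are no longer
meaningful inside the swept region).

What a green test on these worlds does **not** establish: behaviour under
recombination within loci, sequencing error, missing data patterns of real
resequencing, reference bias, or realistic outgroup depth.

## SFS construction (`sfs`)

Sites enter the observed SFS after four filters — intergenic, outside CpG
islands (both taken as input annotations), fully genotyped, and thinned to a
minimum 2-kb spacing with a greedy left-to-right rule — and after outgroup
polarization: the allele carried by every non-missing outgroup haplotype is
ancestral; sites with a polymorphic or fully missing outgroup are dropped.
"Confidently inferred ancestral" is operationalized as outgroup monomorphism,
the natural rule for a two-individual outgroup.

The multidimensional SFS counts sites by their joint derived-allele counts;
monomorphic corners are masked everywhere (all likelihoods condition on
polymorphism). Folding maps each entry onto its minor-allele class; an
exact-half entry is assigned once, to the lexicographically smaller member of
the complement pair. Projection to smaller sample sizes is the standard
hypergeometric expectation, applied per population axis; totals are
conserved by both operations.

## Demographic scenarios (`demomodels`)

Ten templates over a fixed deep scaffold (outgroup split, WEW split, NAW/SAW
divergence), so composite likelihoods are comparable across models; only the
TT/X-relevant parameters are free:

* TT1/TT2 — TT splits from NAW / SAW (free: N_TT, T_TT).
* TT3/TT4 — split from NAW / SAW plus a later pulse from the other lineage
  (free: N_TT, T_TT, pulse-time ratio r, alpha).
* TT5 — instantaneous admixed founding; alpha is the SAW-derived fraction
  (free: N_TT, T_TT, alpha). At alpha = 0 or 1 it degenerates to TT1/TT2.
* X1 — X splits from TT; X3/X4 — X splits from NAW/SAW after TT's founding;
  X2/X5 — X has its own admixed founding, older (X2) or younger (X5) than
  TT's. TT's founding parameters are fixed at scaffold values in X models.

Bounds: Ne in [1e2, 1e6] and times in [10, 1e5] generations, both searched
in log10; admixture fractions in [0, 1] linear. Ordering constraints (e.g.
X2's founding older than TT's) are enforced through bounds and named
`ordering` checks. The TT3/TT4 pulse time is parametrized as r x T_TT with
r in [0.05, 0.9]: "subsequently received gene flow" means the pulse is
strictly later than the split, and without the cap TT3/TT4 contain TT5
exactly as their r -> 1 boundary. Even with the cap the boundary optimum of
TT3/TT4 approximates TT5 to within a few log-likelihood units at desk-scale
site counts — the model-comparison consequences are handled by the ranking
rule below.

## Composite-likelihood fitting (`sfsfit`)

The expected SFS under a parameter vector is estimated by Monte-Carlo
coalescent simulation in a compiled (numba) kernel: each simulated genealogy
contributes every branch's length to the spectrum entry indexed by the
branch's descendant counts (a lower-variance estimator than one SNP per
simulation, with the same estimand). Outgroup lineages are simulated too,
and polarization is modelled exactly as the data path applies it: a branch
subtending *all* outgroup haplotypes yields a flipped (mispolarized) entry; a
branch subtending only some outgroup haplotypes yields an
outgroup-polymorphic site, which contributes nothing. Entry probabilities
are normalized over unmasked entries; zero entries are floored at
1/(10 n_sims) and renormalized so likelihoods stay finite.

Likelihoods are in log10: lnL = sum m_i log10 p_i over unmasked entries; the
saturated likelihood uses p_i = m_i/S. Model fit is delta = lnL_obs -
lnL_est (lower is better) and AIC = 2k - 2 ln(10) lnL_est.

Optimization mirrors the two-stage cycle protocol of SFS fitting practice
(an initial tranche of cycles at reduced simulation count, then full-count
cycles; many independent runs from random in-bounds starting values). Each
cycle draws its own seed, re-evaluates the current simplex under that seed
(common random numbers within the cycle) and performs a short Nelder-Mead
descent; the simplex persists across cycles so its shape can adapt to
likelihood ridges (N-T-alpha are strongly correlated), and is re-inflated
around the incumbent when Monte-Carlo noise collapses it. Out-of-bounds
proposals are rejected (infinite objective) and the run continues.

Reported likelihoods are re-evaluated after the last cycle with seeds shared
across runs *and* across model templates (common random numbers for model
comparison); the winning run of each template gets three replicate
evaluations at 40x the search simulation count, yielding the reported
likelihood and its Monte-Carlo standard error. `compare_models` ranks by
delta, but two models whose deltas differ by less than `tie_sigma` (default
2) pooled standard errors cannot be ordered on delta and fall back to AIC,
then to fewer parameters. This matters precisely for the nested-boundary
case above: at 2e4-4e4 sites the fitted TT3/TT4 boundary optima sit within a
few units of TT5's optimum, below any affordable Monte-Carlo resolution, and
the AIC penalty (0.43 log10-units per parameter) is then the only meaningful
discriminator — the same role AIC plays in the reference analysis.

Bootstrap confidence intervals are parametric: S sites are multinomially
resampled from the expected SFS at the best-fit parameters, each replicate
is refit, and 2.5/97.5 percentiles are reported. (Whether the reference
protocol's bootstrap was parametric or block-resampled is not stated; the
parametric choice matches the composite-likelihood model being fitted.)

## Introgression statistics (`introgression`)

D uses the frequency estimator with the outgroup fixing the ancestral state:
per usable site (every population genotyped, outgroup monomorphic),
ABBA = (1-p1) p2 p3 and BABA = p1 (1-p2) p3; D = (sum ABBA - sum BABA) /
(sum ABBA + sum BABA); the standard error is a delete-one block jackknife
over contiguous blocks (default one block per simulated locus; 5-Mb blocks
for real-scale data), and |Z| > 3 is called significant. Outgroup f3 is the
mean of (pO - pA)(pO - pB) with the same jackknife.

f_d divides D's numerator by a donor-maximized denominator (p_D =
max(p2, p3) substituted in both donor roles) over sliding windows of 100
usable SNPs with 50-SNP steps; windows with negative numerator or
non-positive denominator are set to 0 and values are capped at 1. Candidate
excess-sharing windows are the top ceil(q N) by value (q = 1% by default);
window-set overlap counts windows of A sharing >= 1 bp with any window of B.

Topology weighting operates on the simulator's true genealogies: per locus,
one haplotype per group is drawn repeatedly, the rooted quartet topology is
classified by which ingroup pair has the most recent common ancestor, and
per-locus weights (summing to 1) are combined genome-wide with locus-length
weighting. Inferring local genealogies from genotypes is out of scope.

## Sweep scan (`sweeps`)

Windows are anchored at position 0, half-open, 50 kb with 20-kb steps.
Nucleotide diversity is sum over sites of 2 p (1-p) n/(n-1) divided by the
window length; the diversity-reduction signal is log10(pi_reference /
pi_target) with zero-diversity windows dropped. Differentiation is
Weir-Cockerham (1984) windowed Fst, sum(a)/sum(a+b+c), matching the common
VCFtools default; windows with zero denominator are dropped.

XP-EHH: extended haplotype homozygosity is the fraction of haplotype pairs
identical at all SNPs from the core (exclusive, so EHH = 1 at the core
itself) out to the current SNP, computed per population but truncated where
the *pooled*-sample EHH drops below 0.05 or at gaps > 200 kb; iHH integrates
EHH over physical distance by trapezoid in both directions (physical distance
stands in for genetic distance; no genetic map exists for the fixtures).
The raw score ln(iHH_target/iHH_reference) is standardized genome-wide to
mean 0, sd 1; positive scores mean longer haplotypes in the target. Site
scores are aggregated to the window grid by maximum.

Candidate sweep regions are the >= 1-bp intersection of the top-5% window
sets of the three statistics, merged; genes overlap regions by >= 1 bp under
half-open coordinates. Quantile cutoffs are data-derived, never constants.

## Numerical and scale choices

* All randomness flows from user seeds through `numpy.random.SeedSequence`;
  fixed seeds reproduce every artifact byte-for-byte.
* The numba kernel avoids non-finite sentinels (fastmath) and prunes
  populations no sampled lineage can reach.
* Desk-scale defaults (n_sims = 10k, n_runs = 20 in the CLI; smaller in the
  test suite) are scaled-down stand-ins for the reference protocol
  (100 runs x 100k simulations, 25/65 cycles, 100 bootstrap replicates
  each refit 100 times); the test suite's constants are documented at the
  top of `tests/test_acceptance.py` and the asserted thresholds are not
  scaled.
* The delta statistic is standardized as lnL_obs - lnL_est with lower =
  better; one reference description calls the best model the one with the
  "highest" delta, which is inconsistent with the definition used here and
  is treated as an editorial slip.

## Known limitations

* Expected-SFS estimation and data generation share the coalescent model
  family; the cross-check between the numba kernel and msprime (chi-square
  agreement test) guards against implementation errors, not model
  misspecification.
* At desk-scale site counts the TT3/TT4-vs-TT5 comparison rests on the
  AIC-backed tie rule (above); at the reference scale (~3e7 SNPs) the
  likelihood separation itself would dominate.
* XP-EHH uses physical distance and max-aggregation to windows; selscan's
  map-file and per-site normalization variants are not reproduced.
* The CpG and genic annotations of synthetic data are uniformly benign
  (`intergenic`, non-CpG); the filters are exercised by toy matrices in the
  unit tests, not by the coalescent fixtures.
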