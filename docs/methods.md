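# Methods

`mosaictrace` re-implements, as a tested library, the analysis chain used to
dissect recently admixed human genomes against continental reference panels:
population-structure summaries, local ancestry painting, ancestry masking,
four-population admixture tests, supervised ancestry proportions, and
admixture dating from ancestry tract lengths. Because the motivating kind of
dataset (a handful of admixed genomes plus public reference panels) is rarely
redistributable, the package ships a forward simulator that generates admixed
genomes with exact ancestry truth, and every estimator is validated against
that truth.

## Synthetic data model

**Reference panels.** Per-population allele frequencies follow the
Balding–Nichols model: given an ancestral frequency `p ~ Uniform(0.05, 0.95)`
and a differentiation parameter `F` (an FST analogue, default 0.15 for every
continental panel — typical of between-continent human differentiation on
genotyping-array SNPs), each population draws
`f ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` independently per site. Panel haplotypes
are i.i.d. Bernoulli(f) per site; the derived allele is coded as ALT and the
ancestral allele annotation (INFO/AA) always equals REF in simulated data.
Sites are spread uniformly in genetic distance over a constant-rate genome
(default 22 chromosomes of 1.5 Morgans at 1 cM/Mb, ≈33 M total, close to the
human autosomal map).

**Admixed genomes.** A pulse history is a founding ancestry plus dated
migration pulses `(T, ancestry, m)`. The simulator runs a random-mating
Wright–Fisher population of `pop_size` diploids (default 500) forward in
time; meiosis places crossovers by a Poisson process of rate 1 per Morgan
without interference. A pulse `T` generations ago replaces each *haplotype*
of the receiving generation independently with probability `m` by an
unadmixed migrant haplotype. The gamete-level convention is deliberate:
it makes every one of the `T` post-pulse meioses capable of creating an
ancestry junction, so junction density is `T` per Morgan and expected final
fractions compose as products across pulses — exactly the convention assumed
by the tract-length likelihood below. (Under individual-level replacement the
first post-pulse meiosis recombines two same-ancestry haplotypes and the
junction density is `T−1`; the literature uses both conventions, differing by
one meiosis. The simulator and the likelihood must share one convention, and
we validated empirically that the implemented pair is self-consistent:
fitting simulations at T ∈ {3, 5, 13, 20} recovers T̂ ≈ T.)

**What the simulator does not emulate.** No LD within reference panels
(irrelevant for frequency-based statistics; window-PCA painting draws its
signal from between-panel differentiation, not within-panel LD), no
recombination-rate variation beyond piecewise-linear maps, no selection, no
phasing or genotyping error, and no X chromosome. Passing tests therefore
demonstrate correctness of the estimators under the model's assumptions, not
robustness to real-data artefacts such as switch errors or reference bias.

## Local ancestry painting

Phased reference haplotypes are tiled into windows of `window_size`
consecutive SNPs (default 30). Per window the reference haplotype matrix is
mean-centered and reduced by SVD to `n_pcs` components (default
`max(2, K−1)`); each panel's scores define a Gaussian class with its own mean
and a pooled diagonal covariance floored at 1e-6 (stable at small panel
sizes). Query haplotypes are mean-imputed, projected, and scored; window
log-likelihoods are smoothed by a continuous-time HMM along the genetic map:
between windows `d` Morgans apart, ancestry is carried over with probability
`exp(−ρd)` and otherwise redrawn from the prior. The switch rate ρ defaults
to 10 per Morgan — the order of the expected generation depth of recent
admixture; it trades off smoothing against sensitivity to short tracts and is
deliberately not tuned per dataset. Windows whose posterior maximum reaches
the threshold (default 0.8, ties pass) are assigned; others stay
"unassigned" and break tracts. Tract boundaries fall midway between window
midpoints, extended to the chromosome ends. Monomorphic windows are flagged
uninformative and contribute only the prior.

On the default synthetic panels (FST 0.15, 30-SNP windows) window-level
calling accuracy against truth exceeds 95 %. The resolution limit matters
downstream: tracts shorter than a few windows are absorbed by the HMM, so
tract-dating from painted calls underestimates the pulse age, which is why
the scenario report shows call-based and truth-based fits side by side.

## Masking and masked PCA

Masking sets to missing every haplotype allele outside segments called as
the kept ancestry (unassigned included); downstream frequency code uses
non-missing haplotypes only, so diploid sites may become hemi-informative.
Masked PCA operates at haplotype level (so ancestry-heterozygous diploids
still contribute their target-ancestry haplotype segments), mean-imputes
missing entries per site, and drops haplotypes retaining under 5 % of sites.
Mean imputation is the simplest deterministic choice; it shrinks heavily
masked haplotypes toward the origin rather than inventing structure.

## IBS, MDS, relatedness

IBS between diploids is the mean of `(2 − |g_i − g_j|)/2` over co-observed
sites. Classical (Torgerson) scaling of `d = 1 − IBS` double-centers
`−d²/2`, eigendecomposes, and scales the top-k eigenvectors by the square
root of their eigenvalues; axis orientation is arbitrary and negative
eigenvalues (non-Euclidean distances) are counted and reported, never
silently clipped into coordinates. The relatedness screen is the
method-of-moments identity-by-descent decomposition: observed IBS-state
counts are equated with their expectations under IBD ∈ {0,1,2} given panel
allele frequencies, solved sequentially, truncated to [0,1] and
renormalized; `PI_HAT = P(IBD1)/2 + P(IBD2)` with a flag above 0.1875 (the
conventional midpoint between second- and third-degree relatives). No formal
p-value is attached: the moment estimator has no clean finite-sample null.

## D-statistics

`D(P1,P2;P3,O) = Σ(p1−p2)(p3−p4) / Σ(p1+p2−2p1p2)(p3+p4−2p3p4)` over sites
with complete frequencies, polarized so the outgroup carries the ancestral
state; `D > 0` means P1 shares excess derived alleles with P3. By default
the ancestral allele itself is the outgroup (`p4 ≡ 0`), which sidesteps the
genotype-encoding ambiguity of a synthetic all-ancestral sample; the
synthetic-sample route (`build_ancestral_outgroup`, in both the published
0/1 encoding and a strict 1/1 mode) is retained and agrees exactly with the
direct route in strict mode. Standard errors come from a leave-one-block-out
jackknife over contiguous 5 Mb physical blocks (last partial block kept),
weighted by block informative-site counts (Busing's unequal-weight
delete-one formulas); significance is `Z = D/SE` with the conventional
threshold Z < −2. Under a simulated null, Z is standard normal to within
the suite's calibration band (SD ∈ [0.8, 1.25], |Z| < 3 in ≥99 % of 200
replicates).

Power note: with a two-haplotype target the per-site binomial noise of the
target frequency dominates the SE, and ~10⁵ sites are needed before a
~10 % shared-drift signal clears |Z| = 2. The built-in scenario therefore
pools several painted target individuals as the focal group.

## Supervised ancestry proportions

For one individual with dosages `g_s` and fixed panel frequencies `f_ks`,
the fractions `q` maximize
`Σ_s [g_s log Σ_k q_k f_ks + (2−g_s) log Σ_k q_k (1−f_ks)]` on the simplex.
EM on allele-wise responsibilities converges monotonically (asserted at run
time); with `f` fixed the problem is concave in `q`, so the uniform start is
benign. Frequencies are clipped to `[1e-6, 1−1e-6]`; exactly duplicated
columns are flagged non-identifiable and the symmetric start returns the
uniform split among the tied ancestries. Convergence: ΔlogL < 1e-7, cap
2000 iterations.

## Tract-length dating

Along the genetic map, ancestry under a single pulse (fraction `m` of
ancestry A, `T` generations ago) is approximated by a two-state Markov jump
process: junctions at density `T` per Morgan, each redrawing ancestry from
`(m, 1−m)`, hence exit rates `r_A=(1−m)T` and `r_B=mT` per Morgan. The
likelihood of a tract set is `log π(first state)` per contiguous segment,
plus `log(exit rate)` at each interior junction, minus `rate × length` for
every tract; chromosome ends and unassigned call gaps censor the flanking
tracts, which then contribute only the survival term (this avoids the length
inflation of bridging gaps). Fitting is a coarse grid (`T ∈ 1..50`,
`m ∈ 0.01..0.99`) evaluated from six sufficient statistics, followed by
L-BFGS-B refinement with `T` continuous; `T` is reported both raw and
rounded. Years = generations × 30 by convention.

The three-ancestry history is fitted by a marginal approximation rather than
the full multi-state Markov model: the youngest pulse ancestry is fitted
against the pooled complement, and the two older ancestries are fitted with
the youngest ancestry's tracts excised, every excision boundary treated as
censoring (flanks are not concatenated). The approximation is accurate for
the youngest pulse (T̂₂ within ±2 generations, fraction within ±0.04 in the
suite) but biases the older event's T̂₁ low by roughly the factor
`(1−n)` — the excision thins older junctions without the likelihood knowing;
this is flagged in the output as an approximation.

**Accuracy of the Markov approximation itself.** The exponential tract law
is a large-population, long-chromosome limit. Two finite-size effects are
measurable at desk scale: (i) uncensored tracts are conditioned to complete
inside a chromosome, biasing their empirical distribution by roughly
mean-length/chromosome-length (~6 % on 1.5 M chromosomes at T=13); (ii) with
2N = 1000, drift spreads the realized admixture fraction (SD ≈
√(m(1−m)T/2N) ≈ 0.03), so pooled tracts are a mixture of exponentials.
Distributional tests therefore run at pop ≥ 1500 on 8–10 M chromosomes,
where both effects are negligible; the parameter-recovery tests run at the
study conditions (pop 500, 22 × 1.5 M), where the maximum-likelihood fit —
which models censoring explicitly — still recovers T and m (median T̂ = 13,
m̂ within half a point of 88.1 %, across ten seeds).

## The built-in scenario

`pipeline.run_scenario` wires the stages together under one seed (every
stage draws from a named substream, so reports are byte-reproducible):
Balding–Nichols panels for African, European, Native American and East
African ancestries (100 haplotypes each, FST 0.15); an East African panel
confounded with 40 % European admixture at the frequency level — realistic
for Horn-of-Africa reference panels and the ingredient behind the masking
artefact; 42 admixed diploids from the pulse history *(founding African;
11.9 % European at generation 13; 11.6 % Native American at generation 10)*
typed at 150,000 sites (the scale of the corresponding published D
analyses); painting of 6 target individuals; the four D-test configurations
(Native, European, East African unmasked, East African after African
masking); supervised-EM fractions; and tract-length dating on both truth
and called tracts. The expected qualitative result, reproduced in ≥8/10
seeds by the acceptance suite: Native and European gene flow strongly
significant; East African "gene flow" significant *only* before masking —
the spurious signal is the European ancestry shared between the target and
the confounded panel, and it vanishes once the target is reduced to its
African segments.

## Numerical and degenerate-input choices

Missing alleles are coded −1 end to end and excluded from frequencies;
frequencies are NaN where no haplotype is observed. PCA uses the exact
full-SVD solver (the randomized solver is silently nondeterministic at
panel-sized inputs). Posterior rows are renormalized after forward–backward
scaling; emissions are max-shifted before exponentiation. Zero-variance
windows fall back to the prior. A jackknife whose leave-one-out estimates
are all identical raises rather than reporting Z = ∞. The EM raises if its
log-likelihood ever decreases by more than 1e-8. Grid likelihoods at
`m ∈ {0,1}` are −∞ by the open-interval constraint. Ties in posterior
calling pass at exactly the threshold; ties in model ranking are broken by
model name for stable output.

## Known limitations

Painting resolution censors the tract-length spectrum below a few window
widths, so call-based dating is biased recent; use truth tracts (simulation)
or accept the bias (real data). The marginal two-pulse fit is not a full
multi-ancestry Markov likelihood and should not be used to compare histories
with more than two pulses. The D-statistic module assumes biallelic sites
with a known ancestral state; sites with missing or mismatching ancestral
annotation are dropped, which on real data can be a non-random filter. IBS
and IBD treat genotypes as unphased dosages and ignore LD, as is standard
for these screens.
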