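# Methods

This note records the models implemented in clinekit, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Hybrid index

Given a diagnostic panel (loci where two parental reference panels are
fixed for alternative alleles after missing-data exclusion, thinned to one
locus per 10 kb window with the lowest-position SNP kept — a deterministic
tie-break), each non-missing allele copy of an individual is P1-derived
independently with probability *h*. The likelihood is therefore binomial
in the P1-copy total; female Z loci and mtDNA contribute one copy
(hemizygous/haploid), not two, and female Z heterozygote calls in input
VCFs are treated as genotyping artifacts and set to missing (counted and
logged). mtDNA pseudo-chromosomes are excluded from the nuclear panel so
the uniparental mitotype cannot leak into *h*.

- Prior: Beta(0.5, 0.5) (Jeffreys), configurable. It is conjugate here, so
  the sampler is validated against the closed-form posterior mean
  (k + 0.5)/(n + 1); the MCMC exists for interface parity with the cline
  samplers and to supply draws/credible intervals uniformly.
- Sampler: random-walk Metropolis on logit *h*, per-chain step sizes
  adapted every 100 burn-in iterations toward 20–50% acceptance, frozen
  afterwards. Defaults 5,000 burn-in / 10,000 retained.
- Samples with no diagnostic data get the prior back, flagged.

Hybrid classes: F1 iff het ≥ 0.95 and |h − 0.5| ≤ 0.05; parental-like iff
h < 0.1 (or > 0.9) and het < 0.1 — the same thresholds as the
least-admixed filter used for windowed F_ST cohorts; everything else is
"admixed/backcross". All thresholds are arguments.

## Genomic clines

φ(h; v, c) = logistic(v (logit h − logit c)) is the probability that an
allele copy at the focal locus is P1-derived in a carrier with hybrid
index h. v = 1, c = 0.5 is the identity (genome-average transition);
φ(0) = 0 and φ(1) = 1 by continuity (h is clipped at 1e−6 internally so
parental individuals contribute finite likelihood).

- Priors Normal(0, 1.5²) on ln v and logit c; joint random-walk proposals
  per locus, all loci sampled in one vectorized batch.
- p_v = 2 · min(Pr(ln v > 0), Pr(ln v < 0)) from the retained draws;
  "restricted introgression" = posterior-mean v > 1 and p_v < 0.05. No
  multiple-testing correction by default (per-locus α), Benjamini–
  Hochberg behind a flag.
- Hybrid indexes enter as fixed values; hybrid-index posterior uncertainty
  is not propagated (a deliberate simplification — with hundreds of
  diagnostic loci the h posterior is far tighter than the per-locus cline
  posterior).
- Calibration at desk scale (n = 300 diploids): the 95% CI covers a true
  v = 3 in ≥ 90% of replicates and the false restriction-call rate at
  v = 1 is ≈ α/2 (the call is one-sided).

## Geographic clines

The ancestry proxy is PC1 affinely anchored so the parental panel means
map to 0 and 1 (resolving PC1's sign ambiguity), or the hybrid index
passed through. Sample coordinates project orthogonally onto the transect
line in a local equirectangular plane (longitude scaled by cos of the
line's mean latitude) — adequate below a few degrees of span; a haversine
helper exists for long baselines.

The trait follows pmin + (pmax − pmin)·S(x) with the central sigmoid
S(x) = 1/(1 + e^(−4(x−c)/w)), so the maximum slope is (pmax − pmin)/w and
w is the conventional cline width. An exponential tail beginning δ km from
the centre decays with rate 4τ/(w(1 + e^(−4δ/w))), which makes the tail
slope a fraction τ of the central slope at the junction and the curve
continuous there (checked to machine precision in tests). The five
candidate models are the tail configurations; "mirror" shares one (δ, τ)
pair across both sides, "both" frees them.

- Observation model: Gaussian, homoscedastic, residual SD a free
  parameter. MH on transformed coordinates (logs for w, δ, σ; logit for τ)
  with single-coordinate adaptive updates; 3,000 burn-in / 9,000 kept.
- Model selection by AICc computed from the maximum log-likelihood visited
  (all free parameters including σ counted); exact ties break toward
  fewer parameters.
- Width support interval: all visited w with log L ≥ max log L − 2. At
  n = 150 and residual SD ≈ 0.08 this interval covers the generating width
  in ≈ 90% of replicates.
- Falling clines (proxy decreasing along x) are fitted on the mirrored
  axis and mapped back (model flagged `ascending=False`), so reversing a
  transect maps c to length − c and leaves w untouched.

## Differentiation statistics

Per-SNP F_ST is the Weir & Cockerham (1984) two-population θ̂ from the
variance components a, b, c; only diploid genotypes enter (the estimator's
heterozygosity terms are undefined for hemizygous calls). Monomorphic loci
are undefined (NaN), never zero; negative estimates are reported as-is.
Windows (25 kb, 5 kb step, anchored at position 1 — anchoring is
configurable because data-anchored windows are equally defensible) use the
ratio-of-sums Σa / Σ(a+b+c), the standard multi-locus combination, which
tests verify against a direct per-component transliteration.

Individual inbreeding F is the method-of-moments
(O_hom − E_hom)/(L − E_hom) with E_het,l = 2p(1−p)·n_l/(n_l − 1) over the
individual's non-missing diploid loci (n_l = observed allele copies).

Mitotyping: PCA over the mtDNA variants, centroids of the allopatric
reference samples per clade in the top-2 PC plane, nearest centroid;
exact ties break by clade label order and are flagged.

## Inversion scan

SNP–PC association on one chromosome: local PCA (no thinning), then for
each retained PC a likelihood-ratio test of a logistic model of PC-halves
membership (coordinate above/below the median) on genotype dosage; the
score is max over PCs of −log10 p, 0 for monomorphic SNPs. The Newton
solver is vectorized across SNPs; perfect separation simply saturates the
deviance, which is the desired behaviour for a scan statistic.

Boundary detection fits piecewise-constant models with 1..5 segments by
exact dynamic programming (least-squares cost), picks the segment count by
BIC, and calls the contiguous run whose mean exceeds the outside mean by
3× *and* by 3 outside-SDs (the second rule rejects noise plateaus when
the outside mean is near zero; both rules are scale-invariant) and spans
≥ 5% of the chromosome's SNP extent. The called core is then snapped to
the block edges by binarize-and-bridge: SNPs are classified against the
midpoint of block/outside means and the block extends across gaps of ≤ 2
low SNPs — real non-recombining blocks contain occasional uninformative
SNPs whose score dips would otherwise drag the least-squares cut inward.
One region is called per invocation; a qualifying secondary region only
raises a warning (re-run masked to call it).

Haplotype-group genotyping: 1-D Gaussian mixture (tied covariance, BIC
over 1–3 components) on local PC1; groups labelled AA/AB/BB by mean
genotype dosage; clusters separated by less than half an allele copy are
collapsed (noise on a monomorphic block). The AB group is validated as
having the lowest mean individual F, flagged if not. Reported length is
(end − start)/10⁶ Mb to one decimal — end minus start, not the inclusive
span, matching the convention of subtracting printed breakpoints.

The scan presumes a sample set without genome-wide admixture structure
(allopatric panels, or transect birds of homogeneous background): in a
panel spanning an ancestry cline, PC1 is the cline and every diagnostic
SNP associates with it.

## Tension-zone simulator

Stepping-stone of D demes × N diploids, secondary-contact start (left
demes fixed for one allele, right for the other, at all loci). Each
generation: nearest-neighbour migration (probability m, direction uniform,
reflecting edges), viability selection, then within-deme random mating
with fitness-proportional parents (selfing allowed), free recombination
among unlinked loci and exactly N offspring per deme (soft selection).

Fitness = (1 − s)^(#heterozygous selected loci) × (1 − s_env)^d, where d
is the fraction of selected allele copies mismatching the side of the
environmental boundary b(t) = b(0) + r·t the deme is on. Movement is thus
an advancing ecotone (selective asymmetry), not forced deme turnover —
the climate-envelope reading of zone movement.

The genome carries `l_selected` loci under both pressures plus
`l_neutral` neutral markers. Genome-wide ancestry (the hybrid index fed
to cline fitting) is the allele fraction over *all* loci. This matters: if
the hybrid index were computed from exactly the loci whose clines are
fitted, exchangeability would force E[locus ancestry | h] = h and v ≡ 1
at every selection strength; measuring selected-locus clines against a
genome-wide background that includes neutral markers is what lets
restricted introgression register as v > 1 — and it is how empirical
genomic-cline analyses are set up.

Defaults (D = 24, N = 120, 8 selected + 24 neutral loci, m = 0.25,
G = 100) were chosen so that desk-scale runs finish in seconds while
drift stays weak enough for the neutral case to behave neutrally: with
small demes every neutral locus's realized cline drifts into its own
steep, displaced profile and the mean fitted steepness rises above 1 for
purely stochastic reasons. Steepness summaries from the simulator use the
posterior *median* of v per locus: under weak data the posterior mean of
v inherits the lognormal prior's upward skew (prior mean e^(1.125) ≈ 3)
while the median stays at 1.

Diagnostics: `sigmoid_width` (least-squares sigmoid fit to the deme-mean
ancestry profile; for equilibrium questions restrict it to the selected
loci — the neutral profile flattens forever) and `run_experiment_grid`
(mean steepness and width over an (s, r) grid). Verified properties:
single-deme drift variance matches Wright–Fisher p(1−p)/(2N); neutral
width grows monotonically; selected-locus width equilibrates (t = G vs
t = G/2 within 10%, averaged over replicates); v̄ ≈ 1 at s = 0; v̄ rises
with s; and equal spans of s move v̄ more than equal spans of r.

## Synthetic data

The generator emulates: two parental reference panels fixed for
alternative alleles at diagnostic loci on a 10 kb grid (background loci
Balding–Nichols around shared ancestral frequencies, F = 0.02 by
default); transect individuals whose ancestry q is Beta-distributed
(concentration 30) around a sigmoid cline along the transect, with every
diagnostic allele copy independently P1-derived with probability q; an
mtDNA haploid pseudo-chromosome with three clades (one parental-0, two
parental-1 with a shared species block plus clade-private blocks);
hemizygous female Z genotypes; and an optional recombination-suppressed
block segregating as AA/AB/BB states whose frozen haplotypes cover all
loci inside the region (diagnostics opposite, background drawn once per
arrangement — so some in-block SNPs are uninformative, as in real
inversions), with 1% genotype noise. A fixed seed fixes every emitted
file byte-for-byte.

It does not emulate: linkage outside the inversion block (allele copies
are independent given q — adequate for estimators that assume thinned,
unlinked loci, silent about LD-aware methods), sequencing error or depth
variation, related individuals, or spatially autocorrelated sampling.
Passing tests therefore demonstrate estimator correctness under the
model's own assumptions, not robustness to real-data artifacts.

## Numerical conventions

Coordinates are 1-based inclusive throughout; windows are fixed-origin
(first window starts at 1). Thinning keeps the lowest-position SNP per
window. Missing genotypes are −1 with ploidy 0 reserved for
unknown-copy-number entries (unknown sex on Z). PCA imputes missing
dosage by the locus mean, doubles hemizygous dosage onto the diploid
scale, and uses a full SVD (deterministic signs via scikit-learn). All
samplers take explicit seeds; adaptation stops at the end of burn-in.

## Limitations

Single-locus genomic clines assume diagnostic loci (allele state =
ancestry state); no ancestry HMM is provided for non-diagnostic markers.
The geographic model set omits the three-part stepped cline. The
simulator is 1-D with soft selection and no assortative mating. Inversion
breakpoints are resolved to the SNP grid — nothing finer than the marker
spacing can be claimed, and no read-level evidence is consulted.
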