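# Methods

## The model

A recessive embryonic lethal at pre-selection (zygote) frequency q
removes its homozygotes before sampling. Among survivors the genotype
distribution at a fully linked marker is

    P(major hom) = p² / (1 − q²),    P(het) = 2pq / (1 − q²),    P(minor hom) = 0,

with p = 1 − q, giving the survivor heterozygote fraction
H = 2q/(1+q) and survivor allele frequency q/(1+q) (every surviving
copy of the allele sits in a heterozygote, so the allele frequency is
exactly H/2). At q ≈ 0.21, H ≈ 0.35 — the regime of the pooled
Thoroughbred data the defaults are calibrated to.

Selection is modelled as complete pre-sampling lethality; partial
penetrance is out of scope. The lethal block is emitted in perfect
coupling (identical survivor genotypes at adjacent map positions);
partial coupling is exercised only through the linked-marker simulator.

## Exact Hardy–Weinberg test

The test conditions on the observed allele counts and enumerates every
heterozygote count h of the right parity, with
P(h) ∝ n!·2ʰ / (n_AA(h)!·h!·n_BB(h)!), evaluated in log space with a
single max-shift and normalized. The two-sided p-value sums P(h′) over
tables with P(h′) ≤ P(h_obs)·(1 + 1e−10) (the relative tolerance
captures exact rational ties without absorbing neighbours); the
"deficit" mode sums h′ ≥ h_obs, the heterozygote-excess direction a
lethal produces. Monomorphic variants return p = 1 by convention.
Distributions are cached per (n, minor-allele count), which makes the
panel-wide scan linear-time in practice. The test suite verifies
agreement with an exact-rational enumerator on every genotype table
with n ≤ 30 (max |Δp| < 1e−9).

The scan's default test mode is two-sided, matching standard tooling;
significance is applied to FDR-adjusted values at α = 0.05. FDR is
computed once across the merged panel; per-population tables report raw
p-values. Variants below the MAF floor (default 0.01) or monomorphic
receive p = 1, are excluded from the FDR adjustment, and can never be
candidates — a lethal at detectable carrier frequency cannot be
monomorphic.

Storey q-values estimate π₀ on the λ-grid 0.05, 0.10, …, 0.95 with a
cubic polynomial evaluated at λ = 0.95 (approximating the reference
smoother), clamped to (0, 1] with a minimum-over-grid fallback when the
fit leaves that interval. Benjamini–Hochberg (via statsmodels) is the
dependency-light alternative.

## Candidate blocks

"Adjacent" means consecutive positions in the tested panel on the same
chromosome — on an array that is neighbouring markers, whatever their
bp gap (an optional max-gap cap exists but defaults to unlimited).
Runs shorter than 2 are discarded: a single zero-homozygote SNP is as
consistent with a clustering artifact as with a lethal, and the
recall-then-rescan stage exists precisely to clear such artifacts when
raw intensities are available.

## Two-locus LD by EM

Haplotype frequencies are estimated from unphased genotypes by EM over
the double-heterozygote phase ambiguity (all other genotype pairs
resolve deterministically). Convergence: log-likelihood improvement
< 1e−10 or 1,000 iterations. The EM is run from three deterministic
starts — the product of marginal allele frequencies plus the two
D-extreme configurations — keeping the best likelihood. The extra
starts matter: the linkage-equilibrium point is an exact fixed point of
the EM map on tables dominated by double heterozygotes, where the
likelihood maximum sits at |D| extremes; a single product-of-marginals
start stalls there. On exact phase-symmetric ties the low-p11 basin is
tried first, a deterministic tie-break.

D′ uses D_max = min(p_A·p_b, p_a·p_B) for D > 0 and
min(p_A·p_B, p_a·p_b) otherwise, is reported unsigned, and is defined
as 0 when D = 0. r² = D²/(p_A·p_a·p_B·p_b). Monomorphic partners raise
an undefined-LD error, which the shortlist treats as "not linked".
The shortlist window is ±5 Mb around the index variant and both
thresholds (r² > 0.8, D′ > 0.9) are strict inequalities.

## Mixture-model genotype recalling

Intensities are projected to θ = (2/π)·atan2(y, x) ∈ [0, 1]; genotype
classes cluster near 0 (AA), 0.5 (AB) and 1 (BB). A 1-D Gaussian
mixture is fitted by EM for K ∈ {1, 2, 3} (tolerance 1e−8, ≤ 500
iterations, variance floor 1e−6 against duplicate intensities) and K is
chosen by BIC — K must be selectable because a variant with a truly
absent genotype class has at most two clusters. Each K is fitted from
two deterministic starts and the better likelihood kept: means at
evenly spaced data quantiles (with 1e−6 seeded jitter when quantiles
coincide), and means at evenly spaced canonical positions
0.05…0.95. The second start is essential for the package's use case:
when a genotype class is rare (a handful of re-appearing minor
homozygotes), quantile starts place two components inside a dominant
cluster, the twin components never separate, and BIC then under-selects
K — the rare class is exactly what a recall of a suspect lethal SNP
must not miss.

Components are ordered by mean; K = 3 maps to AA/AB/BB directly, K < 3
to the nearest distinct canonical positions in {0, 0.5, 1}. Samples
with maximum posterior below 0.95 (configurable) become no-calls, and
no-calls become missing genotypes on re-call. The fit is deterministic
given panel and seed.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the scan assumes:
survivor genotypes under complete recessive lethality, independent
neutral SNPs at exact HWE with MAFs uniform on (0.01, 0.5), a linked
marker propagated through discrete generations of random mating with
per-meiosis recombination fraction c and per-generation removal of
causal homozygotes (the mechanism by which minor homozygotes reappear
at a marker while the causal column keeps zero — the Coldblooded
Trotter pattern), and two-channel intensity clusters on the unit arc
with a configurable miscall fraction. Cluster draws are reflected at
the arc boundaries rather than clipped, so no artificial intensity
atoms appear at θ = 0 or 1.

It does **not** emulate: linkage disequilibrium among neutral
background SNPs (they are independent, so the neutral two-adjacent-SNP
false-positive rate is conservative relative to real arrays, where
neighbouring markers are correlated), pedigree structure, sire-usage
skew, genotyping batch effects, allele-frequency spectra of real
arrays, or historical demography. Passing tests therefore demonstrate
correctness of the machinery under the stated model, not performance
guarantees on any particular real dataset.

Default regime: n = 526 survivors, q_pre = 0.21, two lethal markers,
5,000 neutral SNPs — the pooled-Thoroughbred scale at which the
acceptance checks run. The linked-marker simulator defaults to 20
generations, enough for the deterministic recursion
q_{t+1} = q_t/(1+q_t) to bite visibly while staying cheap.

## Numerical and design choices

- Coordinates are 1-based chrom:pos; variants are strictly ordered by
  (chrom, pos) and duplicates rejected.
- VCF site filters ("average filtered depth over 10", "Phred score over
  20") are strict inequalities; mean depth is the mean of per-sample
  FORMAT/DP over non-missing samples. Multi-allelic records are skipped
  with a logged count.
- Merging harmonizes allele-label swaps (codes flipped 0↔2) but refuses
  incompatible allele sets rather than guessing strand flips; missing
  genotypes are excluded from all counts, never imputed.
- Expected counts are rounded half-away-from-zero, which reproduces
  every published rounded value from its printed genotype counts.
- Minor-allele ties (q = 0.5) resolve to allele B, deterministically.
- The absence criterion is parameterized (`max_observed_minor_hom`,
  default 0, strict), so a marker with re-appeared homozygotes is
  representable as a non-candidate while still being testable.
- All pipeline randomness flows from one seed; identical config + seed
  gives byte-identical reports (the output directory is excluded from
  the config hash for that reason).

## Problem sizes used by the checks

The test suite runs the exact-test oracle exhaustively to n = 30, the
EM-LD grid oracle exhaustively over all two-locus tables with n ≤ 5
(resolution 1e−4), power at 200 replicates of the full 526 × 5,002
cohort, the closed-form carrier check at n = 10⁵, and recall accuracy
over 100 seeded panels of 200 samples at 6-sd cluster separation with
5% injected miscalls. The analysis drivers use reduced sizes (noted in
their docstrings) to stay interactive.

## Known limitations

- The scan is genotype-based; phased-haplotype approaches (as used for
  cattle lethal screens) and pedigree transmission tests are out of
  scope.
- Storey π₀ estimation is a polynomial approximation of the reference
  smoother; on panels with very few tests it falls back conservatively.
- The merge step cannot resolve palindromic (A/T, C/G) strand
  ambiguity; such conflicts raise an error listing the variant.
- The intensity model is a single-variant contrast model; multi-variant
  affine/quantile normalization and CNV-aware calling are not
  implemented.
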