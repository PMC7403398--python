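# lethscan

Genome-wide scanning for **recessive embryonic-lethal haplotypes** in
genotype data from managed animal populations.

A variant whose homozygotes die before birth never shows up as a
homozygote in the living population, yet its carriers can be common —
in closed, intensely selected breeds a lethal haplotype can drift to
carrier frequencies of 30% or more. The footprint in SNP-array or
sequencing genotypes is characteristic: a significant deviation from
Hardy–Weinberg equilibrium driven by heterozygote excess, a complete
absence of minor-allele homozygotes, and the same signal repeated
across tightly linked markers. `lethscan` implements the full
desk-scale workflow around that signature, for geneticists screening
breeds such as the Thoroughbred where fertility is managed without
reproductive technologies.

## The statistics at the core

For a biallelic variant with genotype counts (n_AA, n_AB, n_BB),
n = n_AA + n_AB + n_BB and minor-allele frequency
q̂ = min(f_B, 1 − f_B):

* **Expected minor homozygotes** under random mating: E = n·q̂², rounded
  half-away-from-zero for reporting. Zero observed against a large E is
  the lethal signature; P(zero | HWE) = (1 − q̂²)ⁿ.
* **Conditional exact HWE test**: conditioning on the observed allele
  counts, every admissible heterozygote count h (same parity as the
  minor-allele count) has probability ∝ n!·2ʰ / (n_AA(h)!·h!·n_BB(h)!).
  The two-sided p sums all tables no more probable than the observed
  one; a one-sided "deficit" mode sums the heterozygote-excess tail.
  Computed in log space, exact to the rational arithmetic for all n.
* **FDR control** across the panel: Benjamini–Hochberg, or Storey
  q-values with π₀ estimated on the λ-grid 0.05…0.95.
* **Adjacency clustering**: flagged variants are kept only in runs of
  ≥ 2 consecutive panel markers — an isolated zero-homozygote SNP is as
  likely a calling artifact as a lethal.
* **LD shortlisting**: two-locus haplotype frequencies by EM over the
  double-heterozygote phase ambiguity; partners within ±5 Mb of an
  index SNP with r² > 0.8 **and** D′ > 0.9 (both strict) are
  shortlisted.
* **Genotype recalling**: suspect SNPs are re-called from raw
  two-channel intensities with a 1-D Gaussian mixture on
  θ = (2/π)·atan2(y, x), K ∈ {1,2,3} chosen by BIC (a true lethal has
  at most two clusters), calls below posterior 0.95 set to missing.
* **Forward simulation**: survivor cohorts under complete recessive
  lethality — survivor heterozygote fraction 2q/(1+q) at pre-selection
  frequency q — with neutral background SNPs, a marker at recombination
  fraction c from the causal locus, and intensity clusters with
  injected miscalls.

## Worked example

Scan a simulated survivor cohort (526 survivors, pre-selection lethal
frequency 0.21, two planted lethal markers among 5,000 neutral SNPs):

```python
import lethscan as ls
from lethscan.sim import LethalSimConfig

matrix, truth = ls.simulate_lethal_population(LethalSimConfig(seed=42))
report = ls.run_pipeline(ls.PipelineConfig(seed=42), matrix=matrix)
```

which the driver `analysis/03_scan_candidates.py` prints as:

```
variants tested: 5002
flagged: 2; candidate blocks: 1; singletons discarded: 0
block on chr6: ['lethal_0', 'lethal_1'], span 777 bp, min q-value 5.81e-06
planted markers: ['lethal_0', 'lethal_1']; recovered: True
```

Exactly the two planted markers are flagged (heterozygote fraction
≈ 0.35, zero minor homozygotes against ≈ 16 expected) and they form a
single adjacent candidate block; no neutral SNP survives the FDR step
plus the adjacency requirement.

The published per-breed genotype counts for the candidate two-SNP
haplotype ship with the package (`lethscan.datasets`); feeding them
through the same machinery (`analysis/01_reproduce_breed_table.py`)
gives, e.g.:

| breed | n | minor hom | het | expected E | het % | p < 0.05 |
|---|---|---|---|---|---|---|
| Australian Thoroughbred | 156 | 0 | 66 | 7 | 42 | yes |
| Thoroughbred (pooled) | 526 | 0 | 183 | 16 | 35 | yes |
| Quarter Horse | 137 | 0 | 97 | 17 | 71 | yes |
| Coldblooded Trotter (2nd SNP) | 641 | 22 | 226 | 28 | 35 | no |

The Coldblooded Trotter second SNP carries 22 minor homozygotes — it
fails the absence criterion, consistent with recombination between that
marker and the causal variant (`analysis/04_ld_and_recall.py` simulates
this decay).

There is also a CLI for the individual stages:

```bash
lethscan simulate --n 526 --q-pre 0.21 --seed 42 --out-prefix sim
lethscan scan --ped sim.ped --map sim.map --out scan.tsv
lethscan ld --ped sim.ped --map sim.map --index 6:38278097 --out linked.tsv
lethscan recall --ped sim.ped --map sim.map \
    --intensities sim_intensities.tsv --snp 6:38278097 --out changes.tsv
```

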