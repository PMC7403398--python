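"""Forward simulation of survivor cohorts segregating a recessive lethal.

The generative model mirrors the signature the scan is built to find.
A lethal haplotype segregates at pre-selection frequency ``q_pre``;
zygotes form at Hardy-Weinberg proportions, lethal homozygotes die
before sampling, so among survivors the genotype distribution at the
lethal markers is

    P(major hom) = p^2 / (1 - q^2),   P(het) = 2 p q / (1 - q^2),

with p = 1 - q_pre, giving the closed-form survivor heterozygote
fraction H = 2q / (1 + q) and survivor allele frequency q / (1 + q).
At q_pre ~ 0.21 this yields the ~35% carrier fraction observed in
Thoroughbreds for the candidate haplotype.

The simulator emits: the lethal block (markers in perfect coupling,
adjacent map positions, zero minor homozygotes by construction),
independent neutral background SNPs at HWE, an optional marker linked
to the causal locus at recombination fraction c (propagated through
discrete generations of random mating with selection, so recombinant
minor homozygotes can appear — the phenomenon seen in Coldblooded
Trotters), and two-channel intensity clusters with injected miscalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lethscan.hwe import ScanConfig, cluster_adjacent, scan_deficit
from lethscan.io import MISSING, GenotypeMatrix, VariantDef
from lethscan.recall import IntensityPanel

#: Map positions used for the planted lethal block (chromosome 6).
_LETHAL_CHROM = "6"
_LETHAL_POS0 = 38_278_097
_LETHAL_SPACING = 777


@dataclass(frozen=True)
class IntensityModel:
    """Per-genotype intensity cluster geometry in the theta contrast.

    Cluster centers sit at theta = 0.05 / 0.5 / 0.95 for genotype codes
    0 / 1 / 2 with common spread ``cluster_sd``; a ``miscall_rate``
    fraction of samples is drawn from a wrong cluster.
    """

    cluster_centers: tuple[float, float, float] = (0.05, 0.5, 0.95)
    cluster_sd: float = 0.03
    radius_mean: float = 1.0
    radius_sd: float = 0.1
    miscall_rate: float = 0.0


@dataclass(frozen=True)
class LethalSimConfig:
    """Full parameterization of the synthetic survivor cohort.

    Defaults are the regime of the pooled Thoroughbred data: n = 526
    survivors, pre-selection lethal-haplotype frequency q_pre = 0.21
    (survivor carrier fraction 2q/(1+q) ~ 0.347), a two-SNP lethal
    block in perfect coupling, and 5,000 neutral background SNPs with
    MAFs uniform on (maf_floor, 0.5).
    """

    n_samples: int = 526
    q_pre: float = 0.21
    n_lethal_snps: int = 2
    n_neutral: int = 5000
    neutral_maf_range: tuple[float, float] = (0.01, 0.5)
    recomb_fraction: float = 0.0
    n_generations: int = 20
    intensity: IntensityModel = field(default_factory=IntensityModel)
    population_label: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q_pre <= 0.5:
            raise ValueError("q_pre must lie in [0, 0.5]")
        if not 0 <= self.recomb_fraction <= 0.5:
            raise ValueError("recomb_fraction must lie in [0, 0.5]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    lethal_variant_indices: list[int]
    lethal_genotypes: np.ndarray  # per-survivor code at the lethal block
    carrier_fraction: float  # realized among survivors
    allele_frequency: float  # realized minor-allele frequency among survivors
    neutral_mafs: np.ndarray


def survivor_carrier_fraction(q_pre: float) -> tuple[float, float]:
    """Closed-form survivor heterozygote fraction and allele frequency.

    Removing lethal homozygotes from HWE zygotes leaves heterozygotes at
    H = 2q/(1+q) and the lethal allele at q/(1+q); the allele frequency
    is always exactly half the carrier fraction because every surviving
    copy of the allele sits in a heterozygote.
    """
    if not 0 <= q_pre < 1:
        raise ValueError("q_pre must lie in [0, 1)")
    return 2 * q_pre / (1 + q_pre), q_pre / (1 + q_pre)


def simulate_lethal_population(
    config: LethalSimConfig,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Survivor genotype matrix: lethal block + neutral background.

    Survivor genotypes at the lethal markers are drawn from
    {major hom, het} with probabilities p^2/(1-q^2) and 2pq/(1-q^2); all
    ``n_lethal_snps`` markers carry identical genotypes (perfect
    coupling, adjacent positions on chromosome 6).  Neutral SNPs are
    independent HWE draws on chromosomes 1 and 2.  Deterministic under
    the config seed.
    """
    rng = np.random.default_rng(config.seed)
    n, q = config.n_samples, config.q_pre

    if q > 0:
        p = 1 - q
        p_het = 2 * p * q / (1 - q * q)  # = 2q/(1+q)
        lethal_geno = (rng.random(n) < p_het).astype(np.int8)
    else:
        lethal_geno = np.zeros(n, dtype=np.int8)

    lo, hi = config.neutral_maf_range
    mafs = rng.uniform(lo, hi, size=config.n_neutral)
    neutral = rng.binomial(2, mafs[None, :], size=(n, config.n_neutral)).astype(np.int8)

    variants: list[VariantDef] = []
    half = (config.n_neutral + 1) // 2
    for k in range(config.n_neutral):
        chrom = "1" if k < half else "2"
        pos = (k % half + 1) * 10_000
        variants.append(VariantDef(chrom, pos, f"neutral_{k}", "A", "C"))
    for k in range(config.n_lethal_snps):
        variants.append(
            VariantDef(
                _LETHAL_CHROM,
                _LETHAL_POS0 + k * _LETHAL_SPACING,
                f"lethal_{k}",
                "A",
                "G",
            )
        )

    calls = np.concatenate(
        [neutral, np.tile(lethal_geno[:, None], (1, config.n_lethal_snps))], axis=1
    )
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    variants = [variants[i] for i in order]
    calls = calls[:, order]
    lethal_idx = [i for i, v in enumerate(variants) if v.id.startswith("lethal_")]

    samples = [f"S{i:05d}" for i in range(n)]
    matrix = GenotypeMatrix(
        variants=variants,
        samples=samples,
        calls=calls,
        population={s: config.population_label for s in samples},
    )
    truth = SimTruth(
        lethal_variant_indices=lethal_idx,
        lethal_genotypes=lethal_geno,
        carrier_fraction=float((lethal_geno == 1).mean()),
        allele_frequency=float(lethal_geno.sum() / (2 * n)),
        neutral_mafs=mafs,
    )
    return matrix, truth


def simulate_linked_marker(
    config: LethalSimConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Marker linked to the causal lethal at recombination fraction c.

    A population of ``n_samples`` diploids starts with the marker in
    perfect coupling with the lethal allele (pre-selection frequency
    q_pre) and is propagated through ``n_generations`` of discrete
    random mating; each transmitted gamete recombines between marker and
    causal locus with probability c, and causal homozygotes die each
    generation before reproducing.  Unlike the causal column, the
    emitted marker column can contain minor homozygotes — recombinant
    haplotypes carry the marker allele without the lethal.

    Returns (marker genotype codes, causal genotype codes, info dict).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, q, c = config.n_samples, config.q_pre, config.recomb_fraction

    def survivors_from(hap_pool: np.ndarray, n_out: int) -> np.ndarray:
        """Mate random gamete pairs, drop causal homozygote offspring."""
        out = np.empty((0, 2, 2), dtype=np.int8)
        while out.shape[0] < n_out:
            k = 2 * (n_out - out.shape[0]) + 16
            # draw parent haplotype pairs per gamete, recombine
            idx = rng.integers(0, hap_pool.shape[0] // 2, size=(k, 2, 2))
            gametes = np.empty((k, 2, 2), dtype=np.int8)
            for g in range(2):
                h1 = hap_pool[2 * idx[:, g, 0]]
                h2 = hap_pool[2 * idx[:, g, 0] + 1]
                pick = rng.integers(0, 2, size=k)
                causal = np.where(pick == 0, h1[:, 0], h2[:, 0])
                marker = np.where(pick == 0, h1[:, 1], h2[:, 1])
                rec = rng.random(k) < c
                marker_other = np.where(pick == 0, h2[:, 1], h1[:, 1])
                marker = np.where(rec, marker_other, marker)
                gametes[:, g, 0] = causal
                gametes[:, g, 1] = marker
            alive = gametes[:, :, 0].sum(axis=1) < 2
            out = np.concatenate([out, gametes[alive]])
        return out[:n_out]

    # founder haplotype pool: (causal, marker) perfectly coupled
    n_hap = 2 * n
    carrier = (rng.random(n_hap) < q).astype(np.int8)
    pool = np.stack([carrier, carrier], axis=1)
    # remove founder causal homozygotes
    indiv = pool.reshape(n, 2, 2)
    alive = indiv[:, :, 0].sum(axis=1) < 2
    indiv = indiv[alive]
    pool = indiv.reshape(-1, 2)

    for _ in range(config.n_generations):
        indiv = survivors_from(pool, n)
        pool = indiv.reshape(-1, 2)

    marker_geno = indiv[:, :, 1].sum(axis=1).astype(np.int8)
    causal_geno = indiv[:, :, 0].sum(axis=1).astype(np.int8)
    info = {
        "marker_minor_hom": int((marker_geno == 2).sum()),
        "causal_minor_hom": int((causal_geno == 2).sum()),
        "marker_freq": float(marker_geno.sum() / (2 * len(marker_geno))),
        "causal_freq": float(causal_geno.sum() / (2 * len(causal_geno))),
    }
    return marker_geno, causal_geno, info


def simulate_intensities(
    genotypes, config: LethalSimConfig, variant: VariantDef | None = None,
    seed: int | None = None, samples: list[str] | None = None,
) -> tuple[IntensityPanel, dict]:
    """Two-channel intensities for given genotype codes, with miscalls.

    Each sample's (x, y) is drawn around its genotype's cluster center
    on the unit arc; a ``miscall_rate`` fraction is drawn from a wrong
    cluster (the truth dict records which).  Missing genotypes draw from
    a random cluster and are recorded as unknowable.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = np.asarray(genotypes, dtype=int)
    n = g.size
    im = config.intensity

    cluster = g.copy()
    unknown = cluster == MISSING
    cluster[unknown] = rng.integers(0, 3, size=int(unknown.sum()))
    miscalled = (rng.random(n) < im.miscall_rate) & ~unknown
    for i in np.where(miscalled)[0]:
        others = [k for k in range(3) if k != cluster[i]]
        cluster[i] = others[rng.integers(0, 2)]

    centers = np.asarray(im.cluster_centers)
    theta = rng.normal(centers[cluster], im.cluster_sd)
    # reflect at the arc boundaries: keeps theta in [0, 1] without the
    # zero/one atoms a hard clip would create (intensities stay >= 0)
    theta = np.abs(theta)
    theta = np.where(theta > 1.0, 2.0 - theta, theta)
    theta = np.clip(theta, 0.0, 1.0)
    r = np.abs(rng.normal(im.radius_mean, im.radius_sd, size=n))
    r = np.maximum(r, 1e-3)
    x = r * np.cos(theta * np.pi / 2)
    y = r * np.sin(theta * np.pi / 2)

    if variant is None:
        variant = VariantDef(_LETHAL_CHROM, _LETHAL_POS0, "lethal_0", "A", "G")
    if samples is None:
        samples = [f"S{i:05d}" for i in range(n)]
    panel = IntensityPanel(variant=variant, samples=list(samples), x=x, y=y)
    truth = {
        "true_genotypes": g,
        "drawn_cluster": cluster,
        "miscalled": miscalled,
        "unknown": unknown,
    }
    return panel, truth


def power_estimate(
    n: int,
    q_pre: float,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
    n_neutral: int = 5000,
    scan_config: ScanConfig | None = None,
) -> dict:
    """Monte-Carlo power of the deficit scan to flag the planted block.

    Runs ``n_reps`` independent cohorts (n survivors, pre-selection
    frequency q_pre, two lethal markers, ``n_neutral`` neutral SNPs),
    scans each, and reports: the fraction of replicates in which the
    planted block is recovered as a candidate block (power), the
    per-variant neutral false-positive rate at raw p < alpha, and
    Monte-Carlo standard errors for both.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = scan_config or ScanConfig(alpha=alpha)
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)

    hits = 0
    fp = 0
    n_neutral_tests = 0
    for rep_seed in rep_seeds:
        sim_cfg = LethalSimConfig(
            n_samples=n, q_pre=q_pre, n_neutral=n_neutral, seed=int(rep_seed)
        )
        matrix, truth = simulate_lethal_population(sim_cfg)
        results = scan_deficit(matrix, cfg)
        blocks = cluster_adjacent(results, cfg)
        planted = set(truth.lethal_variant_indices)
        if any(planted == {m.index for m in b.members} for b in blocks):
            hits += 1
        neutral = [r for r in results if r.index not in planted and r.tested]
        fp += sum(r.p_hwe < alpha for r in neutral)
        n_neutral_tests += len(neutral)

    power = hits / n_reps
    fp_rate = fp / n_neutral_tests if n_neutral_tests else float("nan")
    return {
        "power": power,
        "power_se": float(np.sqrt(power * (1 - power) / n_reps)),
        "neutral_fp_rate": fp_rate,
        "neutral_fp_se": float(np.sqrt(fp_rate * (1 - fp_rate) / n_neutral_tests))
        if n_neutral_tests
        else float("nan"),
        "n_reps": n_reps,
        "n_neutral_tests": n_neutral_tests,
    }
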