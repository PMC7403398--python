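"""Exact Hardy-Weinberg testing and the homozygote-deficit scan.

A recessive lethal segregating at pre-selection frequency q leaves
survivors with heterozygote excess and zero minor homozygotes, so the
scan combines three ingredients per variant:

* the conditional exact HWE test (enumerating every heterozygote count
  compatible with the observed allele counts),
* the expected minor-homozygote count E = n * q^2 under random mating,
* the absence criterion (observed minor homozygotes <= a threshold,
  default 0).

P-values are FDR-adjusted across the panel (Benjamini-Hochberg or
Storey q-values) and flagged variants are clustered into runs of
adjacent markers: an isolated flagged SNP is as likely a calling
artifact as a lethal, so only blocks of >= 2 adjacent flagged markers
survive as candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from lethscan.errors import DegenerateVariantError
from lethscan.io import MISSING, GenotypeMatrix, VariantDef


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic variant."""

    n_AA: int
    n_AB: int
    n_BB: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB, self.n_missing) < 0:
            raise ValueError("genotype counts must be >= 0")

    @property
    def n(self) -> int:
        """Number of genotyped (non-missing) individuals."""
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def f_B(self) -> float:
        """Frequency of allele B."""
        return (2 * self.n_BB + self.n_AB) / (2 * self.n)

    @property
    def minor_is_B(self) -> bool:
        """True when allele B is the minor allele (ties resolve to B)."""
        return self.f_B <= 0.5

    @property
    def q(self) -> float:
        """Minor-allele frequency, in [0, 0.5]."""
        return min(self.f_B, 1.0 - self.f_B)

    @property
    def n_minor_hom(self) -> int:
        return self.n_BB if self.minor_is_B else self.n_AA

    @property
    def n_major_hom(self) -> int:
        return self.n_AA if self.minor_is_B else self.n_BB


@dataclass(frozen=True)
class ScanConfig:
    """Tuning knobs of the deficit scan.

    alpha is applied to FDR-adjusted q-values (default 0.05);
    ``max_observed_minor_hom`` is the absence criterion (0 = strictly no
    minor homozygotes); ``min_block_size`` the shortest adjacent run kept
    as a candidate block; ``maf_floor`` the minimum minor-allele
    frequency for a variant to be testable; ``max_gap_bp`` an optional
    cap on the bp gap between adjacent block members.
    """

    alpha: float = 0.05
    fdr_method: str = "storey"
    max_observed_minor_hom: int = 0
    min_block_size: int = 2
    maf_floor: float = 0.01
    test_mode: str = "two_sided"
    max_gap_bp: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_block_size < 2:
            raise ValueError("min_block_size must be >= 2")
        if self.fdr_method not in ("bh", "storey"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")


@dataclass
class DeficitTestResult:
    """Per-variant outcome of the homozygote-deficit scan."""

    variant: VariantDef
    counts: GenotypeCounts
    q: float
    expected_minor_hom: float
    expected_minor_hom_rounded: int
    observed_minor_hom: int
    p_hwe: float
    q_value: float
    zero_minor_hom: bool
    tested: bool = True
    flagged: bool = False
    index: int = -1


@dataclass
class CandidateBlock:
    """A run of >= 2 adjacent flagged variants on one chromosome."""

    chrom: str
    members: list[DeficitTestResult]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        pos = [m.variant.pos for m in self.members]
        return max(pos) - min(pos)

    @property
    def min_q_value(self) -> float:
        return min(m.q_value for m in self.members)


def genotype_counts(
    matrix: GenotypeMatrix, variant_index: int, subset: set[str] | None = None
) -> GenotypeCounts:
    """Tabulate genotype counts at one variant, optionally over a sample subset."""
    col = matrix.calls[:, variant_index]
    if subset is not None:
        unknown = subset - set(matrix.samples)
        if unknown:
            raise KeyError(f"unknown sample ids in subset: {sorted(unknown)}")
        mask = np.array([s in subset for s in matrix.samples])
        col = col[mask]
    counts = GenotypeCounts(
        n_AA=int((col == 0).sum()),
        n_AB=int((col == 1).sum()),
        n_BB=int((col == 2).sum()),
        n_missing=int((col == MISSING).sum()),
    )
    if counts.n == 0:
        v = matrix.variants[variant_index]
        raise DegenerateVariantError(f"all calls missing at {v.chrom}:{v.pos}")
    return counts


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_minor_homozygotes(counts: GenotypeCounts) -> tuple[float, int]:
    """Expected minor-homozygote count E = n * q^2 under Hardy-Weinberg.

    q is the observed minor-allele frequency; returns the real value and
    its nearest-integer rounding (half away from zero).  A tie q = 0.5
    treats allele B as minor.
    """
    if counts.n < 1:
        raise DegenerateVariantError("no genotyped samples")
    e = counts.n * counts.q**2
    return e, _round_half_away(e)


@lru_cache(maxsize=100_000)
def _het_distribution(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given allele counts.

    Conditional on n diploid individuals carrying ``n_minor`` copies of
    the minor allele, the heterozygote count h ranges over values of the
    same parity as n_minor with 0 <= h <= min(n_minor, 2n - n_minor),
    with P(h) proportional to n! 2^h / (n_AA(h)! h! n_BB(h)!).  Computed
    in log space and normalized.  Returns (h values, probabilities).
    """
    h_max = min(n_minor, 2 * n - n_minor)
    hs = np.arange(n_minor % 2, h_max + 1, 2)
    n_hom_minor = (n_minor - hs) // 2
    n_hom_major = n - hs - n_hom_minor
    from scipy.special import gammaln

    logw = (
        hs * math.log(2.0)
        - gammaln(n_hom_minor + 1)
        - gammaln(hs + 1)
        - gammaln(n_hom_major + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return hs, w / w.sum()


def hwe_exact_test(counts: GenotypeCounts, mode: str = "two_sided") -> float:
    """Conditional exact Hardy-Weinberg test.

    "two_sided" sums P(h') over all heterozygote counts whose table
    probability does not exceed the observed one; "deficit" sums over
    h' >= h_obs, the heterozygote-excess / homozygote-deficit tail that
    a recessive lethal produces.  Monomorphic variants return p = 1 by
    convention.
    """
    if mode not in ("two_sided", "deficit"):
        raise ValueError(f"unknown mode {mode!r}")
    n = counts.n
    if n < 1:
        raise DegenerateVariantError("no genotyped samples")
    n_minor = 2 * counts.n_minor_hom + counts.n_AB
    if n_minor == 0 or n_minor == 2 * n:
        return 1.0
    hs, probs = _het_distribution(n, n_minor)
    h_obs = counts.n_AB
    i = int(np.searchsorted(hs, h_obs))
    if i >= len(hs) or hs[i] != h_obs:
        raise ValueError(
            f"heterozygote count {h_obs} incompatible with allele count {n_minor}"
        )
    if mode == "deficit":
        p = probs[hs >= h_obs].sum()
    else:
        p = probs[probs <= probs[i] * (1 + 1e-10)].sum()
    return float(min(1.0, p))


def _storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with pi0 from a cubic smoother over the lambda grid."""
    m = p.size
    lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_at = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, pi0_at, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    except np.linalg.LinAlgError:
        pi0 = float(pi0_at.min())
    if not 0 < pi0 <= 1:
        # monotone fallback: running mean is non-increasing in expectation
        pi0 = float(min(1.0, max(pi0_at.min(), np.finfo(float).tiny)))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fdr_adjust(p_values, method: str = "storey") -> np.ndarray:
    """FDR-adjust p-values; "bh" step-up or "storey" q-values.

    Output order matches input order.  Storey estimates the null
    proportion pi0 on the lambda grid 0.05, 0.10, ..., 0.95 with a cubic
    smoother extrapolated to lambda -> 1, clamped to (0, 1]; its
    q-values can be smaller than the BH ones when pi0 < 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        return _storey_qvalues(p)
    raise ValueError(f"unknown FDR method {method!r}")


def scan_deficit(
    matrix: GenotypeMatrix, config: ScanConfig = ScanConfig()
) -> list[DeficitTestResult]:
    """Per-variant homozygote-deficit scan over a genotype matrix.

    Every variant appears exactly once in the output.  Variants that are
    monomorphic or below ``maf_floor`` receive p = 1, are excluded from
    the FDR adjustment, and can never be candidates.  A variant is
    flagged when its q-value is below alpha AND its observed
    minor-homozygote count is <= ``max_observed_minor_hom``.
    """
    calls = matrix.calls
    n_AA = (calls == 0).sum(axis=0)
    n_AB = (calls == 1).sum(axis=0)
    n_BB = (calls == 2).sum(axis=0)
    n_miss = (calls == MISSING).sum(axis=0)
    n = n_AA + n_AB + n_BB

    results: list[DeficitTestResult] = []
    p_raw = np.ones(matrix.n_variants)
    tested = np.zeros(matrix.n_variants, dtype=bool)
    for j, v in enumerate(matrix.variants):
        counts = GenotypeCounts(int(n_AA[j]), int(n_AB[j]), int(n_BB[j]), int(n_miss[j]))
        if counts.n == 0:
            raise DegenerateVariantError(f"all calls missing at {v.chrom}:{v.pos}")
        q = counts.q
        tested[j] = q >= config.maf_floor and q > 0
        p_raw[j] = hwe_exact_test(counts, config.test_mode) if tested[j] else 1.0
        e_real, e_round = expected_minor_homozygotes(counts)
        results.append(
            DeficitTestResult(
                variant=v,
                counts=counts,
                q=q,
                expected_minor_hom=e_real,
                expected_minor_hom_rounded=e_round,
                observed_minor_hom=counts.n_minor_hom,
                p_hwe=float(p_raw[j]),
                q_value=1.0,
                zero_minor_hom=counts.n_minor_hom == 0,
                tested=bool(tested[j]),
                index=j,
            )
        )

    if tested.any():
        qvals = fdr_adjust(p_raw[tested], config.fdr_method)
        for r, qv in zip([r for r in results if r.tested], qvals):
            r.q_value = float(qv)
    for r in results:
        r.flagged = (
            r.tested
            and r.q_value < config.alpha
            and r.observed_minor_hom <= config.max_observed_minor_hom
        )
    return results


def cluster_adjacent(
    results: list[DeficitTestResult], config: ScanConfig = ScanConfig()
) -> list[CandidateBlock]:
    """Group flagged variants into maximal runs adjacent in panel order.

    Adjacency means consecutive positions in the tested variant panel on
    the same chromosome (neighboring array markers), optionally capped
    by ``max_gap_bp``.  Runs shorter than ``min_block_size`` are
    discarded as possible calling errors.
    """
    blocks: list[CandidateBlock] = []
    run: list[DeficitTestResult] = []

    def close_run() -> None:
        if len(run) >= config.min_block_size:
            blocks.append(CandidateBlock(chrom=run[0].variant.chrom, members=list(run)))
        run.clear()

    prev: DeficitTestResult | None = None
    for r in results:
        contiguous = (
            r.flagged
            and run
            and prev is not None
            and r.variant.chrom == prev.variant.chrom
            and r.index == prev.index + 1
            and (
                config.max_gap_bp is None
                or r.variant.pos - prev.variant.pos <= config.max_gap_bp
            )
        )
        if r.flagged and not contiguous:
            close_run()
            run.append(r)
        elif contiguous:
            run.append(r)
        elif not r.flagged:
            close_run()
        prev = r
    close_run()
    return blocks


def summarize_genotype_counts(counts: GenotypeCounts) -> dict:
    """Table-style summary of one set of genotype counts.

    Returns observed counts ordered (minor hom, het, major hom), the
    rounded expected minor-homozygote count under HWE, the exact-test
    p-value, the heterozygote fraction as a percentage rounded to the
    nearest integer, and a significance star at p < 0.05.
    """
    e_real, e_round = expected_minor_homozygotes(counts)
    p = hwe_exact_test(counts, "two_sided")
    het_pct = _round_half_away(100.0 * counts.n_AB / counts.n)
    return {
        "n": counts.n,
        "n_minor_hom": counts.n_minor_hom,
        "n_het": counts.n_AB,
        "n_major_hom": counts.n_major_hom,
        "n_missing": counts.n_missing,
        "maf": counts.q,
        "expected_minor_hom": e_real,
        "expected_minor_hom_rounded": e_round,
        "p_hwe": p,
        "het_percent": het_pct,
        "significant": p < 0.05,
    }


def population_summary(
    matrix: GenotypeMatrix,
    variant_indices: list[int],
    by: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-population genotype summaries at selected variants.

    One row per population x variant with observed counts, rounded
    expected minor homozygotes, exact-test p, heterozygote percentage
    and a significance star; samples without a label are grouped as
    "unassigned".  A population with every call missing yields an n = 0
    row without a test.
    """
    labels = by if by is not None else (matrix.population or {})
    pops = [labels.get(s, "unassigned") for s in matrix.samples]
    rows = []
    for pop in sorted(set(pops)):
        members = {s for s, g in zip(matrix.samples, pops) if g == pop}
        for j in variant_indices:
            v = matrix.variants[j]
            base = {"population": pop, "chrom": v.chrom, "pos": v.pos, "id": v.id}
            try:
                counts = genotype_counts(matrix, j, subset=members)
            except DegenerateVariantError:
                rows.append(
                    base
                    | {
                        "n": 0,
                        "n_minor_hom": 0,
                        "n_het": 0,
                        "n_major_hom": 0,
                        "n_missing": len(members),
                        "maf": float("nan"),
                        "expected_minor_hom": float("nan"),
                        "expected_minor_hom_rounded": 0,
                        "p_hwe": float("nan"),
                        "het_percent": 0,
                        "significant": False,
                    }
                )
                continue
            rows.append(base | summarize_genotype_counts(counts))
    return pd.DataFrame(rows)


def zero_homozygote_null_prob(n: int, q: float) -> float:
    """P(zero minor homozygotes among n individuals) under HWE: (1 - q^2)^n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= q <= 0.5:
        raise ValueError("q must lie in [0, 0.5]")
    return (1.0 - q * q) ** n
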