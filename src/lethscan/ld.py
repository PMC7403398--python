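"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated by EM over the phase ambiguity of
double heterozygotes (the classical Hill/Excoffier-Slatkin estimator);
D, D' and r^2 follow from the fitted frequencies.  The shortlist
operation reproduces the narrowing step of a lethal-haplotype scan:
variants within a window of an index SNP whose r^2 and D' both exceed
strict thresholds.

Haplotype frequency indexing: p11, p12, p21, p22 are frequencies of the
haplotypes (A-allele_1, B-allele_1), (A1, B2), (A2, B1), (A2, B2) where
allele 1 at each locus is the reference allele (genotype code counts
copies of allele 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lethscan.errors import UndefinedLDError
from lethscan.io import MISSING, GenotypeMatrix, VariantDef


@dataclass(frozen=True)
class LDConfig:
    """Window and strict LD thresholds for shortlisting linked variants."""

    window_bp: int = 5_000_000
    r2_min: float = 0.8
    dprime_min: float = 0.9
    maf_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        for t in (self.r2_min, self.dprime_min):
            if not 0 < t < 1:
                raise ValueError("LD thresholds must lie in (0, 1)")


@dataclass
class LDStat:
    """LD summary for one variant pair."""

    index_variant: VariantDef
    partner_variant: VariantDef
    hap_freqs: tuple[float, float, float, float]  # p11, p12, p21, p22
    D: float
    D_prime: float
    r2: float
    n_used: int


def _pair_counts(genoA: np.ndarray, genoB: np.ndarray) -> np.ndarray:
    """3x3 genotype-pair count table over double-nonmissing samples."""
    ok = (genoA != MISSING) & (genoB != MISSING)
    a, b = genoA[ok].astype(int), genoB[ok].astype(int)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table


def _loglik(table: np.ndarray, p: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 genotype-pair table.

    p = (p11, p12, p21, p22).  Genotype-pair probabilities are products
    of two haplotype draws; the double heterozygote pools both phases.
    """
    p11, p12, p21, p22 = p
    hap = np.array([[p11, p12], [p21, p22]])  # hap[i][j]: allele i+1 at A, j+1 at B
    ll = 0.0
    for gA in range(3):
        for gB in range(3):
            n = table[gA, gB]
            if n == 0:
                continue
            if gA == 1 and gB == 1:
                prob = 2 * (p11 * p22 + p12 * p21)
            else:
                # outside the double het the two haplotypes are determined:
                # each locus contributes its alleles in a fixed split
                allelesA = [0] * (2 - gA) + [1] * gA
                allelesB = [0] * (2 - gB) + [1] * gB
                h1 = hap[allelesA[0], allelesB[0]]
                h2 = hap[allelesA[1], allelesB[1]]
                # distinct unordered haplotype pair -> factor 2
                mult = 2 if (gA == 1) != (gB == 1) else 1
                prob = mult * h1 * h2
            if prob <= 0:
                return -math.inf
            ll += n * math.log(prob)
    return ll


def _em_from(table: np.ndarray, p0: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    n2 = 2 * table.sum()
    # fixed haplotype contributions from phase-unambiguous genotype pairs
    base = np.zeros(4)  # counts of hap 11, 12, 21, 22
    for gA in range(3):
        for gB in range(3):
            n = table[gA, gB]
            if n == 0 or (gA == 1 and gB == 1):
                continue
            allelesA = [0] * (2 - gA) + [1] * gA
            allelesB = [0] * (2 - gB) + [1] * gB
            if gA == 1 and gB != 1:
                pairs = [(0, allelesB[0]), (1, allelesB[0])]
            elif gB == 1 and gA != 1:
                pairs = [(allelesA[0], 0), (allelesA[0], 1)]
            else:
                pairs = [(allelesA[0], allelesB[0]), (allelesA[1], allelesB[1])]
            for ia, ib in pairs:
                base[2 * ia + ib] += n
    n_dh = table[1, 1]

    p = p0.copy()
    ll = _loglik(table, p)
    for _ in range(max_iter):
        p11, p12, p21, p22 = p
        denom = p11 * p22 + p12 * p21
        w = 0.5 if denom <= 0 else p11 * p22 / denom
        counts = base.copy()
        counts[0] += n_dh * w
        counts[3] += n_dh * w
        counts[1] += n_dh * (1 - w)
        counts[2] += n_dh * (1 - w)
        p_new = counts / n2
        p_new /= p_new.sum()
        ll_new = _loglik(table, p_new)
        p = p_new
        if ll_new - ll < tol:
            ll = ll_new
            break
        ll = ll_new
    return p, ll


def estimate_haplotype_freqs_em(
    genoA, genoB, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, float]:
    """EM haplotype-frequency estimate for two biallelic loci.

    Input genotype codes count copies of allele 2 at each locus; missing
    codes are dropped pairwise.  Returns (p11, p12, p21, p22) and the
    final log-likelihood.  The EM is started from the product of the
    marginal allele frequencies plus the two D-extreme configurations
    (guarding against the linkage-equilibrium fixed point that traps a
    single-start EM on double-heterozygote-rich tables); the best
    likelihood wins.

    Raises :class:`UndefinedLDError` when either locus is monomorphic
    among double-nonmissing samples, or fewer than 2 such samples exist.
    """
    genoA = np.asarray(genoA)
    genoB = np.asarray(genoB)
    table = _pair_counts(genoA, genoB)
    n = int(table.sum())
    if n < 2:
        raise UndefinedLDError("fewer than 2 double-nonmissing samples")
    fA2 = (table.sum(axis=1) * np.array([0, 1, 2])).sum() / (2 * n)
    fB2 = (table.sum(axis=0) * np.array([0, 1, 2])).sum() / (2 * n)
    if fA2 in (0.0, 1.0) or fB2 in (0.0, 1.0):
        raise UndefinedLDError("monomorphic locus among double-nonmissing samples")

    pA1, pB1 = 1 - fA2, 1 - fB2

    def freqs_at(p11: float) -> np.ndarray:
        return np.array(
            [p11, pA1 - p11, pB1 - p11, 1 - pA1 - pB1 + p11], dtype=float
        ).clip(0, 1)

    lo = max(0.0, pA1 + pB1 - 1.0)
    hi = min(pA1, pB1)
    eps = 1e-6 * (hi - lo)
    # start order matters only for phase-symmetric tables with two equal
    # maxima: the low-p11 basin is tried first, a deterministic tie-break
    starts = [
        freqs_at(pA1 * pB1),
        freqs_at(lo + eps),
        freqs_at(hi - eps),
    ]
    best_p, best_ll = None, -math.inf
    for p0 in starts:
        p0 = np.maximum(p0, 1e-12)
        p0 /= p0.sum()
        p, ll = _em_from(table, p0, tol, max_iter)
        if ll > best_ll:
            best_p, best_ll = p, ll
    return best_p, best_ll


def ld_from_hap_freqs(
    hap_freqs, index_variant=None, partner_variant=None, n_used: int = 0
) -> LDStat:
    """Derive D, D' and r^2 from four haplotype frequencies."""
    p11, p12, p21, p22 = (float(x) for x in hap_freqs)
    pA1, pA2 = p11 + p12, p21 + p22
    pB1, pB2 = p11 + p21, p12 + p22
    D = p11 * p22 - p12 * p21
    if D > 0:
        d_max = min(pA1 * pB2, pA2 * pB1)
    else:
        d_max = min(pA1 * pB1, pA2 * pB2)
    d_prime = 0.0 if D == 0 or d_max <= 0 else abs(D) / d_max
    denom = pA1 * pA2 * pB1 * pB2
    r2 = 0.0 if denom <= 0 else D * D / denom
    return LDStat(
        index_variant=index_variant,
        partner_variant=partner_variant,
        hap_freqs=(p11, p12, p21, p22),
        D=D,
        D_prime=min(1.0, d_prime),
        r2=min(1.0, r2),
        n_used=n_used,
    )


def compute_ld(matrix: GenotypeMatrix, i: int, j: int) -> LDStat:
    """EM-based LD statistics between variants i and j of a matrix."""
    if i == j:
        raise ValueError("need two distinct variants")
    genoA = matrix.calls[:, i]
    genoB = matrix.calls[:, j]
    freqs, _ = estimate_haplotype_freqs_em(genoA, genoB)
    ok = (genoA != MISSING) & (genoB != MISSING)
    return ld_from_hap_freqs(
        freqs,
        index_variant=matrix.variants[i],
        partner_variant=matrix.variants[j],
        n_used=int(ok.sum()),
    )


def shortlist_linked(
    matrix: GenotypeMatrix, index: VariantDef | tuple[str, int], config: LDConfig = LDConfig()
) -> list[LDStat]:
    """Variants linked to an index SNP: same chromosome, within the
    window, r^2 > r2_min AND D' > dprime_min (both strict).

    Monomorphic or sub-MAF-floor partners are treated as not linked.
    Output is sorted by descending r^2, ties by position.
    """
    if isinstance(index, VariantDef):
        chrom, pos = index.chrom, index.pos
    else:
        chrom, pos = index
    i = matrix.variant_index(chrom, pos)
    out: list[LDStat] = []
    for j, v in enumerate(matrix.variants):
        if j == i or v.chrom != chrom or abs(v.pos - pos) > config.window_bp:
            continue
        col = matrix.calls[:, j]
        ok = col != MISSING
        if not ok.any():
            continue
        fb = col[ok].sum() / (2 * ok.sum())  # fast MAF screen before the EM
        if min(fb, 1 - fb) < config.maf_floor:
            continue
        try:
            stat = compute_ld(matrix, i, j)
        except UndefinedLDError:
            continue
        if stat.r2 > config.r2_min and stat.D_prime > config.dprime_min:
            out.append(stat)
    out.sort(key=lambda s: (-s.r2, s.partner_variant.pos))
    return out
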