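"""Re-call suspect SNP genotypes from raw two-channel intensities.

Array genotyping produces, per sample, a pair of channel intensities
(x for allele A, y for allele B).  Genotype classes form clusters in
the contrast coordinate theta = (2/pi) * atan2(y, x): homozygous AA
near 0, heterozygous near 0.5, homozygous BB near 1.  A variant whose
minor-homozygote class is genuinely absent (a recessive lethal) has at
most two clusters, so the number of mixture components is itself chosen
from the data by BIC over K in {1, 2, 3}.

The mixture is a one-dimensional Gaussian mixture on theta fitted by
EM with deterministic quantile initialization; samples whose maximum
posterior falls below the call threshold are left as no-calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lethscan.errors import InsufficientDataError
from lethscan.io import MISSING, GenotypeMatrix, VariantDef

#: Assignment label for samples not confidently called.
NO_CALL: int = -1

_CANONICAL = np.array([0.0, 0.5, 1.0])  # cluster centers for codes 0, 1, 2


@dataclass
class IntensityPanel:
    """Raw two-channel intensities for one variant."""

    variant: VariantDef
    samples: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.samples) == self.x.size == self.y.size):
            raise ValueError("samples, x and y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("intensities must be finite")


@dataclass
class MixtureFit:
    """A fitted genotype mixture and the calls it implies."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    genotype_codes: np.ndarray  # component index -> genotype code 0/1/2
    assignments: np.ndarray  # per-sample genotype code or NO_CALL
    posterior: np.ndarray  # per-sample max posterior
    call_threshold: float
    loglik_trace: np.ndarray


def project_intensities(panel: IntensityPanel) -> tuple[np.ndarray, np.ndarray]:
    """Contrast projection theta = (2/pi) atan2(y, x) in [0, 1].

    Returns (theta, projectable mask); samples at x = y = 0 are flagged
    unprojectable (theta set to NaN).
    """
    theta = (2.0 / math.pi) * np.arctan2(panel.y, panel.x)
    bad = (panel.x == 0) & (panel.y == 0)
    theta = theta.astype(float)
    theta[bad] = np.nan
    return theta, ~bad


def _em_1d(theta: np.ndarray, k: int, rng: np.random.Generator,
           mu0: np.ndarray | None = None,
           tol: float = 1e-8, max_iter: int = 500,
           var_floor: float = 1e-6) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """One-dimensional Gaussian-mixture EM from a given or quantile start."""
    n = theta.size
    if mu0 is None:
        mu = np.quantile(theta, (np.arange(k) + 0.5) / k)
        if k > 1 and np.any(np.diff(mu) <= 0):
            mu = mu + rng.normal(0.0, 1e-6, size=k)  # break coincident quantiles
            mu.sort()
    else:
        mu = np.asarray(mu0, dtype=float).copy()
    var = np.full(k, max(np.var(theta) / max(k, 1), var_floor))
    w = np.full(k, 1.0 / k)

    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        logp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (theta[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * theta[:, None]).sum(axis=0) / nk
        var = (resp * (theta[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, var_floor)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            break
        ll_prev = ll
    return w, mu, var, trace[-1], np.array(trace)


def _map_components_to_codes(mu_sorted: np.ndarray) -> np.ndarray:
    """Map ordered component means to genotype codes via canonical centers.

    K = 3 maps to (0, 1, 2) directly; K < 3 components take the nearest
    canonical position in {0, 0.5, 1}, kept distinct and increasing.
    """
    k = mu_sorted.size
    if k == 3:
        return np.array([0, 1, 2])
    codes = []
    prev = -1
    for i, m in enumerate(mu_sorted):
        # nearest canonical code not yet used, leaving room for the rest
        cands = [c for c in range(3) if prev < c <= 2 - (k - 1 - i)]
        best = min(cands, key=lambda c: abs(_CANONICAL[c] - m))
        codes.append(best)
        prev = best
    return np.array(codes)


def fit_genotype_mixture(
    panel: IntensityPanel, seed: int = 0, call_threshold: float = 0.95
) -> MixtureFit:
    """Fit genotype clusters on projected intensities and call genotypes.

    For K in {1, 2, 3} a Gaussian mixture on theta is fitted by EM
    (quantile initialization, log-likelihood tolerance 1e-8, at most 500
    iterations, variance floor 1e-6) and the BIC-minimizing K is kept.
    Components are ordered by mean and mapped to genotype codes; samples
    with maximum posterior below ``call_threshold`` become NO_CALL.
    """
    theta, ok = project_intensities(panel)
    usable = theta[ok]
    if usable.size < 10:
        raise InsufficientDataError(
            f"only {usable.size} projectable samples (need >= 10)"
        )
    rng = np.random.default_rng(seed)
    fits = {}
    for k in (1, 2, 3):
        # two deterministic starts: data quantiles, and evenly spaced
        # canonical positions — the latter finds rare genotype classes
        # (e.g. a handful of minor homozygotes) that quantile starts
        # place inside a dominant cluster
        starts: list[np.ndarray | None] = [None, np.linspace(0.05, 0.95, k)]
        best = None
        for mu0 in starts:
            w, mu, var, ll, trace = _em_1d(usable, k, rng, mu0=mu0)
            if best is None or ll > best[3]:
                best = (w, mu, var, ll, trace)
        w, mu, var, ll, trace = best
        n_params = 3 * k - 1
        bic = -2.0 * ll + n_params * math.log(usable.size)
        fits[k] = (w, mu, var, ll, trace, bic)
    best_k = min(fits, key=lambda k: fits[k][5])
    w, mu, var, ll, trace, bic = fits[best_k]

    order = np.argsort(mu)
    w, mu, var = w[order], mu[order], var[order]
    codes = _map_components_to_codes(mu)

    logp = (
        np.log(np.maximum(w, 1e-300))[None, :]
        - 0.5 * np.log(2 * np.pi * var)[None, :]
        - 0.5 * (theta[:, None] - mu[None, :]) ** 2 / var[None, :]
    )
    with np.errstate(invalid="ignore"):
        m = np.nanmax(logp, axis=1, keepdims=True)
        resp = np.exp(logp - m)
        resp /= resp.sum(axis=1, keepdims=True)
    post = np.nanmax(resp, axis=1)
    comp = np.nanargmax(np.where(np.isnan(resp), -np.inf, resp), axis=1)
    assignments = codes[comp]
    assignments = np.where(post >= call_threshold, assignments, NO_CALL)
    assignments = np.where(ok, assignments, NO_CALL)
    post = np.where(ok, post, np.nan)

    return MixtureFit(
        K=best_k,
        weights=w,
        means=mu,
        variances=var,
        log_likelihood=ll,
        bic=bic,
        genotype_codes=codes,
        assignments=assignments.astype(int),
        posterior=post,
        call_threshold=call_threshold,
        loglik_trace=trace,
    )


def recall_variant(
    matrix: GenotypeMatrix,
    panel: IntensityPanel,
    seed: int = 0,
    call_threshold: float = 0.95,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replace one variant's calls with mixture calls from intensities.

    Returns a new matrix plus a change report listing every sample whose
    call changed (old code, new code, posterior); NO_CALL becomes
    MISSING.  Panel samples must be a subset of matrix samples.
    """
    v = panel.variant
    j = matrix.variant_index(v.chrom, v.pos)  # KeyError if absent
    sample_pos = {s: i for i, s in enumerate(matrix.samples)}
    unknown = [s for s in panel.samples if s not in sample_pos]
    if unknown:
        raise KeyError(f"panel references unknown sample ids: {unknown[:5]}")

    fit = fit_genotype_mixture(panel, seed=seed, call_threshold=call_threshold)
    new_calls = matrix.calls.copy()
    changes = []
    for k, sid in enumerate(panel.samples):
        i = sample_pos[sid]
        old = int(matrix.calls[i, j])
        new = int(fit.assignments[k])
        new_code = MISSING if new == NO_CALL else new
        if new_code != old:
            changes.append(
                {
                    "sample_id": sid,
                    "old_call": old,
                    "new_call": new_code,
                    "posterior": float(fit.posterior[k])
                    if np.isfinite(fit.posterior[k])
                    else float("nan"),
                }
            )
        new_calls[i, j] = new_code
    out = GenotypeMatrix(
        variants=list(matrix.variants),
        samples=list(matrix.samples),
        calls=new_calls,
        population=dict(matrix.population) if matrix.population else None,
    )
    report = pd.DataFrame(changes, columns=["sample_id", "old_call", "new_call", "posterior"])
    return out, report
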