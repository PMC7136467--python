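"""Bayesian admixture inference with correlated allele frequencies.

The model is the Pritchard-style admixture model: individual ``i`` has an
ancestry vector Q_i over K clusters (Dirichlet(alpha) prior with a single
shared alpha), each allele copy originates from cluster ``z`` drawn from
Q_i, and carries the counted allele with the cluster's frequency p_{k,l}.
Under the correlated-frequencies ("F-model") prior the cluster frequencies
are tied to an ancestral frequency:

    p_{k,l} ~ Beta(pbar_l (1-F_k)/F_k, (1-pbar_l)(1-F_k)/F_k),
    pbar_l ~ Beta(lambda, lambda),

with per-cluster drift F_k.  Inference is by Gibbs sampling: the copy-level
ancestries z, the Q rows and the p_{k,l} have conjugate updates; pbar, F_k
and alpha move by random-walk Metropolis.  Missing genotype copies carry no
likelihood term (their z is drawn from Q alone).

Model choice uses the STRUCTURE-style evidence estimate
``ln Pr(X|K) ~= mean(lnL) - var(lnL)/2`` over post-burn-in sweeps (sample
variance), and the Evanno ΔK second-difference statistic across K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import betaln, gammaln

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class AdmixtureModelSpec:
    K: int
    alpha_init: float = 1.0
    lam: float = 1.0            # ancestral-frequency Beta(lambda, lambda)
    burn_in: int = 10000
    reps: int = 100000
    n_runs: int = 20
    seed: int = 0
    alpha_max: float = 10.0
    alpha_step: float = 0.025
    f_step: float = 0.01
    pbar_step: float = 0.03

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in <= 0 or self.reps <= 0:
            raise ValueError("burn_in and reps must be positive")


@dataclass
class AdmixtureFit:
    Q: np.ndarray               # n x K posterior means, rows sum to 1
    P: np.ndarray               # K x L posterior-mean cluster frequencies
    F: np.ndarray               # per-cluster drift estimates
    alpha: float
    lnL_trace: np.ndarray       # one entry per sweep (burn-in included)
    ln_evidence: float
    spec: AdmixtureModelSpec


@dataclass
class AlignedRuns:
    permutations: list          # per-run column permutation arrays
    Q_mean: np.ndarray
    dispersion: np.ndarray      # per-run mean |Q_aligned - Q_mean|


def _copy_alleles(ds: GenotypeDataset):
    """Split genotypes into two allele-copy rows per individual.

    Returns (A, obs): 2n x L allele matrices (heterozygotes contribute one
    copy of each allele) and the non-missing mask.
    """
    g = ds.calls
    n, L = g.shape
    A = np.zeros((2 * n, L), dtype=np.float64)
    A[0::2] = (g >= 1)
    A[1::2] = (g == 2)
    obs = np.repeat(g != MISSING, 2, axis=0)
    A[~obs] = 0.0
    return A, obs


def fit_admixture(ds: GenotypeDataset, spec: AdmixtureModelSpec) -> AdmixtureFit:
    """Run one Gibbs chain and return posterior means over post-burn-in sweeps."""
    n, L, K = ds.n_samples, ds.n_markers, spec.K
    if K > n:
        raise ValueError(f"K={K} exceeds the number of individuals {n}")
    rng = np.random.default_rng(spec.seed)
    A, obs = _copy_alleles(ds)
    obs_f = obs.astype(np.float64)
    sign = (2.0 * A - 1.0) * obs_f          # +1 for allele 1, -1 for allele 0
    base = (1.0 - A) * obs_f + (1.0 - obs_f)  # lik = sign*p + base

    # initial state
    alpha = spec.alpha_init
    F = np.full(K, 0.1)
    Q = rng.dirichlet(np.full(K, 1.0), size=n)
    pbar = np.full(L, 0.5)
    p = np.clip(rng.beta(1.0, 1.0, size=(K, L)), 1e-6, 1 - 1e-6)

    total = spec.burn_in + spec.reps
    trace = np.empty(total)
    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L))
    F_sum = np.zeros(K)
    alpha_sum = 0.0
    cols = np.arange(L)

    for sweep in range(total):
        # --- z: copy-level ancestry ---------------------------------------
        lik = sign[:, :, None] * p.T[None, :, :] + base[:, :, None]
        prob = Q.repeat(2, axis=0)[:, None, :] * lik
        norm = prob.sum(axis=2)
        if not np.all(norm > 0):
            raise FloatingPointError(
                f"likelihood underflow at sweep {sweep}")
        trace[sweep] = float(np.log(norm).sum())
        cum = np.cumsum(prob, axis=2)
        u = rng.random((2 * n, L, 1)) * norm[:, :, None]
        z = (u > cum).sum(axis=2)

        # --- Q | z --------------------------------------------------------
        counts = np.zeros((n, K))
        for k in range(K):
            per_copy = (z == k).sum(axis=1)
            counts[:, k] = per_copy[0::2] + per_copy[1::2]
        # floor guards against gamma underflow at very small shape, which
        # would zero a Q entry and break the log terms of the alpha update
        gam = np.maximum(rng.gamma(alpha + counts), 1e-300)
        Q = gam / gam.sum(axis=1, keepdims=True)

        # --- p | z under the F-model prior --------------------------------
        scale = (1.0 - F) / F               # (K,)
        for k in range(K):
            in_k = (z == k) & obs
            tot = in_k.sum(axis=0)
            x = (in_k & (A == 1)).sum(axis=0)
            p[k] = rng.beta(pbar * scale[k] + x,
                            (1.0 - pbar) * scale[k] + tot - x)
        p = np.clip(p, 1e-9, 1 - 1e-9)

        # --- pbar: random-walk Metropolis per locus -----------------------
        prop = pbar + rng.normal(0.0, spec.pbar_step, size=L)
        ok = (prop > 1e-6) & (prop < 1 - 1e-6)
        lp = np.log(p)
        l1p = np.log1p(-p)

        def pbar_loglik(pb):
            a = pb[None, :] * scale[:, None]
            b = (1.0 - pb)[None, :] * scale[:, None]
            ll = ((a - 1) * lp + (b - 1) * l1p - betaln(a, b)).sum(axis=0)
            return ll + (spec.lam - 1) * (np.log(pb) + np.log1p(-pb))

        cur_ll = pbar_loglik(pbar)
        prop_safe = np.where(ok, prop, 0.5)
        new_ll = pbar_loglik(prop_safe)
        accept = ok & (np.log(rng.random(L)) < new_ll - cur_ll)
        pbar = np.where(accept, prop_safe, pbar)

        # --- F_k: random-walk Metropolis ----------------------------------
        for k in range(K):
            fp = F[k] + rng.normal(0.0, spec.f_step)
            if not 1e-4 < fp < 1 - 1e-4:
                continue
            sc_new = (1.0 - fp) / fp
            a_new = pbar * sc_new
            b_new = (1.0 - pbar) * sc_new
            a_old = pbar * scale[k]
            b_old = (1.0 - pbar) * scale[k]
            ll_new = ((a_new - 1) * lp[k] + (b_new - 1) * l1p[k]
                      - betaln(a_new, b_new)).sum()
            ll_old = ((a_old - 1) * lp[k] + (b_old - 1) * l1p[k]
                      - betaln(a_old, b_old)).sum()
            if np.log(rng.random()) < ll_new - ll_old:
                F[k] = fp

        # --- alpha: random-walk Metropolis --------------------------------
        if K > 1:
            ap = alpha + rng.normal(0.0, spec.alpha_step)
            if 1e-4 < ap <= spec.alpha_max:
                slq = np.log(Q).sum()
                ll_new = n * (gammaln(K * ap) - K * gammaln(ap)) \
                    + (ap - 1) * slq
                ll_old = n * (gammaln(K * alpha) - K * gammaln(alpha)) \
                    + (alpha - 1) * slq
                if np.log(rng.random()) < ll_new - ll_old:
                    alpha = ap

        if sweep >= spec.burn_in:
            Q_sum += Q
            P_sum += p
            F_sum += F
            alpha_sum += alpha

    post = spec.reps
    Q_mean = Q_sum / post
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    return AdmixtureFit(
        Q=Q_mean, P=P_sum / post, F=F_sum / post, alpha=alpha_sum / post,
        lnL_trace=trace,
        ln_evidence=ln_evidence(trace[spec.burn_in:]),
        spec=spec)


def ln_evidence(trace) -> float:
    """STRUCTURE-style evidence: mean(lnL) - var(lnL)/2 (sample variance)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("post-burn-in trace must have at least 2 sweeps")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


def delta_k(evidence: dict[int, list[float]]) -> pd.DataFrame:
    """Evanno ΔK table from per-K ln-evidence values over independent runs.

    ΔK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); endpoints
    are undefined (NaN) and a zero sd flags the entry as infinite.
    """
    ks = sorted(evidence)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks[:-1], ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(evidence[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(evidence[k])) for k in ks}
    sd = {k: float(np.std(evidence[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            dk = np.nan
        else:
            num = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = np.inf if sd[k] == 0 else num / sd[k]
        rows.append((k, mean[k], sd[k], dk))
    return pd.DataFrame(rows, columns=["K", "mean_ln_evidence",
                                       "sd_ln_evidence", "delta_k"])


def select_k(evidence: dict[int, list[float]]) -> int:
    """Choose the number of clusters from per-K ln-evidence over runs.

    Uses the rate-of-change criterion: the K maximizing the Evanno ΔK
    second-difference statistic.  Raw argmax of the evidence is unreliable
    for this estimator, which typically plateaus (with small noisy gains)
    beyond the true K; the second difference isolates the K where the
    evidence stops improving.  Endpoint K values cannot be selected — the
    standard caveat of the ΔK approach.
    """
    tab = delta_k(evidence)
    inner = tab.dropna(subset=["delta_k"])
    return int(inner.loc[inner["delta_k"].idxmax(), "K"])


def align_runs(runs: list[np.ndarray]) -> AlignedRuns:
    """Resolve label switching across independent runs.

    The first run anchors the reference; each later run's columns are
    permuted to minimize the total absolute difference to the running mean
    of the already-aligned runs (optimal assignment), after which all
    aligned runs are averaged.
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    shape = runs[0].shape
    if any(r.shape != shape for r in runs):
        raise ValueError("all runs must share the same (n, K) shape")
    K = shape[1]
    aligned = [runs[0]]
    perms = [np.arange(K)]
    ref_sum = runs[0].copy()
    for r in runs[1:]:
        ref = ref_sum / len(aligned)
        cost = np.zeros((K, K))     # cost[src, tgt] = L1 mismatch
        for src in range(K):
            cost[src] = np.abs(r[:, src, None] - ref).sum(axis=0)
        row, col = linear_sum_assignment(cost)
        perm = row[np.argsort(col)]  # perm[tgt] = source column
        a = r[:, perm]
        perms.append(perm)
        aligned.append(a)
        ref_sum += a
    Q_mean = ref_sum / len(aligned)
    dispersion = np.array([np.abs(a - Q_mean).mean() for a in aligned])
    return AlignedRuns(permutations=perms, Q_mean=Q_mean,
                       dispersion=dispersion)


def fit_multiple(ds: GenotypeDataset, spec: AdmixtureModelSpec):
    """Independent chains (different seeds), aligned and averaged.

    Returns ``(fits, AlignedRuns)``; per-run seeds derive from ``spec.seed``
    by fixed offsets.
    """
    fits = []
    for run in range(spec.n_runs):
        run_spec = AdmixtureModelSpec(
            K=spec.K, alpha_init=spec.alpha_init, lam=spec.lam,
            burn_in=spec.burn_in, reps=spec.reps, n_runs=1,
            seed=spec.seed + 1000 * run + 1,
            alpha_max=spec.alpha_max, alpha_step=spec.alpha_step,
            f_step=spec.f_step, pbar_step=spec.pbar_step)
        fits.append(fit_admixture(ds, run_spec))
    aligned = align_runs([f.Q for f in fits])
    return fits, aligned
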