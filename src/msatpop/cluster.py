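"""Bayesian admixture-model clustering by Gibbs sampling.

The model: each of K clusters has its own allele-frequency vectors
(independent across clusters, symmetric Dirichlet(lambda) prior); each
diploid individual has membership proportions Q ~ Dirichlet(alpha); every
observed allele copy carries a latent cluster-of-origin Z. One sweep
samples Z | P,Q, then P | Z and Q | Z from their Dirichlet full
conditionals; the shared admixture hyperparameter alpha takes a
random-walk Metropolis step under a uniform prior on (0, alpha_max).
Missing allele copies are skipped everywhere.

Model choice per K uses the harmonic-style estimator
``Ln P(D) = mean(lnL) - var(lnL)/2`` on the post-burn-in likelihood
trace, and the second-order rate-of-change statistic delta-K across K.
Replicate runs are merged after greedy label alignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .genotype import MISSING, GenotypeMatrix


@dataclass
class MCMCConfig:
    k: int
    burn_in: int = 5_000
    n_reps: int = 20_000
    lamb: float = 1.0
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.025
    thin: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.burn_in <= 0 or self.n_reps <= 0:
            raise ValueError("burn_in and n_reps must be positive")
        if self.lamb <= 0:
            raise ValueError("lambda must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class RunResult:
    q: np.ndarray  # (n, k), rows sum to 1
    ln_pd: float
    ln_l_mean: float
    ln_l_var: float
    alpha_mean: float
    alpha_range: tuple[float, float]
    k: int
    sample_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if self.ln_pd > self.ln_l_mean + 1e-9:
            raise ValueError("Ln P(D) cannot exceed the mean log-likelihood")


def code_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integer-code alleles per locus: (n, L, 2) codes, -1 = missing.

    Returns the code array and the per-locus allele-size ladders.
    """
    arr = matrix.allele_array()
    n, L, _ = arr.shape
    coded = np.full((n, L, 2), -1, dtype=np.int64)
    ladders = []
    for j in range(L):
        present = arr[:, j, 0] > MISSING
        alleles = np.unique(arr[present, j, :])
        ladders.append(alleles)
        lookup = {a: i for i, a in enumerate(alleles)}
        for i in range(n):
            if present[i]:
                coded[i, j, 0] = lookup[arr[i, j, 0]]
                coded[i, j, 1] = lookup[arr[i, j, 1]]
    return coded, ladders


def loglik(coded: np.ndarray, q: np.ndarray, p: np.ndarray) -> float:
    """ln P(data | P, Q): sum over observed allele copies of
    ``log(sum_k Q[i,k] * P[k, locus, allele])``."""
    i_idx, l_idx, c_idx = np.nonzero(coded >= 0)
    a_idx = coded[i_idx, l_idx, c_idx]
    pk = p[:, l_idx, a_idx]  # (K, M)
    per_copy = np.sum(q[i_idx] * pk.T, axis=1)
    return float(np.sum(np.log(np.maximum(per_copy, 1e-300))))


def _dirichlet_sym_loglik(q: np.ndarray, alpha: float) -> float:
    """Sum over rows of log Dirichlet(alpha,...,alpha) density."""
    n, k = q.shape
    const = gammaln(k * alpha) - k * gammaln(alpha)
    return float(n * const + (alpha - 1.0) * np.sum(np.log(np.maximum(q, 1e-300))))


def run_admixture(matrix: GenotypeMatrix, config: MCMCConfig) -> RunResult:
    """One MCMC run; returns the posterior-mean Q and trace summaries."""
    if matrix.n_samples == 0:
        raise ValueError("empty matrix")
    coded, ladders = code_matrix(matrix)
    return _run_admixture_coded(
        coded, [len(l) for l in ladders], config, sample_ids=matrix.sample_ids
    )


def _run_admixture_coded(
    coded: np.ndarray,
    n_alleles: Sequence[int],
    config: MCMCConfig,
    sample_ids: Sequence[str] | None = None,
) -> RunResult:
    rng = np.random.default_rng(config.seed)
    n, L, _ = coded.shape
    K = config.k
    A = max(n_alleles)
    valid = np.zeros((L, A), dtype=bool)
    for j, na in enumerate(n_alleles):
        valid[j, :na] = True

    # flat view of observed allele copies
    i_idx, l_idx, c_idx = np.nonzero(coded >= 0)
    a_idx = coded[i_idx, l_idx, c_idx]
    M = i_idx.size
    if M == 0:
        raise ValueError("matrix contains no typed allele copies")
    flat_pla = l_idx * A + a_idx  # locus-allele flat index for P counts

    lamb = config.lamb
    alpha = config.alpha_init

    # initial state: uniform memberships, prior frequencies
    q = np.full((n, K), 1.0 / K)
    p = rng.gamma(lamb, size=(K, L, A)) * valid
    p /= p.sum(axis=2, keepdims=True)

    total_iters = config.burn_in + config.n_reps
    lnl_trace = np.empty(config.n_reps)
    alpha_trace = np.empty(config.n_reps)
    q_accum = np.zeros((n, K))
    n_q_samples = 0

    for it in range(total_iters):
        if K == 1:
            z = np.zeros(M, dtype=np.int64)
        else:
            w = q[i_idx] * p[:, l_idx, a_idx].T  # (M, K)
            cum = np.cumsum(w, axis=1)
            u = rng.random(M) * cum[:, -1]
            z = (cum > u[:, None]).argmax(axis=1)

        # P | Z
        counts_p = np.bincount(z * (L * A) + flat_pla, minlength=K * L * A).reshape(
            K, L, A
        )
        p = rng.gamma(lamb + counts_p) * valid
        p /= np.maximum(p.sum(axis=2, keepdims=True), 1e-300)

        # Q | Z
        if K == 1:
            q = np.ones((n, 1))
        else:
            counts_q = np.bincount(i_idx * K + z, minlength=n * K).reshape(n, K)
            q = rng.gamma(alpha + counts_q)
            q /= np.maximum(q.sum(axis=1, keepdims=True), 1e-300)

            # alpha | Q: random-walk Metropolis, uniform prior on (0, alpha_max)
            prop = alpha + rng.normal(0.0, config.alpha_proposal_sd)
            if 0.0 < prop < config.alpha_max:
                log_ratio = _dirichlet_sym_loglik(q, prop) - _dirichlet_sym_loglik(
                    q, alpha
                )
                if math.log(rng.random()) < log_ratio:
                    alpha = prop

        if it >= config.burn_in:
            t = it - config.burn_in
            pk = p[:, l_idx, a_idx]  # (K, M)
            per_copy = np.sum(q[i_idx] * pk.T, axis=1)
            lnl_trace[t] = np.sum(np.log(np.maximum(per_copy, 1e-300)))
            alpha_trace[t] = alpha
            if t % config.thin == 0:
                q_accum += q
                n_q_samples += 1

    q_mean = q_accum / n_q_samples
    q_mean /= q_mean.sum(axis=1, keepdims=True)

    warnings_list: list[str] = []
    a_min, a_max = float(alpha_trace.min()), float(alpha_trace.max())
    if K > 1 and (a_max - a_min) > config.alpha_max / 2:
        warnings_list.append(
            f"alpha range ({a_min:.3f}, {a_max:.3f}) exceeds half of alpha_max; "
            "chain may not have converged"
        )

    mean_l = float(lnl_trace.mean())
    var_l = float(lnl_trace.var(ddof=1))  # sample variance, n - 1
    return RunResult(
        q=q_mean,
        ln_pd=mean_l - var_l / 2.0,
        ln_l_mean=mean_l,
        ln_l_var=var_l,
        alpha_mean=float(alpha_trace.mean()),
        alpha_range=(a_min, a_max),
        k=K,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
        warnings=warnings_list,
    )


def ln_pd(ln_l_trace: Sequence[float]) -> float:
    """Model log probability: ``mean(trace) - var(trace)/2`` (sample variance)."""
    trace = np.asarray(ln_l_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 entries")
    return float(trace.mean() - trace.var(ddof=1) / 2.0)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvannoSummary:
    ks: tuple[int, ...]
    mean_l: tuple[float, ...]
    sd_l: tuple[float, ...]
    l_prime: tuple[float, ...]  # NaN where undefined
    abs_l_double_prime: tuple[float, ...]
    delta_k: tuple[float, ...]
    best_k: int | None

    def as_rows(self):
        for i, k in enumerate(self.ks):
            yield {
                "K": k,
                "mean_LnPD": self.mean_l[i],
                "sd_LnPD": self.sd_l[i],
                "L_prime": self.l_prime[i],
                "abs_L_double_prime": self.abs_l_double_prime[i],
                "delta_K": self.delta_k[i],
            }


def evanno(ln_pd_by_k: Mapping[int, Sequence[float]]) -> EvannoSummary:
    """Delta-K model choice over replicate Ln P(D) values per K.

    ``L'(K) = mean_L(K) - mean_L(K-1)``, ``|L''(K)| = |L'(K+1) - L'(K)|``,
    ``delta_K = |L''(K)| / sd_L(K)``; defined only for interior K with a
    positive replicate standard deviation. ``best_k`` is the argmax over
    defined values (None when none is defined).
    """
    ks = sorted(ln_pd_by_k)
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K values must be consecutive")
    mean_l = np.array([np.mean(ln_pd_by_k[k]) for k in ks])
    sd_l = np.array([np.std(ln_pd_by_k[k], ddof=1) for k in ks])

    nan = float("nan")
    l_prime = [nan] + [float(mean_l[i] - mean_l[i - 1]) for i in range(1, len(ks))]
    abs_lpp = [nan] * len(ks)
    delta = [nan] * len(ks)
    for i in range(1, len(ks) - 1):
        abs_lpp[i] = abs(l_prime[i + 1] - l_prime[i])
        if sd_l[i] > 0:
            delta[i] = abs_lpp[i] / sd_l[i]
    defined = [i for i in range(len(ks)) if not math.isnan(delta[i])]
    best_k = ks[max(defined, key=lambda i: delta[i])] if defined else None
    return EvannoSummary(
        ks=tuple(ks),
        mean_l=tuple(float(x) for x in mean_l),
        sd_l=tuple(float(x) for x in sd_l),
        l_prime=tuple(l_prime),
        abs_l_double_prime=tuple(abs_lpp),
        delta_k=tuple(delta),
        best_k=best_k,
    )


def write_evanno_tsv(summary: EvannoSummary, path) -> None:
    lines = ["K\tmean_LnPD\tsd_LnPD\tL_prime\tabs_L_double_prime\tdelta_K"]
    for row in summary.as_rows():
        lines.append(
            "\t".join(
                str(row["K"]) if c == "K" else f"{row[c]:.4f}"
                for c in (
                    "K",
                    "mean_LnPD",
                    "sd_LnPD",
                    "L_prime",
                    "abs_L_double_prime",
                    "delta_K",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# replicate-run merging (label alignment)
# ---------------------------------------------------------------------------

def align_and_merge(runs: Sequence[RunResult]) -> np.ndarray:
    """Average replicate Q matrices after greedy column alignment.

    The first run anchors the labeling; each further run contributes the
    column permutation maximizing the sum of elementwise products with
    the running reference (exhaustive over permutations, fine for K <= 6).
    Rows of the merged matrix are renormalized to sum to 1.
    """
    if not runs:
        raise ValueError("no runs to merge")
    k = runs[0].k
    n = runs[0].q.shape[0]
    for r in runs:
        if r.k != k or r.q.shape[0] != n:
            raise ValueError("runs must share K and sample count")
    acc = runs[0].q.copy()
    for r in runs[1:]:
        best_perm = None
        best_score = -np.inf
        for perm in itertools.permutations(range(k)):
            score = float(np.sum(acc * r.q[:, perm]))
            if score > best_score:
                best_score = score
                best_perm = perm
        acc += r.q[:, best_perm]
    merged = acc / len(runs)
    merged /= merged.sum(axis=1, keepdims=True)
    return merged


def write_q_tsv(q: np.ndarray, sample_ids: Sequence[str], path) -> None:
    k = q.shape[1]
    lines = ["sample_id\t" + "\t".join(f"Q{c + 1}" for c in range(k))]
    for sid, row in zip(sample_ids, q):
        lines.append(sid + "\t" + "\t".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
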