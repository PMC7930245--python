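"""Dirichlet-process mixture clustering of mutations across N samples.

Mutations are clustered on their joint (alt count, depth) profile across
all samples: alt_{m,s} ~ Binomial(depth_{m,s}, theta_{k,s}) for mutation m
in cluster k, with independent Beta(1,1) priors on the per-sample success
probabilities theta and a Chinese-restaurant-process prior on the
partition. Because the likelihood works on raw counts it naturally weighs
samples by their coverage and needs no hard VAF cut-offs.

Inference is collapsed Gibbs sampling: theta is integrated out of the
assignment moves through the beta-binomial predictive, and the DP
concentration alpha is resampled from its conditional under a Gamma prior
(Escobar & West auxiliary-variable step). The compute-heavy sweep is a
numba kernel; a seed makes the whole run deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .datatypes import VariantTable

DEFAULT_N_ITER = 2000
DEFAULT_BURN_IN = 500
DEFAULT_ALPHA_PRIOR = (1.0, 1.0)
DEFAULT_MIN_CLUSTER_SIZE = 5


class EmptyInputError(ValueError):
    """Clustering was asked for zero somatic mutations."""


class DegeneratePartitionError(ValueError):
    """Every cluster in the chosen state is below the minimum size."""


@njit(cache=True)
def _betaln(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def _gibbs_kernel(alt, depth, n_iter, burn_in, seed, a_shape, a_rate, alpha0, sample_alpha):
    """Collapsed CRP/binomial Gibbs sweep. Returns (states, alphas, logposts)."""
    np.random.seed(seed)
    M, S = alt.shape
    ref = depth - alt
    cap = M + 1
    A = np.zeros((cap, S))
    B = np.zeros((cap, S))
    lognorm = np.zeros((cap, S))  # betaln(1+A, 1+B) cache per active slot
    nk = np.zeros(cap, np.int64)
    z = np.zeros(M, np.int64)

    for m in range(M):
        for s in range(S):
            A[0, s] += alt[m, s]
            B[0, s] += ref[m, s]
    nk[0] = M
    for s in range(S):
        lognorm[0, s] = _betaln(1.0 + A[0, s], 1.0 + B[0, s])

    free = np.empty(cap, np.int64)
    n_free = 0
    high = 1  # slots ever allocated
    alpha = alpha0

    n_keep = n_iter - burn_in
    states = np.empty((n_keep, M), np.int64)
    alphas = np.empty(n_keep)
    logposts = np.empty(n_keep)
    logw = np.empty(cap)
    cand = np.empty(cap, np.int64)

    for it in range(n_iter):
        for m in range(M):
            k_old = z[m]
            nk[k_old] -= 1
            for s in range(S):
                A[k_old, s] -= alt[m, s]
                B[k_old, s] -= ref[m, s]
            if nk[k_old] == 0:
                free[n_free] = k_old
                n_free += 1
            else:
                for s in range(S):
                    lognorm[k_old, s] = _betaln(1.0 + A[k_old, s], 1.0 + B[k_old, s])

            nc = 0
            for k in range(high):
                if nk[k] > 0:
                    w = math.log(nk[k])
                    for s in range(S):
                        w += (
                            _betaln(1.0 + A[k, s] + alt[m, s], 1.0 + B[k, s] + ref[m, s])
                            - lognorm[k, s]
                        )
                    logw[nc] = w
                    cand[nc] = k
                    nc += 1
            w = math.log(alpha)
            for s in range(S):
                w += _betaln(1.0 + alt[m, s], 1.0 + ref[m, s])
            logw[nc] = w
            cand[nc] = -1
            nc += 1

            mx = logw[0]
            for i in range(1, nc):
                if logw[i] > mx:
                    mx = logw[i]
            tot = 0.0
            for i in range(nc):
                logw[i] = math.exp(logw[i] - mx)
                tot += logw[i]
            u = np.random.random() * tot
            acc = 0.0
            pick = nc - 1
            for i in range(nc):
                acc += logw[i]
                if u <= acc:
                    pick = i
                    break
            k_new = cand[pick]
            if k_new == -1:
                if n_free > 0:
                    n_free -= 1
                    k_new = free[n_free]
                else:
                    k_new = high
                    high += 1
                for s in range(S):
                    A[k_new, s] = 0.0
                    B[k_new, s] = 0.0
            z[m] = k_new
            nk[k_new] += 1
            for s in range(S):
                A[k_new, s] += alt[m, s]
                B[k_new, s] += ref[m, s]
                lognorm[k_new, s] = _betaln(1.0 + A[k_new, s], 1.0 + B[k_new, s])

        K = 0
        for k in range(high):
            if nk[k] > 0:
                K += 1

        if sample_alpha:
            # Escobar & West auxiliary update of the DP concentration
            eta = np.random.beta(alpha + 1.0, M)
            rate = a_rate - math.log(eta)
            num = a_shape + K - 1.0
            pi = num / (num + M * rate)
            if np.random.random() < pi:
                alpha = np.random.gamma(a_shape + K, 1.0 / rate)
            else:
                alpha = np.random.gamma(a_shape + K - 1.0, 1.0 / rate)
            if alpha < 1e-12:
                alpha = 1e-12

        if it >= burn_in:
            lp = K * math.log(alpha) + math.lgamma(alpha) - math.lgamma(alpha + M)
            for k in range(high):
                if nk[k] > 0:
                    lp += math.lgamma(float(nk[k]))
                    for s in range(S):
                        lp += lognorm[k, s]
            if sample_alpha:
                lp += (a_shape - 1.0) * math.log(alpha) - a_rate * alpha
            j = it - burn_in
            states[j] = z
            alphas[j] = alpha
            logposts[j] = lp

    return states, alphas, logposts


def _canonical(state: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance so labels are reproducible."""
    out = np.empty_like(state)
    mapping: dict[int, int] = {}
    for i, k in enumerate(state):
        k = int(k)
        if k not in mapping:
            mapping[k] = len(mapping)
        out[i] = mapping[k]
    return out


@dataclass
class PosteriorTrace:
    """Retained post-burn-in states of one Gibbs run."""

    assignments: np.ndarray  # (n_states, n_mutations), canonical labels
    alphas: np.ndarray
    log_posteriors: np.ndarray
    mutation_ids: pd.Index
    sample_ids: list[str]
    alt: np.ndarray
    depth: np.ndarray
    seed: int

    @property
    def n_states(self) -> int:
        return self.assignments.shape[0]

    def cluster_counts(self) -> np.ndarray:
        return np.array([len(np.unique(s)) for s in self.assignments])

    def co_assignment(self, max_states: int = 200) -> pd.DataFrame:
        """Mutation x mutation co-clustering frequency.

        Averaged over at most ``max_states`` evenly spaced retained states
        (the matrix is quadratic in the number of mutations, so thinning
        keeps diagnostics cheap without biasing the estimate).
        """
        idx = np.linspace(0, self.n_states - 1, min(max_states, self.n_states)).astype(int)
        idx = np.unique(idx)
        m = self.assignments.shape[1]
        co = np.zeros((m, m))
        for i in idx:
            s = self.assignments[i]
            co += s[:, None] == s[None, :]
        co /= len(idx)
        return pd.DataFrame(co, index=self.mutation_ids, columns=self.mutation_ids)


@dataclass
class MutationCluster:
    """One inferred clone branch: member mutations and per-sample VAF."""

    cluster_id: int
    members: list[str]
    theta_hat: pd.Series  # posterior-mean VAF per sample
    prevalence: pd.Series  # min(1, 2 * theta) under the diploid assumption

    @property
    def burden(self) -> int:
        return len(self.members)


def gibbs_run(
    table: VariantTable,
    presence=None,
    n_iter: int = DEFAULT_N_ITER,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
    alpha_prior: tuple[float, float] = DEFAULT_ALPHA_PRIOR,
    fixed_alpha: float | None = None,
) -> PosteriorTrace:
    """Run the collapsed Gibbs sampler on the (somatic) variant table.

    ``presence`` is accepted for signature parity with the pipeline but
    does not alter the likelihood: the mixture model itself accounts for
    noise, and presence calls are only used downstream for reporting.
    """
    if table.n_sites == 0:
        raise EmptyInputError("no somatic mutations to cluster")
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    alt = np.ascontiguousarray(table.alt.to_numpy(np.int64))
    depth = np.ascontiguousarray(table.depth.to_numpy(np.int64))
    a_shape, a_rate = alpha_prior
    sample_alpha = fixed_alpha is None
    alpha0 = 1.0 if sample_alpha else float(fixed_alpha)
    states, alphas, logposts = _gibbs_kernel(
        alt,
        depth,
        int(n_iter),
        int(burn_in),
        int(seed),
        float(a_shape),
        float(a_rate),
        alpha0,
        sample_alpha,
    )
    states = np.stack([_canonical(s) for s in states])
    return PosteriorTrace(
        assignments=states,
        alphas=alphas,
        log_posteriors=logposts,
        mutation_ids=table.site_ids,
        sample_ids=table.samples,
        alt=alt,
        depth=depth,
        seed=int(seed),
    )


def sample_theta(
    alt: np.ndarray, depth: np.ndarray, assignment: np.ndarray, n_draws: int, seed: int = 0
) -> np.ndarray:
    """Draw theta from its conditional posterior for a fixed partition.

    Given the assignment, theta_{k,s} | data ~ Beta(1 + sum alt,
    1 + sum(depth - alt)) over cluster members. Returns draws of shape
    (n_draws, n_clusters, n_samples) with clusters in sorted label order.
    """
    rng = np.random.default_rng(seed)
    labels = np.unique(assignment)
    a = np.stack([alt[assignment == k].sum(axis=0) for k in labels]).astype(float)
    b = np.stack([(depth - alt)[assignment == k].sum(axis=0) for k in labels]).astype(float)
    return rng.beta(1.0 + a, 1.0 + b, size=(n_draws,) + a.shape)


def point_estimate(
    trace: PosteriorTrace, min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE
) -> list[MutationCluster]:
    """Deterministic partition: the retained state of maximal posterior density.

    Clusters smaller than ``min_cluster_size`` are dissolved and their
    members reassigned to the surviving cluster with the highest binomial
    likelihood; theta is then the conditional posterior mean
    (1 + sum alt) / (2 + sum depth) under the final membership.
    """
    if trace.n_states == 0:
        raise ValueError("empty trace")
    best = int(np.argmax(trace.log_posteriors))
    z = trace.assignments[best].copy()
    labels, counts = np.unique(z, return_counts=True)
    survivors = labels[counts >= min_cluster_size]
    if survivors.size == 0:
        raise DegeneratePartitionError(
            f"no cluster reaches min_cluster_size={min_cluster_size}"
        )
    if survivors.size < labels.size:
        theta = np.stack(
            [
                (1.0 + trace.alt[z == k].sum(axis=0))
                / (2.0 + trace.depth[z == k].sum(axis=0))
                for k in survivors
            ]
        )
        doomed = ~np.isin(z, survivors)
        ll = np.stack(
            [
                stats.binom.logpmf(trace.alt[doomed], trace.depth[doomed], t).sum(axis=1)
                for t in theta
            ]
        )
        z[doomed] = survivors[np.argmax(ll, axis=0)]

    clusters = []
    for new_id, k in enumerate(np.unique(z)):
        members = z == k
        theta = (1.0 + trace.alt[members].sum(axis=0)) / (
            2.0 + trace.depth[members].sum(axis=0)
        )
        theta_s = pd.Series(theta, index=trace.sample_ids)
        clusters.append(
            MutationCluster(
                cluster_id=new_id,
                members=list(trace.mutation_ids[members]),
                theta_hat=theta_s,
                prevalence=np.minimum(1.0, 2.0 * theta_s),
            )
        )
    return clusters
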