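"""Supervised admixture estimation from polyTE dosages.

The model: individual i's dosage at locus l is Binomial(2, p_il) with
p_il = sum_k q_ik f_kl, where f_kl are insertion-allele frequencies of K
ancestral clusters and q_i is the individual's ancestry-fraction vector on
the simplex. Supervised estimation is two-phase: cluster frequencies come in
closed form from labelled reference individuals (targets never inform F),
then each target's q is the maximum-likelihood point found by EM on the
simplex from a uniform start — fully deterministic, no seed involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_panel import DosageMatrix, PopulationPanel

__all__ = [
    "AncestralFrequencies",
    "AncestryFractions",
    "estimate_ancestral_frequencies",
    "estimate_q",
    "estimate_q_batch",
    "supervised_admixture",
]

DEFAULT_EPSILON = 1e-4
DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 2000


@dataclass
class AncestralFrequencies:
    """Per-cluster insertion-allele frequencies over an active marker set.

    Frequencies are clamped to [epsilon, 1 - epsilon] so the binomial
    log-likelihood stays finite for any dosage.
    """

    clusters: list[str]
    locus_ids: list[str]
    freq: np.ndarray  # (K, L)
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.clusters), len(self.locus_ids)):
            raise ValueError("freq shape inconsistent with clusters x loci")
        if (self.freq < self.epsilon - 1e-15).any() or \
           (self.freq > 1 - self.epsilon + 1e-15).any():
            raise ValueError("frequencies not clamped to [eps, 1-eps]")

    @property
    def k(self) -> int:
        return len(self.clusters)

    def degenerate_pairs(self, atol: float = 1e-12) -> list[tuple[str, str]]:
        """Cluster pairs with identical frequency vectors (q unidentifiable
        between them)."""
        out = []
        for i in range(self.k):
            for j in range(i + 1, self.k):
                if np.allclose(self.freq[i], self.freq[j], atol=atol):
                    out.append((self.clusters[i], self.clusters[j]))
        return out


@dataclass
class AncestryFractions:
    """Per-individual ancestry fractions q over K clusters (simplex rows)."""

    samples: list[str]
    clusters: list[str]
    q: np.ndarray  # (N, K)
    log_likelihood: np.ndarray  # (N,)
    n_iter: np.ndarray  # (N,)
    converged: np.ndarray  # (N,) bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=self.samples, columns=self.clusters)

    def write_q(self, path) -> None:
        """Whitespace-delimited K-column Q matrix, one row per individual."""
        np.savetxt(path, self.q, fmt="%.6f", delimiter=" ")


def estimate_ancestral_frequencies(
    m: DosageMatrix,
    labels: Mapping[str, str] | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> AncestralFrequencies:
    """Closed-form cluster frequencies from labelled reference individuals.

    f_kl = (insertion alleles in cluster k at locus l) / (2 n_k), clamped to
    [epsilon, 1 - epsilon]. Every reference sample carries exactly one
    cluster label; an empty cluster is an error.
    """
    labels = dict(labels)
    clusters = sorted(set(labels.values()))
    F = np.empty((len(clusters), m.n_loci))
    for k, cl in enumerate(clusters):
        members = [s for s in m.samples if labels.get(s) == cl]
        if not members:
            raise ValueError(f"cluster {cl!r} has no reference samples")
        idx = m.sample_indices(members)
        F[k] = m.dosage[idx].sum(axis=0, dtype=np.int64) / (2.0 * len(members))
    F = np.clip(F, epsilon, 1.0 - epsilon)
    return AncestralFrequencies(clusters, m.locus_ids, F, epsilon)


def _loglik(G: np.ndarray, P: np.ndarray) -> np.ndarray:
    return (G * np.log(P) + (2.0 - G) * np.log1p(-P)).sum(axis=1)


def estimate_q_batch(
    G: np.ndarray,
    F: AncestralFrequencies,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """EM maximisation of the fixed-F binomial likelihood for many targets.

    Each row of ``G`` is one individual's dosage vector over F's loci. The
    multiplicative EM update on the simplex,

        q_k <- q_k / (2L) * sum_l [ g_l f_kl / p_l + (2-g_l)(1-f_kl)/(1-p_l) ],

    never decreases the log-likelihood (asserted each iteration) and stops
    when the improvement drops below ``tol`` or after ``max_iter`` sweeps.
    Uniform initialisation makes the whole procedure deterministic.

    Returns (q, log_likelihood, n_iter, converged).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    N, L = G.shape
    K = F.k
    if L != len(F.locus_ids):
        raise ValueError("dosage vector length does not match F's locus set")
    if L == 0:
        raise ValueError("empty marker set")
    Fm = F.freq  # (K, L)
    Q = np.full((N, K), 1.0 / K)
    P = Q @ Fm
    ll = _loglik(G, P)
    if not np.isfinite(ll).all():
        raise FloatingPointError("non-finite likelihood at initialisation")
    n_iter = np.zeros(N, dtype=int)
    converged = np.zeros(N, dtype=bool)
    act = np.arange(N)
    for it in range(1, max_iter + 1):
        Ga, Qa = G[act], Q[act]
        Pa = Qa @ Fm
        A = Ga / Pa            # (n, L)
        B = (2.0 - Ga) / (1.0 - Pa)
        Qn = Qa * (A @ Fm.T + B @ (1.0 - Fm).T) / (2.0 * L)
        Qn /= Qn.sum(axis=1, keepdims=True)
        ll_new = _loglik(Ga, Qn @ Fm)
        if not np.isfinite(ll_new).all():
            raise FloatingPointError("non-finite likelihood during EM")
        if (ll_new < ll[act] - 1e-8 * (1 + np.abs(ll[act]))).any():
            raise AssertionError("EM decreased the log-likelihood")
        improved = ll_new - ll[act]
        Q[act] = Qn
        ll[act] = ll_new
        n_iter[act] = it
        done = improved < tol
        converged[act[done]] = True
        act = act[~done]
        if act.size == 0:
            break
    return Q, ll, n_iter, converged


def estimate_q(
    g: np.ndarray,
    F: AncestralFrequencies,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, float]:
    """Ancestry fractions for one individual; returns (q, log_likelihood)."""
    Q, ll, _, _ = estimate_q_batch(np.asarray(g)[None, :], F, tol, max_iter)
    return Q[0], float(ll[0])


def supervised_admixture(
    m: DosageMatrix,
    panel: PopulationPanel,
    reference_groups: Sequence[str],
    target_samples: Sequence[str],
    marker_subset: Sequence[str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> AncestryFractions:
    """Supervised ancestry fractions for target individuals.

    Reference clusters are the continental groups in ``reference_groups``;
    their member samples (which must be disjoint from the targets) provide
    closed-form cluster frequencies over ``marker_subset`` (default: all
    loci), and each target's q is then estimated by EM. Identical reference
    clusters leave q unidentifiable between them; such pairs trigger a
    warning.
    """
    targets = list(target_samples)
    if marker_subset is not None:
        m = m.subset_loci(list(marker_subset))
        if m.n_loci == 0:
            raise ValueError("marker subset is empty")
    labels = {}
    for g in reference_groups:
        for s in panel.samples_in_group(g):
            if s in set(m.samples):
                labels[s] = g
    overlap = set(labels) & set(targets)
    if overlap:
        raise ValueError(f"targets overlap reference set: {sorted(overlap)[:5]}")
    refs = [s for s in m.samples if s in labels]
    F = estimate_ancestral_frequencies(m.subset_samples(refs),
                                       {s: labels[s] for s in refs}, epsilon)
    degen = F.degenerate_pairs()
    if degen:
        warnings.warn(
            f"identical reference clusters (q unidentifiable): {degen}",
            UserWarning, stacklevel=2,
        )
    G = m.dosage[m.sample_indices(targets)]
    Q, ll, n_iter, conv = estimate_q_batch(G, F, tol, max_iter)
    return AncestryFractions(targets, F.clusters, Q, ll, n_iter, conv)
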