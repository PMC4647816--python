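"""Marker-subset ancestry prediction and admixture prediction error.

How few polyTE loci suffice to call continental ancestry? Loci are ranked
by their multi-group Weir–Cockerham F_ST; nested top-n subsets feed a
cross-validated supervised-admixture classifier (80/20 stratified splits,
an individual is called to its argmax cluster only when max q >= 0.9), and
an admixed-cohort analysis compares subset-based ancestry fractions to the
full-locus-set estimates via RMSD and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .admixture import (DEFAULT_EPSILON, DEFAULT_MAX_ITER, DEFAULT_TOL,
                        estimate_ancestral_frequencies, estimate_q_batch)
from .io_panel import DosageMatrix, PopulationPanel
from .popgen_stats import weir_cockerham_fst

__all__ = [
    "MarkerSubset",
    "rank_loci",
    "default_subset_sizes",
    "ancestry_cv",
    "admixture_prediction_error",
]


@dataclass
class MarkerSubset:
    """Loci ranked by descending F_ST; top-n prefixes are nested subsets."""

    locus_ids: list[str]
    fst: np.ndarray

    def top(self, n: int) -> list[str]:
        if n > len(self.locus_ids):
            raise ValueError(f"requested top {n} of {len(self.locus_ids)} loci")
        return self.locus_ids[:n]

    def __len__(self) -> int:
        return len(self.locus_ids)


def rank_loci(stats: pd.DataFrame, n_top: int | None = None) -> MarkerSubset:
    """Rank loci by descending F_ST, ties broken by (chrom, pos).

    ``stats`` is a per-locus table with columns locus_id, chrom, pos, fst
    (and optionally fst_defined). Loci with undefined F_ST are excluded
    before ranking.
    """
    df = stats
    if "fst_defined" in df.columns:
        df = df[df["fst_defined"]]
    df = df.dropna(subset=["fst"])
    df = df.sort_values(["fst", "chrom", "pos"],
                        ascending=[False, True, True], kind="mergesort")
    if n_top is not None:
        if n_top > len(df):
            raise ValueError(f"n_top={n_top} exceeds {len(df)} ranked loci")
        df = df.head(n_top)
    return MarkerSubset(df["locus_id"].tolist(), df["fst"].to_numpy())


def default_subset_sizes(full: int = 500, smallest: int = 10,
                         step: int = 10) -> list[int]:
    """The sweep grid 500, 490, ..., 10."""
    return list(range(full, smallest - 1, -step))


def _stratified_split(panel: PopulationPanel, samples: Sequence[str],
                      groups: Sequence[str], split: float,
                      rng: np.random.Generator):
    """80/20-style split within each group; returns (train, test) lists."""
    train, test = [], []
    sset = set(samples)
    for g in groups:
        members = [s for s in panel.samples_in_group(g) if s in sset]
        n_train = int(round(split * len(members)))
        if n_train < 1 or n_train >= len(members):
            raise ValueError(f"group {g!r} too small to stratify")
        perm = rng.permutation(len(members))
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    return train, test


def ancestry_cv(
    m: DosageMatrix,
    panel: PopulationPanel,
    groups: Sequence[str],
    subset_sizes: Sequence[int] | None = None,
    replicates: int = 100,
    call_threshold: float = 0.9,
    split: float = 0.8,
    seed: int = 0,
    level: str = "group",
    ranked: MarkerSubset | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> pd.DataFrame:
    """Cross-validated ancestry prediction over nested marker subsets.

    Per replicate: a stratified ``split`` (default 80/20) partition of each
    stratum; cluster frequencies come from the training fold over the top-n
    loci; each test individual's q is estimated and the individual is
    called to the argmax stratum only when max q >= ``call_threshold``.
    Accuracy is correct calls over calls made (no-calls excluded from both
    numerator and denominator; ``call_rate`` preserves the information).
    Error is the RMSD between the subset-based q and the q computed with
    the complete locus set (same training fold), averaged over all test
    individuals. Loci are ranked once, on the full data, by F_ST across the
    strata unless a pre-computed ranking is supplied. Per-replicate random
    streams derive deterministically from (seed, replicate index); the
    report is reproducible bit-for-bit given (seed, replicates).

    ``level`` = "population" runs the within-group comparison: strata are
    the populations named in ``groups`` and the supervised model has one
    cluster per population.

    Returns one row per subset size with mean accuracy, error (RMSD),
    call_rate, plus the replicate count and seed.
    """
    if subset_sizes is None:
        subset_sizes = default_subset_sizes()
    sizes = sorted({int(s) for s in subset_sizes}, reverse=True)
    if min(sizes) < 1:
        raise ValueError("subset sizes must be positive")
    strata = panel.strata(level)
    for g in groups:
        if g not in strata:
            raise ValueError(f"stratum {g!r} not in panel at level {level!r}")
    cohort = [s for g in groups for s in strata[g]
              if s in set(m.samples)]
    label_of = {}
    for g in groups:
        for s in strata[g]:
            label_of[s] = g
    if ranked is None:
        stats = pd.DataFrame({
            "locus_id": m.locus_ids,
            "chrom": [l.chrom for l in m.loci],
            "pos": [l.pos for l in m.loci],
        })
        sub = m.subset_samples(cohort)
        theta, defined = weir_cockerham_fst(
            sub, panel.subset(cohort), strata=list(groups), level=level)
        stats["fst"] = theta
        stats["fst_defined"] = defined
        ranked = rank_loci(stats)
    if max(sizes) > len(ranked):
        raise ValueError(f"largest subset {max(sizes)} exceeds "
                         f"{len(ranked)} ranked loci")

    idx_all = {lid: i for i, lid in enumerate(m.locus_ids)}
    top_idx = np.array([idx_all[lid] for lid in ranked.top(max(sizes))])
    acc = {n: [] for n in sizes}
    err = {n: [] for n in sizes}
    call = {n: [] for n in sizes}

    # group-level panel view used for the split regardless of level
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        train, test = _stratified_split(
            _as_group_panel(panel, groups, level), cohort, groups, split, rng)
        train_m = m.subset_samples(train)
        F_full = estimate_ancestral_frequencies(
            train_m, {s: label_of[s] for s in train}, epsilon)
        G_test = m.dosage[m.sample_indices(test)].astype(float)
        Q_full, _, _, _ = estimate_q_batch(G_test, F_full, tol, max_iter)
        true_labels = np.array([label_of[s] for s in test])
        clusters = np.array(F_full.clusters)
        for n in sizes:
            sub_idx = top_idx[:n]
            F_sub = _restrict(sub_idx, train_m, label_of, epsilon)
            Q_sub, _, _, _ = estimate_q_batch(G_test[:, sub_idx], F_sub,
                                              tol, max_iter)
            qmax = Q_sub.max(axis=1)
            called = qmax >= call_threshold
            pred = clusters[Q_sub.argmax(axis=1)]
            n_called = int(called.sum())
            call[n].append(n_called / len(test))
            if n_called:
                acc[n].append(
                    float((pred[called] == true_labels[called]).mean()))
            rmsd = np.sqrt(((Q_sub - Q_full) ** 2).mean(axis=1))
            err[n].append(float(rmsd.mean()))

    rows = []
    for n in sizes:
        rows.append({
            "size": n,
            "accuracy": float(np.mean(acc[n])) if acc[n] else np.nan,
            "error": float(np.mean(err[n])),
            "call_rate": float(np.mean(call[n])),
            "replicates": replicates,
            "seed": seed,
        })
    return pd.DataFrame(rows)


def _as_group_panel(panel: PopulationPanel, groups, level):
    """At population level, re-cast the named populations as their own
    'groups' so stratified splitting works uniformly."""
    if level == "group":
        return panel
    pop_of = {s: p for s, p in panel.population_of.items() if p in groups}
    return PopulationPanel(pop_of, {p: p for p in groups})


def _restrict(sub_idx, train_m, label_of, epsilon):
    """Cluster frequencies over a locus subset, from the same training fold."""
    sub_ids = [train_m.locus_ids[i] for i in sub_idx]
    sub = train_m.subset_loci(sub_ids)
    return estimate_ancestral_frequencies(
        sub, {s: label_of[s] for s in sub.samples}, epsilon)


def admixture_prediction_error(
    m: DosageMatrix,
    panel: PopulationPanel,
    reference_groups: Sequence[str],
    target_population: str,
    subset_sizes: Sequence[int] | None = None,
    ranked: MarkerSubset | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> pd.DataFrame:
    """Admixture-fraction error from reduced marker sets.

    Trains the supervised model on the reference groups' individuals, once
    with the complete locus set and once per top-n F_ST subset, and compares
    the target cohort's ancestry fractions between the two runs: RMSD over
    the reference-group components averaged across target individuals, and
    the Pearson correlation of the pooled component fractions. The whole
    procedure is deterministic (closed-form F, uniform-init EM).
    """
    if subset_sizes is None:
        subset_sizes = default_subset_sizes()
    targets = panel.samples_in_population(target_population)
    targets = [s for s in targets if s in set(m.samples)]
    if not targets:
        raise ValueError(f"target population {target_population!r} empty")
    refs = []
    label_of = {}
    for g in reference_groups:
        for s in panel.samples_in_group(g):
            if s in set(m.samples):
                refs.append(s)
                label_of[s] = g
    ref_m = m.subset_samples(refs)
    if ranked is None:
        theta, defined = weir_cockerham_fst(
            ref_m, panel.subset(refs), strata=list(reference_groups))
        stats = pd.DataFrame({
            "locus_id": m.locus_ids,
            "chrom": [l.chrom for l in m.loci],
            "pos": [l.pos for l in m.loci],
            "fst": theta, "fst_defined": defined,
        })
        ranked = rank_loci(stats)

    idx_all = {lid: i for i, lid in enumerate(m.locus_ids)}
    G_t = m.dosage[m.sample_indices(targets)].astype(float)
    F_full = estimate_ancestral_frequencies(ref_m, label_of, epsilon)
    Q_full, _, _, _ = estimate_q_batch(G_t, F_full, tol, max_iter)

    rows = []
    for n in sorted({int(s) for s in subset_sizes}, reverse=True):
        ids = ranked.top(n)
        sub_idx = np.array([idx_all[lid] for lid in ids])
        F_sub = estimate_ancestral_frequencies(
            ref_m.subset_loci(ids), label_of, epsilon)
        Q_sub, _, _, _ = estimate_q_batch(G_t[:, sub_idx], F_sub,
                                          tol, max_iter)
        rmsd = float(np.sqrt(((Q_sub - Q_full) ** 2).mean(axis=1)).mean())
        flat_full, flat_sub = Q_full.ravel(), Q_sub.ravel()
        if np.std(flat_sub) == 0 or np.std(flat_full) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(flat_full, flat_sub)[0, 1])
        rows.append({"size": n, "rmsd": rmsd, "pearson_r": r,
                     "n_targets": len(targets)})
    return pd.DataFrame(rows)
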