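"""Allele-sharing distances between polyTE genotypes.

The distance between two diploid individuals is the total number of
presence/absence alleles that differ between them across all insertion
sites: the L1 distance on dosage vectors. It is a true metric, and because
the ancestral state of every polyTE locus is known to be absence, a
hypothetical ancestral genome (all dosages zero) can be included as a
pseudo-sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ranksums

from .io_panel import DosageMatrix, PopulationPanel

__all__ = [
    "ANCESTOR_LABEL",
    "DistanceMatrix",
    "allele_sharing_distance",
    "with_ancestor",
    "population_average_distances",
    "within_group_diversity",
    "diversity_distributions",
]

#: Label of the hypothetical ancestral genome (no insertion at any locus).
ANCESTOR_LABEL = "ANCESTOR"


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labelled entities."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        """PHYLIP square distance format (label width 10+)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label.ljust(10) + " "
                         + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy())


def allele_sharing_distance(m: DosageMatrix,
                            normalize: bool = False) -> DistanceMatrix:
    """Pairwise L1 allele-sharing distances between all individuals.

    d(i, j) = sum over loci of |dosage_i - dosage_j| — each differing allele
    counted once. With ``normalize`` the raw count is divided by 2 x n_loci,
    giving a value in [0, 1] comparable across locus subsets.
    """
    if m.n_loci == 0:
        raise ValueError("distance undefined with zero loci")
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = squareform(pdist(m.dosage.astype(float), metric="cityblock"))
    if normalize:
        d = d / (2.0 * m.n_loci)
    return DistanceMatrix(list(m.samples), d)


def with_ancestor(m: DosageMatrix, label: str = ANCESTOR_LABEL) -> DosageMatrix:
    """Append the hypothetical ancestral genome (all-zero dosages).

    Its distance to any individual is simply that individual's total
    insertion load.
    """
    if label in m.samples:
        raise ValueError(f"sample {label!r} already present")
    zeros = np.zeros((1, m.n_loci), dtype=np.int8)
    return DosageMatrix(m.samples + [label], m.loci,
                        np.vstack([m.dosage, zeros]))


def _entity_strata(d: DistanceMatrix, panel: PopulationPanel,
                   level: str) -> dict[str, np.ndarray]:
    """Map each matrix label to a stratum; ANCESTOR forms its own."""
    strata: dict[str, list[int]] = {}
    known = set(panel.samples)
    for i, label in enumerate(d.labels):
        if label in known:
            key = (panel.population_of[label] if level == "population"
                   else panel.group_of(label))
        elif label == ANCESTOR_LABEL:
            key = ANCESTOR_LABEL
        else:
            raise KeyError(f"label {label!r} not in panel")
        strata.setdefault(key, []).append(i)
    return {k: np.array(v, dtype=int) for k, v in strata.items()}


def population_average_distances(
    d: DistanceMatrix,
    panel: PopulationPanel,
    level: str = "population",
) -> DistanceMatrix:
    """Average between-stratum allele-sharing distances.

    Entry (P, Q), P != Q, is the mean of d(i, j) over i in P, j in Q;
    within-stratum pairs never enter the between average, and the diagonal
    is zero as required by the neighbor-joining / MDS input conventions.
    Within-stratum diversity is reported separately by
    :func:`within_group_diversity`.
    """
    strata = _entity_strata(d, panel, level)
    names = list(strata)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = d.values[np.ix_(strata[names[i]], strata[names[j]])]
            out[i, j] = out[j, i] = block.mean()
    return DistanceMatrix(names, out)


def _within_values(d: DistanceMatrix, idx: np.ndarray) -> np.ndarray:
    block = d.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return block[iu]


def within_group_diversity(
    d: DistanceMatrix,
    panel: PopulationPanel,
    level: str = "population",
) -> pd.Series:
    """Mean within-stratum pairwise distance (genetic diversity) per stratum."""
    strata = _entity_strata(d, panel, level)
    out = {}
    for name, idx in strata.items():
        if name == ANCESTOR_LABEL:
            continue
        if len(idx) < 2:
            raise ValueError(f"stratum {name!r} has < 2 members")
        out[name] = float(_within_values(d, idx).mean())
    return pd.Series(out, name="diversity")


def diversity_distributions(
    d: DistanceMatrix,
    panel: PopulationPanel,
    level: str = "group",
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Within-stratum pairwise-distance distributions and their contrasts.

    Returns the multiset of within-stratum pairwise distances per stratum
    and, for every stratum pair, the two-sided Wilcoxon rank-sum p-value
    (normal approximation with continuity correction) comparing the two
    multisets.
    """
    strata = _entity_strata(d, panel, level)
    dists = {}
    for name, idx in strata.items():
        if name == ANCESTOR_LABEL:
            continue
        if len(idx) < 2:
            raise ValueError(f"stratum {name!r} has < 2 members")
        dists[name] = _within_values(d, idx)
    names = list(dists)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = dists[names[i]], dists[names[j]]
            if np.array_equal(np.sort(a), np.sort(b)):
                stat, p = 0.0, 1.0
            else:
                stat, p = ranksums(a, b)
            rows.append({"stratum_a": names[i], "stratum_b": names[j],
                         "statistic": float(stat), "p_value": float(p),
                         "median_a": float(np.median(a)),
                         "median_b": float(np.median(b))})
    return dists, pd.DataFrame(rows)
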