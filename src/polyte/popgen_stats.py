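"""Per-locus population-genetic statistics for polyTE presence/absence data.

Allele frequencies are insertion-allele counts over total allele counts
(TEi / 2n) per stratum (population, continental group, or the full cohort).
Population differentiation per locus is measured two ways: the classical
ancestry-informative-marker statistic delta (absolute allele-frequency
difference; maximum pairwise difference when more than two strata are
compared) and the Weir & Cockerham (1984) F_ST estimator theta-hat computed
from its three variance components with observed heterozygote counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_panel import DosageMatrix, PopulationPanel

__all__ = [
    "allele_frequencies",
    "frequency_matrix",
    "unfolded_sfs",
    "SharingSummary",
    "sharing_summary",
    "delta_stat",
    "weir_cockerham_fst",
    "locus_stats_table",
    "aim_threshold_counts",
]

#: Continental groups treated as non-admixed ancestral poles in three-way
#: comparisons ("Asian" = East Asian).
ANCESTRAL_GROUPS = ("African", "Asian", "European")


def _strata(m: DosageMatrix, panel: PopulationPanel | None,
            level: str) -> dict[str, np.ndarray]:
    if level == "overall":
        return {"ALL": np.arange(m.n_samples)}
    if panel is None:
        raise ValueError(f"level {level!r} requires a panel")
    out = {}
    for name, samples in panel.strata(level).items():
        samples = [s for s in samples if s in set(m.samples)]
        if samples:
            out[name] = m.sample_indices(samples)
    missing = set(m.samples) - set(panel.samples)
    if missing and level != "overall":
        raise ValueError(f"samples absent from panel: {sorted(missing)[:5]}...")
    return out


def allele_frequencies(
    m: DosageMatrix,
    panel: PopulationPanel | None = None,
    level: str = "overall",
) -> pd.DataFrame:
    """Insertion allele frequencies TEi/2n per (locus, stratum).

    Returns a long-format frame with columns ``locus_id``, ``stratum``,
    ``te_count`` (TEi, the number of present insertion alleles),
    ``n_alleles`` (2n) and ``freq``.
    """
    strata = _strata(m, panel, level)
    frames = []
    ids = m.locus_ids
    for name, idx in strata.items():
        if idx.size == 0:
            raise ValueError(f"empty stratum {name!r}")
        te = m.dosage[idx].sum(axis=0, dtype=np.int64)
        n_alleles = 2 * idx.size
        frames.append(pd.DataFrame({
            "locus_id": ids,
            "stratum": name,
            "te_count": te,
            "n_alleles": n_alleles,
            "freq": te / n_alleles,
        }))
    return pd.concat(frames, ignore_index=True)


def frequency_matrix(
    m: DosageMatrix,
    panel: PopulationPanel | None = None,
    level: str = "group",
) -> pd.DataFrame:
    """Wide loci x strata frequency table (rows indexed by locus_id)."""
    long = allele_frequencies(m, panel, level)
    wide = long.pivot(index="locus_id", columns="stratum", values="freq")
    return wide.loc[m.locus_ids]


def unfolded_sfs(freqs: pd.DataFrame, bins) -> pd.DataFrame:
    """Unfolded allele-frequency spectrum: histogram of per-locus frequencies.

    ``freqs`` is the long format from :func:`allele_frequencies`. Bins are
    half-open ``[lo, hi)`` except the final bin, which is closed so that a
    frequency equal to the last edge is counted and the total equals the
    number of loci. Returns a frame with one row per (stratum, bin).
    """
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a sorted 1-D array of >= 2 values")
    rows = []
    for stratum, sub in freqs.groupby("stratum", sort=False):
        counts, _ = np.histogram(sub["freq"].to_numpy(), bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"stratum": stratum, "bin_lo": lo, "bin_hi": hi,
                         "count": int(c)})
    return pd.DataFrame(rows)


@dataclass
class SharingSummary:
    """Counts of loci above a frequency threshold per group, and how they
    are shared or exclusive among groups."""

    threshold: float
    above_threshold: dict[str, int]
    exclusive: dict[str, int]
    #: count per non-empty group combination (frozenset of group names)
    combinations: dict[frozenset, int] = field(default_factory=dict)

    @property
    def total_above(self) -> int:
        return sum(self.combinations.values())


def sharing_summary(freq_matrix: pd.DataFrame,
                    threshold: float = 0.05) -> SharingSummary:
    """Which groups does each locus "count for" (freq strictly > threshold)?

    A locus is exclusive to a group when it exceeds the threshold in exactly
    that group; combination counts cover the power set of groups restricted
    to loci above threshold in at least one group.
    """
    groups = list(freq_matrix.columns)
    above = freq_matrix.to_numpy() > threshold
    above_counts = {g: int(above[:, j].sum()) for j, g in enumerate(groups)}
    combos: dict[frozenset, int] = {}
    exclusive = {g: 0 for g in groups}
    for row in above:
        members = frozenset(g for g, a in zip(groups, row) if a)
        if not members:
            continue
        combos[members] = combos.get(members, 0) + 1
        if len(members) == 1:
            (g,) = members
            exclusive[g] += 1
    return SharingSummary(threshold, above_counts, exclusive, combos)


def delta_stat(freqs) -> float:
    """AIM differentiation statistic delta for one locus.

    For two strata the absolute frequency difference; for three or more the
    maximum pairwise absolute difference, which reduces to the two-stratum
    definition and is invariant under stratum permutation and duplication.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size < 2:
        raise ValueError("delta requires frequencies from >= 2 strata")
    return float(f.max() - f.min())


def weir_cockerham_fst(
    m: DosageMatrix,
    panel: PopulationPanel,
    strata: list[str] | None = None,
    level: str = "group",
    return_components: bool = False,
):
    """Per-locus Weir & Cockerham (1984) theta-hat across strata.

    Uses the three variance components — a (among populations), b (among
    individuals within populations) and c (within individuals) — with
    heterozygosity taken from observed heterozygote counts, not
    Hardy–Weinberg expectations. theta-hat = a / (a + b + c). Negative
    estimates are retained; loci monomorphic across all strata have
    a + b + c = 0 and are returned as NaN with ``defined`` False.

    Returns ``(theta, defined)`` arrays of length n_loci, or with
    ``return_components`` the tuple ``(theta, defined, a, b, c)``.
    """
    if strata is None:
        names = panel.groups if level == "group" else panel.populations
    else:
        names = list(strata)
    groups = panel.strata(level)
    sample_sets = []
    present = set(m.samples)
    for name in names:
        if name not in groups:
            raise ValueError(f"stratum {name!r} not in panel at level {level!r}")
        ss = [s for s in groups[name] if s in present]
        if len(ss) < 2:
            raise ValueError(f"stratum {name!r} has < 2 samples")
        sample_sets.append(ss)
    r = len(sample_sets)
    if r < 2:
        raise ValueError("F_ST requires >= 2 strata")

    L = m.n_loci
    n_i = np.array([len(ss) for ss in sample_sets], dtype=float)  # (r,)
    p_i = np.empty((r, L))
    h_i = np.empty((r, L))
    for k, ss in enumerate(sample_sets):
        d = m.dosage[m.sample_indices(ss)]
        p_i[k] = d.sum(axis=0, dtype=np.int64) / (2 * n_i[k])
        h_i[k] = (d == 1).sum(axis=0) / n_i[k]

    n_sum = n_i.sum()
    n_bar = n_sum / r
    n_c = (n_sum - (n_i**2).sum() / n_sum) / (r - 1)
    w = n_i[:, None] / (r * n_bar)
    p_bar = (w * p_i).sum(axis=0)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_i).sum(axis=0)

    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (
        s2 - (pq - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        pq - (r - 1) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
    )
    c = h_bar / 2.0

    denom = a + b + c
    defined = denom != 0.0
    theta = np.full(L, np.nan)
    np.divide(a, denom, out=theta, where=defined)
    if return_components:
        return theta, defined, a, b, c
    return theta, defined


def locus_stats_table(
    m: DosageMatrix,
    panel: PopulationPanel,
    groups: tuple[str, ...] = ANCESTRAL_GROUPS,
    include_populations: bool = False,
) -> pd.DataFrame:
    """Per-locus summary table: family, per-group frequency, F_ST and delta.

    F_ST and delta are computed across ``groups`` (by default the three-way
    African/Asian/European continental comparison; admixed groups are
    excluded from differentiation statistics). With ``include_populations``
    per-population frequency columns are appended.
    """
    groups = tuple(g for g in groups if g in panel.groups)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups present in the panel")
    gfreq = frequency_matrix(m, panel, level="group")[list(groups)]
    theta, defined = weir_cockerham_fst(m, panel, strata=list(groups))
    fvals = gfreq.to_numpy()
    table = pd.DataFrame({
        "locus_id": m.locus_ids,
        "chrom": [l.chrom for l in m.loci],
        "pos": [l.pos for l in m.loci],
        "family": [l.te_family for l in m.loci],
    })
    for g in groups:
        table[f"freq_{g}"] = gfreq[g].to_numpy()
    table["fst"] = theta
    table["fst_defined"] = defined
    table["delta"] = fvals.max(axis=1) - fvals.min(axis=1)
    if include_populations:
        pfreq = frequency_matrix(m, panel, level="population")
        for p in pfreq.columns:
            table[f"freq_pop_{p}"] = pfreq[p].to_numpy()
    return table


def aim_threshold_counts(table: pd.DataFrame,
                         thresholds=(0.3, 0.4, 0.5)) -> dict[float, int]:
    """Number of loci whose delta strictly exceeds each AIM threshold."""
    delta = table["delta"].to_numpy() if len(table) else np.empty(0)
    return {float(t): int((delta > t).sum()) for t in thresholds}
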