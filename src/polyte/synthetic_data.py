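"""Synthetic polyTE genotype datasets with full ground truth.

The generator emulates the statistical structure of genome-wide polyTE
presence/absence data: a strongly low-frequency-skewed allele spectrum
(most loci below 5 % frequency), a sizeable fraction of loci exclusive to a
single continental group, group diversity differences produced by
Balding–Nichols drift along a serial-founder topology (an out-of-Africa
bottleneck shared by the non-African groups), and admixed cohorts whose
ancestry fractions are Dirichlet draws generating binomial genotypes. Loci
are independent — every downstream statistic here is locus-independent —
and no selection or insertion-site model is attempted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .io_panel import TE_FAMILIES, DosageMatrix, PolyTELocus, PopulationPanel

__all__ = [
    "FrequencyLaw",
    "Bottleneck",
    "GroupConfig",
    "AdmixedCohortConfig",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "simulate",
    "serial_founder_preset",
    "write_vcf",
    "write_panel",
]


@dataclass
class FrequencyLaw:
    """Ancestral insertion-allele frequency distribution.

    A mixture of a Beta concentrated near zero (the rare class) and a
    Uniform component for common loci. The Beta/Uniform mixture weight is
    derived from ``target_rare_fraction`` so that the probability of a drawn
    frequency falling below 0.05 equals the target exactly; the uniform
    component starts at 0.05 so it contributes no rare mass.

    ``min_freq`` truncates the rare Beta from below. It models
    ascertainment: catalogued polyTE loci were discovered segregating in a
    sequenced cohort, so frequencies far below one carrier per cohort are
    never observed.
    """

    beta_a: float = 0.5
    beta_b: float = 50.0
    common_lo: float = 0.05
    common_hi: float = 0.6
    target_rare_fraction: float = 0.935
    min_freq: float = 0.003

    @property
    def rare_weight(self) -> float:
        lo = float(beta_dist.cdf(self.min_freq, self.beta_a, self.beta_b))
        hi = float(beta_dist.cdf(0.05, self.beta_a, self.beta_b))
        c = (hi - lo) / (1.0 - lo)  # P(f < 0.05 | f >= min_freq)
        w = self.target_rare_fraction / c
        if not 0.0 < w <= 1.0:
            raise ValueError("target_rare_fraction unreachable with this Beta")
        return w

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(n) < self.rare_weight
        out = np.empty(n)
        # inverse-CDF sampling of the Beta truncated to [min_freq, 1]
        lo = float(beta_dist.cdf(self.min_freq, self.beta_a, self.beta_b))
        u = rng.random(rare.sum())
        out[rare] = beta_dist.ppf(lo + u * (1.0 - lo),
                                  self.beta_a, self.beta_b)
        out[~rare] = rng.uniform(self.common_lo, self.common_hi, (~rare).sum())
        return out


@dataclass
class Bottleneck:
    """A drift step along the demography.

    ``fst`` is the Balding–Nichols differentiation of the step (variance
    F f(1-f), mean preserved). ``founder_size`` optionally models founder
    loss: an allele at frequency f survives the bottleneck only if present
    among 2 x founder_size sampled founder allele copies, i.e. it is lost
    outright with probability (1-f)^(2*founder_size). Loss is what makes a
    bottlenecked lineage segregate fewer loci — the out-of-Africa pattern —
    and is deliberately not mean-preserving.
    """

    fst: float = 0.0
    founder_size: int | None = None

    def apply(self, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = f
        if self.founder_size is not None:
            lost = rng.random(f.shape) < (1.0 - f) ** (2 * self.founder_size)
            out = np.where(lost, 0.0, out)
        return _balding_nichols(out, self.fst, rng)


@dataclass
class GroupConfig:
    """One continental-like group of populations.

    ``divergence`` is the Balding–Nichols F of the group's drift step from
    its ancestor (the root, or a shared clade such as the out-of-Africa
    lineage); larger F means a stronger bottleneck, hence lower diversity.
    ``drift_scale`` is the additional per-population F within the group and
    ``exclusive_fraction`` the fraction of all loci private to this group.
    A group-level ``founder_size`` adds founder loss at the group's own
    founding (serial-founder chains lose variation at every step).
    """

    name: str
    n_populations: int = 2
    n_individuals_each: int = 50
    divergence: float = 0.05
    drift_scale: float = 0.01
    exclusive_fraction: float = 0.0
    clade: str | None = None
    founder_size: int | None = None


@dataclass
class AdmixedCohortConfig:
    """An admixed population: q ~ Dirichlet(alpha) over source groups."""

    name: str
    n_individuals: int = 30
    alpha: dict[str, float] = field(default_factory=dict)
    group: str = "American"


@dataclass
class SimulationConfig:
    n_loci: int = 2000
    family_mix: dict[str, float] = field(
        default_factory=lambda: {"ALU": 0.79, "L1": 0.16, "SVA": 0.05})
    frequency_law: FrequencyLaw = field(default_factory=FrequencyLaw)
    groups: list[GroupConfig] = field(default_factory=list)
    #: shared drift steps (clade name -> Bottleneck) applied before
    #: group-specific divergence, e.g. an out-of-Africa bottleneck
    clades: dict[str, Bottleneck] = field(default_factory=dict)
    admixed_cohorts: list[AdmixedCohortConfig] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValueError("family_mix proportions must sum to 1")
        if set(self.family_mix) - set(TE_FAMILIES):
            raise ValueError(f"family_mix keys must be within {TE_FAMILIES}")
        excl = sum(g.exclusive_fraction for g in self.groups)
        if excl > 1.0 + 1e-12:
            raise ValueError("exclusive fractions sum to > 1")
        names = {g.name for g in self.groups}
        for g in self.groups:
            if g.n_populations < 1 or g.n_individuals_each < 1:
                raise ValueError("counts must be positive")
            if g.clade is not None and g.clade not in self.clades:
                raise ValueError(f"unknown clade {g.clade!r}")
        for c in self.admixed_cohorts:
            missing = set(c.alpha) - names
            if missing:
                raise ValueError(f"cohort {c.name}: unknown sources {missing}")
            if c.n_individuals < 1 or not c.alpha:
                raise ValueError("cohort needs individuals and alpha weights")


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for downstream tests."""

    ancestral_freq: np.ndarray  # (L,)
    group_freq: pd.DataFrame  # loci x groups
    population_freq: pd.DataFrame  # loci x populations
    exclusive_owner: pd.Series  # locus_id -> group name or ""
    q_true: pd.DataFrame  # admixed individuals x source groups
    seed: int


@dataclass
class SimulationResult:
    matrix: DosageMatrix
    panel: PopulationPanel
    truth: GroundTruth
    config: SimulationConfig


def _balding_nichols(f: np.ndarray, F: float,
                     rng: np.random.Generator) -> np.ndarray:
    """One drift step: f' ~ Beta(f(1-F)/F, (1-f)(1-F)/F); fixed alleles and
    F = 0 pass through unchanged. Preserves the mean frequency."""
    if F <= 0:
        return f.copy()
    out = f.copy()
    seg = (f > 0) & (f < 1)
    c = (1.0 - F) / F
    out[seg] = rng.beta(f[seg] * c, (1.0 - f[seg]) * c)
    return out


def simulate(config: SimulationConfig,
             out_dir: str | Path | None = None) -> SimulationResult:
    """Generate a polyTE dataset with known per-population frequencies.

    Frequencies drift root -> (clade) -> group -> population by
    Balding–Nichols steps; group-exclusive loci are zeroed outside their
    owner group before the group step. Non-admixed genotypes are
    Binomial(2, f_pop,l); admixed individuals draw q ~ Dirichlet(alpha) once
    and genotypes Binomial(2, sum_k q_k f_groupk,l) against group-level
    frequencies. Bit-reproducible for a fixed seed. With ``out_dir`` the
    dataset is also written as VCF + panel TSV + ground-truth TSVs + a JSON
    echo of the configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci

    fam_names = [f for f in TE_FAMILIES if config.family_mix.get(f, 0) > 0]
    probs = np.array([config.family_mix[f] for f in fam_names])
    families = rng.choice(fam_names, size=L, p=probs / probs.sum())
    chroms = np.array([f"{1 + i % 22}" for i in range(L)])
    pos = np.zeros(L, dtype=int)
    for ch in np.unique(chroms):
        k = int((chroms == ch).sum())
        # strictly increasing positions via cumulative gaps
        pos[chroms == ch] = 10_000 + np.cumsum(
            rng.integers(1_000, 100_000, size=k))
    loci = [PolyTELocus(c, int(p), f)
            for c, p, f in zip(chroms, pos, families)]

    f_anc = config.frequency_law.sample(L, rng)

    # group-exclusive loci: drawn without replacement, zeroed elsewhere
    owner = np.full(L, "", dtype=object)
    perm = rng.permutation(L)
    cursor = 0
    for g in config.groups:
        k = int(round(g.exclusive_fraction * L))
        owner[perm[cursor:cursor + k]] = g.name
        cursor += k

    clade_freq = {None: f_anc}
    for clade, step in config.clades.items():
        clade_freq[clade] = step.apply(f_anc, rng)

    group_freq: dict[str, np.ndarray] = {}
    pop_freq: dict[str, np.ndarray] = {}
    pop_group: dict[str, str] = {}
    for g in config.groups:
        base = clade_freq[g.clade].copy()
        base[(owner != "") & (owner != g.name)] = 0.0
        gf = Bottleneck(g.divergence, g.founder_size).apply(base, rng)
        group_freq[g.name] = gf
        for p in range(g.n_populations):
            pname = f"{g.name}{p + 1}"
            pop_freq[pname] = _balding_nichols(gf, g.drift_scale, rng)
            pop_group[pname] = g.name

    samples: list[str] = []
    rows: list[np.ndarray] = []
    population_of: dict[str, str] = {}
    for g in config.groups:
        for p in range(g.n_populations):
            pname = f"{g.name}{p + 1}"
            fpop = pop_freq[pname]
            dos = rng.binomial(2, fpop, size=(g.n_individuals_each, L))
            for i in range(g.n_individuals_each):
                sname = f"{pname}_{i:03d}"
                samples.append(sname)
                population_of[sname] = pname
            rows.append(dos)

    q_rows = {}
    for c in config.admixed_cohorts:
        sources = sorted(c.alpha)
        alpha = np.array([c.alpha[s] for s in sources], dtype=float)
        Fsrc = np.vstack([group_freq[s] for s in sources])
        Q = rng.dirichlet(alpha, size=c.n_individuals)
        P = np.clip(Q @ Fsrc, 0.0, 1.0)
        dos = rng.binomial(2, P)
        for i in range(c.n_individuals):
            sname = f"{c.name}_{i:03d}"
            samples.append(sname)
            population_of[sname] = c.name
            q_rows[sname] = dict(zip(sources, Q[i]))
        pop_group[c.name] = c.group
        rows.append(dos)

    matrix = DosageMatrix(samples, loci,
                          np.vstack(rows).astype(np.int8))
    panel = PopulationPanel(population_of, pop_group)
    ids = matrix.locus_ids
    truth = GroundTruth(
        ancestral_freq=f_anc,
        group_freq=pd.DataFrame(group_freq, index=ids),
        population_freq=pd.DataFrame(pop_freq, index=ids),
        exclusive_owner=pd.Series(owner, index=ids, dtype=str),
        q_true=pd.DataFrame.from_dict(q_rows, orient="index").fillna(0.0),
        seed=config.seed,
    )
    result = SimulationResult(matrix, panel, truth, config)
    if out_dir is not None:
        _write_dataset(result, Path(out_dir))
    return result


_FAMILY_ALT = {"ALU": "ALU", "L1": "LINE1", "SVA": "SVA"}


def write_vcf(m: DosageMatrix, path: str | Path) -> None:
    """Write the dosage matrix as a VCF with MEI-style symbolic ALT records
    (``<INS:ME:ALU>`` etc.), the dialect the reader expects; dosage 1 is
    emitted as the phased heterozygote ``0|1``."""
    gt_codes = np.array(["0|0", "0|1", "1|1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS:ME:ALU,Description="Alu insertion">\n')
        fh.write('##ALT=<ID=INS:ME:LINE1,Description="L1 insertion">\n')
        fh.write('##ALT=<ID=INS:ME:SVA,Description="SVA insertion">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                 'Description="SV type">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for ch in sorted({l.chrom for l in m.loci}, key=str):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.samples) + "\n")
        for j, locus in enumerate(m.loci):
            gts = "\t".join(gt_codes[m.dosage[:, j]])
            fh.write(f"{locus.chrom}\t{locus.pos}\t{locus.te_family}_{j}\tA\t"
                     f"<INS:ME:{_FAMILY_ALT[locus.te_family]}>\t.\tPASS\t"
                     f"SVTYPE=INS\tGT\t{gts}\n")


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for s, p in panel.population_of.items():
            fh.write(f"{s}\t{p}\t{panel.group_of_population[p]}\n")


def _write_dataset(result: SimulationResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_vcf(result.matrix, out_dir / "genotypes.vcf")
    write_panel(result.panel, out_dir / "panel.tsv")
    result.truth.population_freq.to_csv(out_dir / "true_population_freq.tsv",
                                        sep="\t")
    result.truth.group_freq.to_csv(out_dir / "true_group_freq.tsv", sep="\t")
    result.truth.q_true.to_csv(out_dir / "true_q.tsv", sep="\t")
    cfg = asdict(result.config)
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")


def serial_founder_preset(seed: int = 0, n_loci: int = 2000,
                          n_individuals_per_group: int = 100,
                          n_admixed: int = 30) -> SimulationConfig:
    """Serial-founder demography preset.

    An African-like group retains near-ancestral diversity (tiny
    divergence, no founder loss); European- and Asian-like groups share an
    out-of-Africa bottleneck with founder loss (rare alleles are lost
    outright, so the bottlenecked lineages segregate far fewer loci), and
    the Asian-like lineage passes a second founder event and drifts
    furthest. Within-group diversity therefore orders
    African > admixed American > European > Asian. Two admixed American
    cohorts are included: a two-way African/European cohort
    (alpha = (8, 2), mean ancestry 0.8/0.2) and a three-way cohort with
    mostly Asian-like plus European-like ancestry, mirroring the two
    admixture profiles seen in panels from the Americas. African-like
    populations carry the largest within-group drift and the largest share
    of group-private loci.
    """
    per_pop = n_individuals_per_group // 2
    return SimulationConfig(
        n_loci=n_loci,
        clades={"OOA": Bottleneck(0.08, founder_size=8)},
        groups=[
            GroupConfig("African", 2, per_pop, divergence=0.01,
                        drift_scale=0.03, exclusive_fraction=0.15),
            GroupConfig("European", 2, per_pop, divergence=0.05,
                        drift_scale=0.01, exclusive_fraction=0.06,
                        clade="OOA"),
            GroupConfig("Asian", 2, per_pop, divergence=0.12,
                        drift_scale=0.01, exclusive_fraction=0.06,
                        clade="OOA", founder_size=15),
        ],
        admixed_cohorts=[
            AdmixedCohortConfig("AfrEurAdmix", n_admixed,
                                {"African": 8.0, "European": 2.0}),
            AdmixedCohortConfig("LatinoLike", n_admixed,
                                {"African": 1.0, "Asian": 5.0,
                                 "European": 4.0}),
        ],
        seed=seed,
    )
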