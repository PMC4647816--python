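"""Input/output for polyTE genotype data.

A polymorphic transposable element (polyTE) locus is a genomic site at which
some individuals carry a TE insertion (Alu, L1 or SVA) and others do not.
Presence/absence genotypes are encoded as insertion-allele *dosages* in
{0, 1, 2} per diploid individual. This module reads MEI records from VCF into
a dense dosage matrix, reads the sample panel mapping individuals to
populations and continental groups, and (de)serialises per-locus statistics
tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TE_FAMILIES",
    "DEFAULT_GROUP_MAP",
    "PolyTELocus",
    "DosageMatrix",
    "PopulationPanel",
    "read_mei_vcf",
    "read_panel",
    "write_locus_stats",
    "read_locus_stats",
]

#: The three actively retrotransposing human TE families.
TE_FAMILIES = ("ALU", "L1", "SVA")

#: Aliases used by MEI callers / the 1000 Genomes release for the families.
FAMILY_ALIASES: dict[str, str] = {
    "ALU": "ALU",
    "LINE1": "L1",
    "L1": "L1",
    "SVA": "SVA",
}

#: Default 26-population -> 5-continental-group assignment. "Asian" denotes
#: the East Asian populations and "Indian" the South Asian populations; the
#: recently admixed populations of the Americas (including ACB/ASW) form the
#: "American" group.
DEFAULT_GROUP_MAP: dict[str, str] = {
    # African
    "ESN": "African", "GWD": "African", "LWK": "African",
    "MSL": "African", "YRI": "African",
    # Asian (East Asian)
    "CDX": "Asian", "CHB": "Asian", "CHS": "Asian",
    "JPT": "Asian", "KHV": "Asian",
    # European
    "CEU": "European", "FIN": "European", "GBR": "European",
    "IBS": "European", "TSI": "European",
    # Indian (South Asian)
    "BEB": "Indian", "GIH": "Indian", "ITU": "Indian",
    "PJL": "Indian", "STU": "Indian",
    # American (admixed)
    "ACB": "American", "ASW": "American", "CLM": "American",
    "MXL": "American", "PEL": "American", "PUR": "American",
}

_MEI_ALT_RE = re.compile(r"<INS:ME:([A-Za-z0-9_]+)>", re.IGNORECASE)


@dataclass(frozen=True)
class PolyTELocus:
    """One polymorphic TE insertion site.

    Attributes
    ----------
    chrom : str
        Chromosome name, kept verbatim from the source file.
    pos : int
        1-based position (VCF convention).
    te_family : str
        One of ``ALU``, ``L1``, ``SVA``.
    """

    chrom: str
    pos: int
    te_family: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.te_family not in TE_FAMILIES:
            raise ValueError(
                f"te_family must be one of {TE_FAMILIES}, got {self.te_family!r}"
            )

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.te_family}"


class DosageMatrix:
    """Individuals x loci matrix of insertion-allele dosages in {0, 1, 2}.

    The universal substrate for every downstream analysis. Phasing is
    deliberately discarded: all statistics computed from these data are
    phase-free.
    """

    def __init__(self, samples: Sequence[str], loci: Sequence[PolyTELocus],
                 dosage: np.ndarray):
        dosage = np.asarray(dosage)
        if dosage.shape != (len(samples), len(loci)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(samples)} samples x {len(loci)} loci"
            )
        if dosage.size and (dosage.min() < 0 or dosage.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample IDs")
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus IDs")
        self.samples = list(samples)
        self.loci = list(loci)
        self.dosage = dosage.astype(np.int8)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def families(self) -> np.ndarray:
        return np.array([l.te_family for l in self.loci])

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in samples], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def subset_samples(self, samples: Sequence[str]) -> "DosageMatrix":
        idx = self.sample_indices(samples)
        return DosageMatrix(list(samples), self.loci, self.dosage[idx])

    def subset_loci(self, locus_ids: Sequence[str]) -> "DosageMatrix":
        index = {lid: i for i, lid in enumerate(self.locus_ids)}
        try:
            idx = [index[lid] for lid in locus_ids]
        except KeyError as e:
            raise KeyError(f"locus {e.args[0]!r} not in matrix") from None
        return DosageMatrix(self.samples, [self.loci[i] for i in idx],
                            self.dosage[:, idx])

    def subset_family(self, family: str) -> "DosageMatrix":
        """Mask the matrix to a single TE family (ALU, L1 or SVA)."""
        if family not in TE_FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        keep = [l.locus_id for l in self.loci if l.te_family == family]
        return self.subset_loci(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosageMatrix):
            return NotImplemented
        return (self.samples == other.samples and self.loci == other.loci
                and np.array_equal(self.dosage, other.dosage))

    def __repr__(self) -> str:
        return f"DosageMatrix({self.n_samples} samples x {self.n_loci} loci)"


@dataclass
class PopulationPanel:
    """Sample -> population -> continental group assignment.

    Continental groups partition the samples; every sample belongs to exactly
    one population and every population to exactly one group.
    """

    population_of: dict[str, str]
    group_of_population: dict[str, str]
    _group_of_sample: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        missing = sorted({p for p in self.population_of.values()
                          if p not in self.group_of_population})
        if missing:
            raise ValueError(
                f"populations without a continental-group assignment: {missing}"
            )
        self._group_of_sample = {
            s: self.group_of_population[p] for s, p in self.population_of.items()
        }

    @property
    def samples(self) -> list[str]:
        return list(self.population_of)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_of.values():
            seen.setdefault(p)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(self.group_of_population[p])
        return list(seen)

    def group_of(self, sample: str) -> str:
        return self._group_of_sample[sample]

    def samples_in_population(self, population: str) -> list[str]:
        return [s for s, p in self.population_of.items() if p == population]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in self._group_of_sample.items() if g == group]

    def population_counts(self) -> pd.Series:
        return pd.Series(self.population_of, name="population").value_counts()

    def strata(self, level: str) -> dict[str, list[str]]:
        """Samples per stratum at ``level`` in {'population', 'group'}."""
        if level == "population":
            return {p: self.samples_in_population(p) for p in self.populations}
        if level == "group":
            return {g: self.samples_in_group(g) for g in self.groups}
        raise ValueError(f"unknown level {level!r}")

    def subset(self, samples: Sequence[str]) -> "PopulationPanel":
        pop = {s: self.population_of[s] for s in samples}
        return PopulationPanel(pop, dict(self.group_of_population))


def _family_from_alt(alt: str) -> str | None:
    m = _MEI_ALT_RE.search(alt)
    if m is None:
        return None
    return FAMILY_ALIASES.get(m.group(1).upper())


def read_mei_vcf(
    vcf_path: str | Path,
    family_filter: Iterable[str] | None = None,
    *,
    missing_policy: str = "error",
    alt_pattern: re.Pattern | None = None,
) -> DosageMatrix:
    """Read mobile-element-insertion records from a VCF into a DosageMatrix.

    The insertion allele is any ALT allele; dosage is the per-genotype count
    of ALT alleles, so multi-allelic MEI records collapse to presence/absence
    of the insertion. Records whose ALT symbolic allele does not match an
    MEI family pattern (``<INS:ME:FAMILY>`` by default) are skipped, as are
    MEI families outside ``family_filter``.

    Parameters
    ----------
    vcf_path : path
        Plain or bgzipped VCF 4.x with GT fields for every sample.
    family_filter : iterable of str, optional
        Subset of {"ALU", "L1", "SVA"} to retain (default: all three).
    missing_policy : {"error", "absent"}
        Missing genotypes either raise (the default; the source release is
        fully genotyped) or are treated as dosage 0, the ancestral absence
        state of every polyTE locus.
    alt_pattern : compiled regex, optional
        Override the ALT-allele pattern whose first group captures the
        family name; MEI dialects differ between callers.
    """
    from cyvcf2 import VCF

    if missing_policy not in ("error", "absent"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    families = set(TE_FAMILIES if family_filter is None else family_filter)
    unknown = families - set(TE_FAMILIES)
    if unknown:
        raise ValueError(f"unknown TE families in filter: {sorted(unknown)}")
    pattern = alt_pattern or _MEI_ALT_RE

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    loci: list[PolyTELocus] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        family = None
        for alt in variant.ALT:
            m = pattern.search(alt)
            if m is not None:
                family = FAMILY_ALIASES.get(m.group(1).upper())
                break
        if family is None or family not in families:
            continue
        # genotype array: columns [allele_0, allele_1, ..., phased]
        gts = variant.genotype.array()
        alleles = gts[:, :-1]
        miss = alleles < 0
        if miss.any():
            if missing_policy == "error":
                raise ValueError(
                    f"missing genotype at {variant.CHROM}:{variant.POS} "
                    f"(sample index {int(np.where(miss.any(axis=1))[0][0])})"
                )
            alleles = np.where(miss, 0, alleles)
        rows.append((alleles > 0).sum(axis=1).astype(np.int8))
        loci.append(PolyTELocus(variant.CHROM, variant.POS, family))
    vcf.close()

    dosage = (np.vstack(rows).T if rows
              else np.empty((len(samples), 0), dtype=np.int8))
    return DosageMatrix(samples, loci, dosage)


def read_panel(
    panel_path: str | Path,
    group_map: Mapping[str, str] | None = None,
) -> PopulationPanel:
    """Read a sample panel TSV (columns: sample, pop[, super_pop, ...]).

    Every population must appear in ``group_map`` (default: the packaged
    26-population -> 5-continental-group assignment); an unmapped population
    is a hard error listing the offenders.
    """
    if group_map is None:
        group_map = DEFAULT_GROUP_MAP
    df = pd.read_csv(panel_path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample" not in df.columns or "pop" not in df.columns:
        raise ValueError("panel must have 'sample' and 'pop' columns")
    unmapped = sorted(set(df["pop"]) - set(group_map))
    if unmapped:
        raise ValueError(f"populations not in group map: {unmapped}")
    population_of = dict(zip(df["sample"], df["pop"]))
    if len(population_of) != len(df):
        raise ValueError("duplicate sample IDs in panel")
    used = {p: g for p, g in group_map.items()}
    return PopulationPanel(population_of, used)


def write_locus_stats(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-locus statistics table as TSV with 6-decimal floats.

    The table is the genome-wide resource analogue: one row per locus with
    family, per-stratum allele frequencies, F_ST and delta. Round-trips
    losslessly at 6 decimal digits through :func:`read_locus_stats`.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_locus_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
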