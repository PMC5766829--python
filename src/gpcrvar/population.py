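"""Per-individual and cohort-level variation metrics from genotype matrices.

Works on 0/1/2 genotype matrices (copies of the alternate allele per
individual and variant site): per-individual burden counts, the four
affected-individual criteria used for drug scoring, the fraction of a
receptor's known functional sites that are polymorphic, and the de novo
missense rate from trio counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .numbering import GenericPosition, SegmentMap
from .sites import FunctionalSiteAnnotation
from .variants import MissenseVariant

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "TrioSummary",
    "CRITERIA",
    "per_individual_counts",
    "fraction_affected",
    "fraction_sites_polymorphic",
    "de_novo_rate",
]

#: the four affected-individual criteria, from most to least conservative:
#: (i) homozygous at a known functional site, (ii) any allele at a known site,
#: (iii) homozygous at a known-or-putative site, (iv) any allele at a
#: known-or-putative site.
CRITERIA = (
    "hom_known",
    "any_known",
    "hom_known_or_putative",
    "any_known_or_putative",
)

_CRITERION_ALIASES = {1: CRITERIA[0], 2: CRITERIA[1], 3: CRITERIA[2], 4: CRITERIA[3]}


def _canonical_criterion(criterion: int | str) -> str:
    if isinstance(criterion, int):
        if criterion not in _CRITERION_ALIASES:
            raise ValueError(f"criterion must be 1..4, got {criterion}")
        return _CRITERION_ALIASES[criterion]
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    return criterion


@dataclass
class GenotypeMatrix:
    """Individuals x variant sites with 0/1/2 alternate-allele counts.

    ``site_receptors`` links every site id to its receptor.  Missing calls in
    the source data are treated as reference; the loader logs how many.
    """

    individuals: list[str]
    sites: list[str]
    calls: np.ndarray
    site_receptors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        bad = set(np.unique(self.calls)) - {0, 1, 2}
        if bad:
            raise ValueError(f"genotype calls must be 0/1/2; found {sorted(bad)}")
        for s in self.sites:
            if self.site_receptors and s not in self.site_receptors:
                raise ValueError(f"site {s!r} has no receptor mapping")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def site_index(self, sites: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sites)}
        try:
            return np.array([lookup[s] for s in sites], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown site id {exc.args[0]!r}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.individuals, columns=self.sites)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "individual"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, site_receptors: Mapping[str, str] | None = None
    ) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        n_missing = int(df.isna().sum().sum())
        if n_missing:
            logger.info("treating %d missing genotype calls as reference", n_missing)
            df = df.fillna(0)
        return cls(
            individuals=[str(i) for i in df.index],
            sites=[str(c) for c in df.columns],
            calls=df.to_numpy(dtype=np.int8),
            site_receptors=dict(site_receptors or {}),
        )

    @classmethod
    def read_vcf(
        cls, path: str | Path, site_receptors: Mapping[str, str] | None = None
    ) -> "GenotypeMatrix":
        """Genotypes from the VCF GT field; site ids from the ID column."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        sites, columns = [], []
        n_missing = 0
        for rec in vcf:
            sites.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
            gts = np.asarray(rec.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            col = np.where(gts == 3, 2, np.where(gts == 1, 1, 0))
            n_missing += int((gts == 2).sum())
            columns.append(col)
        if n_missing:
            logger.info("treating %d missing genotype calls as reference", n_missing)
        calls = (
            np.column_stack(columns)
            if columns
            else np.zeros((len(individuals), 0), dtype=np.int8)
        )
        return cls(
            individuals=individuals,
            sites=sites,
            calls=calls,
            site_receptors=dict(site_receptors or {}),
        )


@dataclass(frozen=True)
class TrioSummary:
    """Counts from father-mother-offspring trios used for the de novo rate."""

    n_trios: int
    n_offspring_with_denovo_mv_in_target: int
    n_denovo_mvs: int = 0
    n_affected_targets: int = 0

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")
        if self.n_offspring_with_denovo_mv_in_target > self.n_trios:
            raise ValueError("affected offspring cannot exceed number of trios")


def per_individual_counts(
    genotypes: GenotypeMatrix,
    clinical_sites: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-individual burden: carried variant sites, distinct receptors, and
    carried sites with known clinical drug-response associations.

    A site is carried with genotype >= 1.  Returns a DataFrame indexed by
    individual with columns ``n_mv``, ``n_receptors``, ``n_clinical``.
    """
    if not genotypes.site_receptors:
        raise ValueError("genotype matrix lacks site-to-receptor mapping")
    carried = genotypes.calls >= 1
    n_mv = carried.sum(axis=1)

    receptors = sorted({genotypes.site_receptors[s] for s in genotypes.sites})
    rec_idx = {r: i for i, r in enumerate(receptors)}
    rec_of_site = np.array(
        [rec_idx[genotypes.site_receptors[s]] for s in genotypes.sites], dtype=int
    )
    per_rec = np.zeros((genotypes.n_individuals, len(receptors)), dtype=bool)
    for j in range(len(genotypes.sites)):
        per_rec[:, rec_of_site[j]] |= carried[:, j]
    n_receptors = per_rec.sum(axis=1)

    clinical = set(clinical_sites or ())
    clin_mask = np.array([s in clinical for s in genotypes.sites], dtype=bool)
    n_clinical = carried[:, clin_mask].sum(axis=1) if clin_mask.any() else np.zeros(
        genotypes.n_individuals, dtype=int
    )
    return pd.DataFrame(
        {"n_mv": n_mv, "n_receptors": n_receptors, "n_clinical": n_clinical},
        index=pd.Index(genotypes.individuals, name="individual"),
    )


def fraction_affected(
    genotypes: GenotypeMatrix,
    site_flags: Mapping[str, tuple[bool, bool]],
    targets: Iterable[str],
    criterion: int | str,
) -> float:
    """Fraction of the cohort with a qualifying genotype in the target receptors.

    ``site_flags`` maps site id → (known_functional, putative_functional).
    Homozygous criteria require genotype 2 at a single qualifying site; the
    any-allele criteria require genotype >= 1.  An individual qualifies with
    at least one qualifying site in at least one target receptor.
    """
    crit = _canonical_criterion(criterion)
    if genotypes.n_individuals == 0:
        raise ValueError("empty cohort")
    target_set = set(targets)
    include_putative = crit.endswith("or_putative")
    min_copies = 2 if crit.startswith("hom") else 1

    qualifying = []
    for j, s in enumerate(genotypes.sites):
        if genotypes.site_receptors.get(s) not in target_set:
            continue
        known, putative = site_flags.get(s, (False, False))
        if known or (include_putative and putative):
            qualifying.append(j)
    if not qualifying:
        return 0.0
    sub = genotypes.calls[:, qualifying]
    affected = (sub >= min_copies).any(axis=1)
    return float(affected.mean())


def fraction_sites_polymorphic(
    variants: Iterable[MissenseVariant],
    known_sites: Iterable[FunctionalSiteAnnotation | GenericPosition | int],
    segment_map: SegmentMap,
) -> float:
    """Share of a receptor's known functional sites carrying >= 1 missense variant.

    Known sites may be given as annotations, generic positions or residue
    indices; variants match generic sites through the segment map.  A
    receptor with zero known sites returns 0 with a log flag.
    """
    generic_keys: set[tuple[str, int]] = set()
    residue_keys: set[int] = set()
    for site in known_sites:
        if isinstance(site, FunctionalSiteAnnotation):
            if site.generic_position is not None:
                generic_keys.add((site.generic_position.segment_label, site.generic_position.index))
            if site.residue_index is not None:
                residue_keys.add(site.residue_index)
        elif isinstance(site, GenericPosition):
            generic_keys.add((site.segment_label, site.index))
        else:
            residue_keys.add(int(site))
    n_known = len(generic_keys) + len(residue_keys)
    if n_known == 0:
        logger.warning("%s has no known functional sites", segment_map.receptor)
        return 0.0

    hit_generic: set[tuple[str, int]] = set()
    hit_residue: set[int] = set()
    for v in variants:
        if v.residue_index in residue_keys:
            hit_residue.add(v.residue_index)
        gp = segment_map.generic_of(v.residue_index)
        if gp is not None and (gp.segment_label, gp.index) in generic_keys:
            hit_generic.add((gp.segment_label, gp.index))
    return (len(hit_generic) + len(hit_residue)) / n_known


def de_novo_rate(trios: TrioSummary) -> tuple[float, str]:
    """De novo missense rate per newborn and its "1 in ~N" presentation.

    N = trios / affected offspring, rounded to one significant figure for
    display.  With zero affected offspring the rate is 0 and N is reported
    as not observed.
    """
    if trios.n_offspring_with_denovo_mv_in_target == 0:
        return 0.0, "not observed"
    rate = trios.n_offspring_with_denovo_mv_in_target / trios.n_trios
    n = trios.n_trios / trios.n_offspring_with_denovo_mv_in_target
    exponent = math.floor(math.log10(n))
    rounded = round(n / 10**exponent) * 10**exponent
    rounded = int(rounded) if rounded >= 1 else rounded
    return rate, f"1 in ~{rounded}"
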