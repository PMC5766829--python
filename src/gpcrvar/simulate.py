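"""Synthetic receptor panels, cohorts, drug maps and prescription ledgers.

Every pipeline stage is testable without external downloads: the generator
emits receptor segment maps with generic numbering, planted functional-site
annotations, missense-variant tables with a rare-dominated allele-frequency
spectrum, Hardy-Weinberg genotype matrices, drug-target maps, and monthly
prescription ledgers with known annual totals.  All ground truth (planted
site sets, enrichment factor, annual costs) is returned alongside the data
so recovery can be asserted.

The defaults emulate the study conditions of the exome-scale GPCR analyses
this package supports: a cohort of 2,504 genotyped individuals, allele
counts on a 60,706-exome scale (AN = 121,412), a variant density of about a
third of residues, and roughly two thirds of variants scored damaging by
SIFT/PolyPhen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .drugs import (
    DrugTargetEntry,
    DrugTargetMap,
    PrescriptionRecord,
    write_drug_target_tsv,
    write_prescriptions_csv,
)
from .numbering import GenericPosition, SegmentMap, write_segment_maps
from .population import GenotypeMatrix
from .sites import FunctionalSiteAnnotation, write_annotations_tsv
from .variants import STANDARD_AA, MissenseVariant, write_missense_tsv

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_receptor_panel",
    "simulate_variants",
    "simulate_genotypes",
    "simulate_drugs_and_prescriptions",
    "simulate_study",
    "write_fixture_dir",
]

_AA = sorted(STANDARD_AA)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_receptors: int = 30
    length_range: tuple[int, int] = (320, 480)
    class_mix: tuple[tuple[str, float], ...] = (
        ("A", 0.85), ("B", 0.05), ("C", 0.05), ("F", 0.05),
    )
    n_individuals: int = 2504
    allele_number: int = 121_412  # 2 x 60,706 exomes
    #: probability mass of singleton variants (AC = 1)
    singleton_mass: float = 0.60
    #: probability mass of common variants (MAF >= 1e-3)
    common_mass: float = 0.028
    #: Zipf exponent of the rare non-singleton allele-count tail
    tail_exponent: float = 2.0
    #: fraction of receptor positions planted as known functional sites
    functional_site_fraction: float = 0.15
    #: relative rate of variants inside functional sites vs outside
    enrichment_rho: float = 1.0
    #: distinct variant positions per residue of receptor length
    mv_site_density: float = 0.25
    #: fraction of variants drawn with damaging SIFT/PolyPhen scores
    damaging_fraction: float = 0.67
    n_drugs: int = 40
    max_targets_per_drug: int = 3
    #: lognormal scale of one drug's monthly prescription cost, GBP
    monthly_cost_scale: float = 1.0e6
    year_window: tuple[int, int] = (2013, 2016)
    include_partial_boundary_years: bool = True

    def __post_init__(self) -> None:
        if self.enrichment_rho <= 0:
            raise ValueError("enrichment_rho must be positive")
        for name in ("singleton_mass", "common_mass", "functional_site_fraction",
                     "mv_site_density", "damaging_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.singleton_mass + self.common_mass > 1.0:
            raise ValueError("singleton_mass + common_mass exceed 1")
        if self.n_receptors < 0:
            raise ValueError("n_receptors must be >= 0")


@dataclass
class SyntheticStudy:
    """A complete synthetic study plus its ground truth."""

    config: SimulationConfig
    receptors: pd.DataFrame
    segment_maps: dict[str, SegmentMap]
    annotations: list[FunctionalSiteAnnotation]
    functional_truth: dict[str, set[int]]  # receptor -> planted site residue indices
    variants: list[MissenseVariant]
    genotypes: GenotypeMatrix
    sample_variants: list[MissenseVariant]  # AC/AN recomputed from the cohort
    target_map: DrugTargetMap
    prescriptions: list[PrescriptionRecord]
    annual_cost_truth: dict[tuple[str, int], float]


def _build_segment_map(receptor: str, rclass: str, rng: np.random.Generator) -> SegmentMap:
    """One receptor: termini, 7 TMs with x-scheme numbers centered on x50,
    loops (ICL2 carries 34x5x generic numbers), helix 8."""
    tm_len = 25  # generic indices x38..x62, anchor x50 mid-helix
    pieces: list[tuple[str, int]] = [
        ("N-term", int(rng.integers(20, 41))),
        ("TM1", tm_len), ("ICL1", int(rng.integers(5, 9))),
        ("TM2", tm_len), ("ECL1", int(rng.integers(4, 7))),
        ("TM3", tm_len), ("ICL2", int(rng.integers(8, 13))),
        ("TM4", tm_len), ("ECL2", int(rng.integers(12, 21))),
        ("TM5", tm_len), ("ICL3", int(rng.integers(15, 31))),
        ("TM6", tm_len), ("ECL3", int(rng.integers(4, 9))),
        ("TM7", tm_len), ("H8", 10),
        ("C-term", int(rng.integers(30, 61))),
    ]
    ranges: dict[str, tuple[int, int]] = {}
    pos = 0
    for seg, n in pieces:
        ranges[seg] = (pos + 1, pos + n)
        pos += n
    length = pos
    generic: dict[int, GenericPosition] = {}
    for tm in range(1, 8):
        start, _end = ranges[f"TM{tm}"]
        for k in range(tm_len):
            generic[start + k] = GenericPosition(
                str(tm), 38 + k, receptor_class=rclass
            )
    # four mid-ICL2 residues carry inter-helix 34x50..34x53 numbers
    icl2_start, icl2_end = ranges["ICL2"]
    mid = (icl2_start + icl2_end) // 2 - 1
    for k in range(4):
        generic[mid + k] = GenericPosition("34", 50 + k, receptor_class=rclass)
    h8_start, _ = ranges["H8"]
    for k in range(10):
        generic[h8_start + k] = GenericPosition("8", 47 + k, receptor_class=rclass)
    seq = "".join(rng.choice(_AA, size=length))
    return SegmentMap(
        receptor=receptor,
        length=length,
        ranges=ranges,
        generic_positions=generic,
        sequence=seq,
        receptor_class=rclass,
    )


def simulate_receptor_panel(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, SegmentMap], list[FunctionalSiteAnnotation], dict[str, set[int]]]:
    """Receptor table, segment maps, and a planted functional-site annotation.

    Exactly ``round(functional_site_fraction * length)`` positions per
    receptor are planted as known functional sites; sites with a generic
    number become pocket/interface annotations, the rest PTM annotations.
    """
    rng = np.random.default_rng(config.seed)
    classes, weights = zip(*config.class_mix) if config.n_receptors else ((), ())
    maps: dict[str, SegmentMap] = {}
    annotations: list[FunctionalSiteAnnotation] = []
    truth: dict[str, set[int]] = {}
    rows = []
    for i in range(config.n_receptors):
        receptor = f"R{i + 1:03d}"
        rclass = str(rng.choice(classes, p=np.array(weights) / sum(weights)))
        sm = _build_segment_map(receptor, rclass, rng)
        maps[receptor] = sm
        n_sites = round(config.functional_site_fraction * sm.length)
        planted = rng.choice(sm.length, size=n_sites, replace=False) + 1
        truth[receptor] = set(int(p) for p in planted)
        structural_cats = ("ligand_binding", "g_protein_interface", "arrestin_interface")
        for p in sorted(truth[receptor]):
            gp = sm.generic_of(p)
            if gp is not None:
                annotations.append(
                    FunctionalSiteAnnotation(
                        receptor=receptor,
                        category=str(rng.choice(structural_cats)),
                        generic_position=gp,
                        provenance="direct_structure",
                    )
                )
            else:
                annotations.append(
                    FunctionalSiteAnnotation(
                        receptor=receptor,
                        category="ptm",
                        residue_index=p,
                        provenance="experimental_ptm",
                    )
                )
        rows.append(
            {"receptor": receptor, "receptor_class": rclass, "length": sm.length,
             "n_functional_sites": n_sites}
        )
    receptors = pd.DataFrame(
        rows, columns=["receptor", "receptor_class", "length", "n_functional_sites"]
    )
    return receptors, maps, annotations, truth


def _draw_allele_count(config: SimulationConfig, rng: np.random.Generator) -> int:
    an = config.allele_number
    u = rng.random()
    if u < config.singleton_mass:
        return 1
    if u < config.singleton_mass + config.common_mass:
        maf = rng.uniform(1e-3, 0.3)
        return max(int(round(maf * an)), int(np.ceil(1e-3 * an)))
    ac = int(rng.zipf(config.tail_exponent))
    return max(1, min(ac, int(1e-3 * an) - 1, an // 2))


def simulate_variants(
    segment_maps: Mapping[str, SegmentMap],
    functional_truth: Mapping[str, set[int]],
    config: SimulationConfig,
) -> list[MissenseVariant]:
    """Missense variants with positions enriched ``rho``-fold in planted sites.

    Per receptor, ``round(mv_site_density * length)`` distinct positions are
    drawn with relative weight rho inside the planted functional sites and 1
    outside.  Allele counts follow the singleton/common/power-law spectrum;
    homozygote counts follow Hardy-Weinberg; SIFT/PolyPhen scores are drawn
    so a ``damaging_fraction`` of variants satisfies the putative rule.
    """
    rng = np.random.default_rng(config.seed + 1)
    out: list[MissenseVariant] = []
    for receptor in sorted(segment_maps):
        sm = segment_maps[receptor]
        sites = functional_truth.get(receptor, set())
        weights = np.ones(sm.length)
        if sites:
            weights[[p - 1 for p in sites]] = config.enrichment_rho
        weights /= weights.sum()
        n_sites = round(config.mv_site_density * sm.length)
        positions = rng.choice(sm.length, size=n_sites, replace=False, p=weights) + 1
        seq = sm.sequence or "A" * sm.length
        for p in sorted(int(x) for x in positions):
            wt = seq[p - 1]
            mut = str(rng.choice([a for a in _AA if a != wt]))
            ac = _draw_allele_count(config, rng)
            freq = ac / config.allele_number
            hom = int(min(rng.binomial(config.allele_number // 2, freq * freq), ac // 2))
            if rng.random() < config.damaging_fraction:
                if rng.random() < 0.5:
                    sift, polyphen = float(rng.uniform(0, 0.05)), float(rng.uniform(0, 0.1))
                else:
                    sift, polyphen = float(rng.uniform(0.06, 1)), float(rng.uniform(0.11, 1))
            else:
                sift, polyphen = float(rng.uniform(0.06, 1)), float(rng.uniform(0, 0.1))
            out.append(
                MissenseVariant(
                    receptor=receptor,
                    residue_index=p,
                    wt_aa=wt,
                    mut_aa=mut,
                    allele_count=ac,
                    allele_number=config.allele_number,
                    hom_count=hom,
                    sift=sift,
                    polyphen=polyphen,
                )
            )
    return out


def simulate_genotypes(
    variants: list[MissenseVariant],
    n_individuals: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[MissenseVariant]]:
    """Hardy-Weinberg genotypes at each variant's allele frequency.

    Genotypes are i.i.d. Binomial(2, p) per individual (2 w.p. p^2, 1 w.p.
    2p(1-p), 0 otherwise).  The realized sample allele counts are written
    back into a second variant list so downstream frequency-based metrics
    stay consistent with the matrix.
    """
    rng = np.random.default_rng(seed)
    freqs = np.array([v.allele_count / v.allele_number for v in variants])
    calls = rng.binomial(2, freqs, size=(n_individuals, len(variants))).astype(np.int8)
    site_ids = [v.site_id for v in variants]
    gm = GenotypeMatrix(
        individuals=[f"I{i + 1:05d}" for i in range(n_individuals)],
        sites=site_ids,
        calls=calls,
        site_receptors={v.site_id: v.receptor for v in variants},
    )
    sample_an = 2 * n_individuals
    sample_variants = []
    for j, v in enumerate(variants):
        ac = int(calls[:, j].sum())
        hom = int((calls[:, j] == 2).sum())
        sample_variants.append(
            MissenseVariant(
                receptor=v.receptor,
                residue_index=v.residue_index,
                wt_aa=v.wt_aa,
                mut_aa=v.mut_aa,
                allele_count=ac,
                allele_number=sample_an,
                hom_count=hom,
                sift=v.sift,
                polyphen=v.polyphen,
                rsid=v.rsid,
            )
            if ac > 0
            else v
        )
    return gm, sample_variants


def simulate_drugs_and_prescriptions(
    receptors: list[str],
    config: SimulationConfig,
) -> tuple[DrugTargetMap, list[PrescriptionRecord], dict[tuple[str, int], float]]:
    """Drug-target map with 1..k targets per drug and a monthly cost ledger.

    Monthly costs are lognormal around ``monthly_cost_scale``; the returned
    truth dict holds each drug's exact annual total within the year window.
    Partial boundary-year months (when enabled) fall outside the window and
    must be excluded by the cost averaging.
    """
    if not receptors:
        raise ValueError("need at least one receptor to assign drug targets")
    rng = np.random.default_rng(config.seed + 2)
    entries: list[DrugTargetEntry] = []
    for i in range(config.n_drugs):
        drug = f"drug{i + 1:03d}"
        k = int(rng.integers(1, config.max_targets_per_drug + 1))
        targets = rng.choice(receptors, size=min(k, len(receptors)), replace=False)
        for j, t in enumerate(targets):
            entries.append(
                DrugTargetEntry(
                    drug=drug,
                    target=str(t),
                    role="primary" if j == 0 else "secondary",
                    status="approved",
                )
            )
    target_map = DrugTargetMap(entries)

    lo, hi = config.year_window
    ledger: list[PrescriptionRecord] = []
    truth: dict[tuple[str, int], float] = {}
    for drug in target_map.drugs:
        scale = config.monthly_cost_scale * float(rng.lognormal(0.0, 1.0))
        for year in range(lo, hi + 1):
            total = 0.0
            for month in range(1, 13):
                cost = round(float(rng.lognormal(np.log(scale), 0.3)), 2)
                items = int(max(1, rng.poisson(cost / 25.0)))
                ledger.append(PrescriptionRecord(drug, year, month, items, cost))
                total += cost
            truth[(drug, year)] = round(total, 2)
        if config.include_partial_boundary_years:
            for year, months in ((lo - 1, (10, 11, 12)), (hi + 1, (1, 2, 3))):
                for month in months:
                    cost = round(float(rng.lognormal(np.log(scale), 0.3)), 2)
                    ledger.append(
                        PrescriptionRecord(drug, year, month, int(max(1, cost / 25)), cost)
                    )
    return target_map, ledger, truth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run all four generators under one seed and bundle data plus truth."""
    receptors, maps, annotations, truth = simulate_receptor_panel(config)
    variants = simulate_variants(maps, truth, config)
    genotypes, sample_variants = simulate_genotypes(
        variants, config.n_individuals, seed=config.seed + 3
    )
    if config.n_receptors:
        target_map, ledger, cost_truth = simulate_drugs_and_prescriptions(
            list(receptors["receptor"]), config
        )
    else:
        target_map, ledger, cost_truth = DrugTargetMap([]), [], {}
    return SyntheticStudy(
        config=config,
        receptors=receptors,
        segment_maps=maps,
        annotations=annotations,
        functional_truth=truth,
        variants=variants,
        genotypes=genotypes,
        sample_variants=sample_variants,
        target_map=target_map,
        prescriptions=ledger,
        annual_cost_truth=cost_truth,
    )


def write_fixture_dir(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory in the dialects the readers ingest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "receptors": out / "receptors.tsv",
        "segments": out / "segment_maps.tsv",
        "annotations": out / "functional_sites.tsv",
        "variants": out / "missense_variants.tsv",
        "genotypes": out / "genotypes.tsv",
        "drug_targets": out / "drug_targets.tsv",
        "prescriptions": out / "prescriptions.csv",
    }
    study.receptors.to_csv(paths["receptors"], sep="\t", index=False)
    write_segment_maps(study.segment_maps, paths["segments"])
    write_annotations_tsv(study.annotations, paths["annotations"])
    write_missense_tsv(study.variants, paths["variants"])
    study.genotypes.write_tsv(paths["genotypes"])
    if study.target_map.entries:
        write_drug_target_tsv(study.target_map, paths["drug_targets"])
        write_prescriptions_csv(study.prescriptions, paths["prescriptions"])
    return paths
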