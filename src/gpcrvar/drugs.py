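"""Drug-level variability scores, in vitro mutant matching, and cost burden.

A drug's exposure to target variability is summarized two ways: the
polymorphic-site score S_polymorphic (sum over its targets of the fraction
of known functional sites carrying a missense variant) and the affected-
individual score S_affected (fraction of the cohort with a qualifying
functional-site variant in any of the drug's targets).  Multiplying a drug's
average yearly prescription cost by its affected fraction gives the
prescription-cost burden estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .population import GenotypeMatrix, fraction_affected

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTargetMap",
    "PrescriptionRecord",
    "InVitroMutant",
    "score_polymorphic",
    "score_affected",
    "rank_drugs_by_polymorphic_score",
    "average_annual_cost",
    "economic_burden",
    "match_in_vitro_mutants",
    "read_drug_target_tsv",
    "read_prescriptions_csv",
    "DEFAULT_YEAR_WINDOW",
]

DEFAULT_YEAR_WINDOW = (2013, 2016)  # inclusive; boundary years have partial data


@dataclass(frozen=True)
class DrugTargetEntry:
    drug: str
    target: str
    role: str = "primary"  # primary | secondary
    status: str = "approved"  # approved | trial | discontinued

    def __post_init__(self) -> None:
        if self.role not in ("primary", "secondary"):
            raise ValueError(f"unknown target role {self.role!r}")
        if self.status not in ("approved", "trial", "discontinued"):
            raise ValueError(f"unknown status {self.status!r}")


class DrugTargetMap:
    """Drug → target-receptor links with role and approval status."""

    def __init__(self, entries: Iterable[DrugTargetEntry]):
        self.entries = list(entries)
        self._by_drug: dict[str, list[DrugTargetEntry]] = {}
        for e in self.entries:
            self._by_drug.setdefault(e.drug, []).append(e)
        for drug, es in self._by_drug.items():
            if not es:
                raise ValueError(f"drug {drug!r} has no targets")

    @property
    def drugs(self) -> list[str]:
        return sorted(self._by_drug)

    def targets_of(
        self,
        drug: str,
        primary_only: bool = False,
        include_non_approved: bool = False,
    ) -> list[str]:
        """Targets entering the drug's scores: approved-status links by
        default, optionally restricted to primary targets."""
        if drug not in self._by_drug:
            raise KeyError(f"drug {drug!r} not in target map")
        out = []
        for e in self._by_drug[drug]:
            if not include_non_approved and e.status != "approved":
                continue
            if primary_only and e.role != "primary":
                continue
            out.append(e.target)
        return sorted(set(out))


@dataclass(frozen=True)
class PrescriptionRecord:
    """One month of a drug's prescription ledger: items and actual cost (GBP)."""

    drug: str
    year: int
    month: int
    items: int
    actual_cost: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")
        if self.items < 0 or self.actual_cost < 0:
            raise ValueError("items and cost must be non-negative")


@dataclass(frozen=True)
class InVitroMutant:
    """An engineered receptor mutant with a measured ligand fold change."""

    receptor: str
    residue_index: int
    wt_aa: str
    mut_aa: str
    ligand: str
    fold_change: float  # signed; negative = loss, positive = gain
    species: str = "human"
    human_identical_at_position: bool = True

    def __post_init__(self) -> None:
        if self.fold_change == 0:
            raise ValueError("fold change cannot be 0")


def score_polymorphic(
    drug: str,
    target_map: DrugTargetMap,
    polymorphic_fractions: Mapping[str, float],
    primary_only: bool = False,
) -> float:
    """S_polymorphic: sum over the drug's targets of the fraction of known
    functional sites that are polymorphic.  Targets without a computed
    fraction contribute 0 with a warning."""
    total = 0.0
    for target in target_map.targets_of(drug, primary_only=primary_only):
        if target not in polymorphic_fractions:
            logger.warning("no polymorphic fraction for target %s of %s", target, drug)
            continue
        total += polymorphic_fractions[target]
    return total


def rank_drugs_by_polymorphic_score(
    target_map: DrugTargetMap,
    polymorphic_fractions: Mapping[str, float],
    primary_only: bool = False,
) -> pd.DataFrame:
    """All drugs ranked by S_polymorphic, ties broken by drug name."""
    rows = [
        {
            "drug": d,
            "s_polymorphic": score_polymorphic(
                d, target_map, polymorphic_fractions, primary_only
            ),
            "n_targets": len(target_map.targets_of(d, primary_only=primary_only)),
        }
        for d in target_map.drugs
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["s_polymorphic", "drug"], ascending=[False, True])
        .reset_index(drop=True)
    )


def score_affected(
    drug: str,
    target_map: DrugTargetMap,
    genotypes: GenotypeMatrix,
    site_flags: Mapping[str, tuple[bool, bool]],
    criterion: int | str,
    primary_only: bool = False,
) -> float:
    """S_affected: fraction of individuals with a qualifying functional-site
    variant in any of the drug's targets (union over targets)."""
    targets = target_map.targets_of(drug, primary_only=primary_only)
    return fraction_affected(genotypes, site_flags, targets, criterion)


def average_annual_cost(
    prescriptions: Iterable[PrescriptionRecord],
    drug: str | None = None,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> float:
    """Average yearly prescription cost over the year window (GBP/year).

    Costs are summed per calendar year inside the inclusive window and
    averaged over the window years with data; boundary years with partial
    ledgers stay outside the window and are ignored.
    """
    lo, hi = year_window
    per_year: dict[int, float] = {}
    for rec in prescriptions:
        if drug is not None and rec.drug != drug:
            continue
        if lo <= rec.year <= hi:
            per_year[rec.year] = per_year.get(rec.year, 0.0) + rec.actual_cost
    if not per_year:
        raise ValueError(
            f"no prescription data for {drug!r} within {lo}-{hi}"
        )
    return sum(per_year.values()) / len(per_year)


def economic_burden(
    annual_cost: float,
    affected_fraction: float,
) -> float:
    """Burden estimate: average yearly cost x fraction of affected individuals."""
    if annual_cost < 0:
        raise ValueError("annual cost must be non-negative")
    if not 0.0 <= affected_fraction <= 1.0:
        raise ValueError("affected fraction must lie in [0, 1]")
    return annual_cost * affected_fraction


def burden_table(
    target_map: DrugTargetMap,
    prescriptions: Sequence[PrescriptionRecord],
    genotypes: GenotypeMatrix,
    site_flags: Mapping[str, tuple[bool, bool]],
    criteria: Sequence[int | str] = (1, 2, 3, 4),
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> pd.DataFrame:
    """Per-drug burden under each affected-individual criterion.

    Drugs prescribed but absent from the target map are reported unscored
    (NaN scores) rather than dropped.
    """
    ledger_drugs = sorted({p.drug for p in prescriptions})
    rows = []
    for drug in ledger_drugs:
        row: dict[str, object] = {"drug": drug}
        try:
            row["annual_cost"] = average_annual_cost(prescriptions, drug, year_window)
        except ValueError:
            row["annual_cost"] = float("nan")
        in_map = drug in target_map.drugs
        row["in_target_map"] = in_map
        for crit in criteria:
            label = crit if isinstance(crit, str) else f"criterion_{crit}"
            if in_map and row["annual_cost"] == row["annual_cost"]:
                frac = score_affected(drug, target_map, genotypes, site_flags, crit)
                row[f"affected_{label}"] = frac
                row[f"burden_{label}"] = economic_burden(float(row["annual_cost"]), frac)
            else:
                row[f"affected_{label}"] = float("nan")
                row[f"burden_{label}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def match_in_vitro_mutants(
    variants: Iterable,
    mutant_db: Iterable[InVitroMutant],
    fold_cutoff: float = 5.0,
) -> pd.DataFrame:
    """Match natural variants to engineered in vitro mutants.

    A match requires identical receptor, position, wild-type and mutant
    amino acid; ortholog records are admitted only when the human residue at
    the shared generic position is identical.  Per matched variant the
    maximum absolute fold change over ligands/records is reported and
    flagged when it reaches ``fold_cutoff``.
    """
    db: dict[tuple[str, int, str, str], list[InVitroMutant]] = {}
    for m in mutant_db:
        if m.species != "human" and not m.human_identical_at_position:
            continue
        db.setdefault((m.receptor, m.residue_index, m.wt_aa, m.mut_aa), []).append(m)

    rows = []
    for v in variants:
        key = (v.receptor, v.residue_index, v.wt_aa, v.mut_aa)
        records = db.get(key)
        if not records:
            continue
        max_abs = max(abs(m.fold_change) for m in records)
        rows.append(
            {
                "receptor": v.receptor,
                "residue_index": v.residue_index,
                "wt_aa": v.wt_aa,
                "mut_aa": v.mut_aa,
                "n_records": len(records),
                "max_abs_fold_change": max_abs,
                "above_cutoff": max_abs >= fold_cutoff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "receptor", "residue_index", "wt_aa", "mut_aa",
            "n_records", "max_abs_fold_change", "above_cutoff",
        ],
    )


# ---------------------------------------------------------------------------
# I/O


def read_drug_target_tsv(path: str | Path) -> DrugTargetMap:
    """Drug-target map TSV: drug, target, role, status (reference id optional)."""
    df = pd.read_csv(path, sep="\t")
    entries = [
        DrugTargetEntry(
            drug=str(r.drug),
            target=str(r.target),
            role=str(getattr(r, "role", "primary")),
            status=str(getattr(r, "status", "approved")),
        )
        for r in df.itertuples(index=False)
    ]
    return DrugTargetMap(entries)


def write_drug_target_tsv(target_map: DrugTargetMap, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"drug": e.drug, "target": e.target, "role": e.role, "status": e.status}
            for e in target_map.entries
        ]
    ).sort_values(["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_prescriptions_csv(path: str | Path) -> list[PrescriptionRecord]:
    """Prescription ledger CSV: drug, month (YYYY-MM), items, actual_cost."""
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples(index=False):
        year_s, month_s = str(r.month).split("-")
        out.append(
            PrescriptionRecord(
                drug=str(r.drug),
                year=int(year_s),
                month=int(month_s),
                items=int(r.items),
                actual_cost=float(r.actual_cost),
            )
        )
    return out


def write_prescriptions_csv(
    records: Iterable[PrescriptionRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "drug": r.drug,
                "month": f"{r.year:04d}-{r.month:02d}",
                "items": r.items,
                "actual_cost": r.actual_cost,
            }
            for r in records
        ]
    ).sort_values(["drug", "month"]).to_csv(path, index=False)
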