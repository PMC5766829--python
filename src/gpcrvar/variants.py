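"""Variant data model and per-receptor variation summary metrics.

Covers the three variant classes aggregated from exome-scale cohorts:
missense variants (MVs) with allele counts and SIFT/PolyPhen impact scores,
protein-truncating loss-of-function (LoF) variants, and gene-level copy
number variation (CNV), plus the per-receptor landscape summary (densities,
rare/common splits, minimum LoF carriers, per-category z-scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MissenseVariant",
    "LoFVariant",
    "CNVRecord",
    "AA_PROPERTY_CLASSES",
    "minor_allele_frequency",
    "classify_rarity",
    "classify_property_change",
    "missense_density",
    "lof_min_carriers",
    "category_zscores",
    "build_receptor_landscape",
    "read_missense_tsv",
    "write_missense_tsv",
    "read_missense_vcf",
    "read_lof_tsv",
    "read_cnv_tsv",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

LOF_CLASSES = ("stop_gained", "frameshift", "essential_splice")

#: amino-acid property classes; an amino acid may belong to several
AA_PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ACFILMVWY"),
    "aromatic": frozenset("FHWY"),
    "polar_uncharged": frozenset("STNQ"),
    "helix_breaker": frozenset("PG"),
    "negative": frozenset("DE"),
    "positive": frozenset("HKR"),
}


@dataclass(frozen=True)
class MissenseVariant:
    """One amino-acid substitution with cohort allele counts and impact scores."""

    receptor: str
    residue_index: int
    wt_aa: str
    mut_aa: str
    allele_count: int
    allele_number: int
    hom_count: int = 0
    sift: float | None = None
    polyphen: float | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.wt_aa == self.mut_aa:
            raise ValueError("wt and mutant amino acids must differ")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in STANDARD_AA:
                raise ValueError(f"non-standard amino acid {aa!r}")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("require 0 <= AC <= AN")
        if self.allele_number <= 0:
            raise ValueError("AN must be positive")
        if 2 * self.hom_count > self.allele_count:
            raise ValueError("2*hom_count cannot exceed AC")
        for name, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} score {score} outside [0, 1]")

    @property
    def maf(self) -> float:
        return minor_allele_frequency(self.allele_count, self.allele_number)

    @property
    def site_id(self) -> str:
        return f"{self.receptor}:{self.wt_aa}{self.residue_index}{self.mut_aa}"


@dataclass(frozen=True)
class LoFVariant:
    """A protein-truncating variant (stop gain, frameshift or essential splice)."""

    receptor: str
    residue_index: int
    lof_class: str
    allele_count: int
    hom_count: int = 0

    def __post_init__(self) -> None:
        if self.lof_class not in LOF_CLASSES:
            raise ValueError(
                f"lof_class must be one of {LOF_CLASSES}, got {self.lof_class!r}"
            )
        if self.allele_count < 0 or self.hom_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class CNVRecord:
    """Gene-level copy-number summary: numbers of deletions and duplications."""

    receptor: str
    n_deletions: int
    n_duplications: int

    def __post_init__(self) -> None:
        if self.n_deletions < 0 or self.n_duplications < 0:
            raise ValueError("CNV counts must be non-negative")


def minor_allele_frequency(ac: int, an: int) -> float:
    """MAF: frequency of the less frequent allele, ``min(ac, an-ac)/an``."""
    if an <= 0:
        raise ValueError("allele number must be positive to define a frequency")
    if not 0 <= ac <= an:
        raise ValueError("require 0 <= ac <= an")
    return min(ac, an - ac) / an


def classify_rarity(maf: float, threshold: float = 1e-3) -> str:
    """Split variants at the MAF threshold: ``rare`` below, ``common`` at/above."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    return "rare" if maf < threshold else "common"


def classify_property_change(wt_aa: str, mut_aa: str, strict: bool = False) -> str:
    """Classify a substitution as ``similar`` or ``changed`` in physicochemistry.

    By default a substitution is ``similar`` when the two residues share at
    least one property class (amino acids can belong to several classes, e.g.
    F is hydrophobic and aromatic).  With ``strict=True`` the full class-
    membership sets must be equal.
    """
    for aa in (wt_aa, mut_aa):
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard amino acid {aa!r}")
    wt_classes = {name for name, members in AA_PROPERTY_CLASSES.items() if wt_aa in members}
    mut_classes = {name for name, members in AA_PROPERTY_CLASSES.items() if mut_aa in members}
    same = wt_classes == mut_classes if strict else bool(wt_classes & mut_classes)
    return "similar" if same else "changed"


def missense_density(n_mv: int, length: int) -> float:
    """Number of missense variants normalized by receptor sequence length."""
    if length <= 0:
        raise ValueError("receptor length must be positive")
    return n_mv / length


def lof_min_carriers(lofs: Sequence[LoFVariant]) -> int:
    """Minimum number of individuals carrying a LoF allele in the receptor.

    Without genotypes, the position with the highest LoF allele count gives a
    lower bound: its allele count minus its homozygote count (each homozygote
    contributed two alleles but is one carrier; the remainder are
    heterozygous carriers).  Empty input → 0.
    """
    if not lofs:
        return 0
    top = max(lofs, key=lambda v: v.allele_count)
    return top.allele_count - top.hom_count


def category_zscores(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standardize one per-receptor metric across the panel: z = (x - mean)/sd.

    Uses the sample standard deviation (ddof=1).  A degenerate category
    (sd = 0) maps every receptor to z = 0 with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scores need at least 2 receptors")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate category (sd = 0); z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


_ZSCORE_CATEGORIES = (
    "n_mv",
    "mv_density",
    "n_lof_positions",
    "lof_min_carrier_fraction",
    "n_deletions",
    "n_duplications",
)


def build_receptor_landscape(
    missense: Iterable[MissenseVariant],
    lofs: Iterable[LoFVariant],
    cnvs: Iterable[CNVRecord],
    receptor_lengths: Mapping[str, int],
    cohort_size: int,
    maf_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Per-receptor variation landscape over a receptor panel.

    One row per receptor in ``receptor_lengths``: MV counts and density, the
    rare/common split at ``maf_threshold``, distinct LoF positions and the
    minimum-carrier bound (count and fraction of ``cohort_size``), CNV
    deletion/duplication counts, and a z-score per category standardized
    across the panel.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    mv_by_rec: dict[str, list[MissenseVariant]] = {r: [] for r in receptor_lengths}
    for mv in missense:
        if mv.receptor not in mv_by_rec:
            raise ValueError(f"variant for unknown receptor {mv.receptor!r}")
        if mv.residue_index > receptor_lengths[mv.receptor]:
            raise ValueError(
                f"{mv.site_id}: residue beyond receptor length "
                f"{receptor_lengths[mv.receptor]}"
            )
        mv_by_rec[mv.receptor].append(mv)
    lof_by_rec: dict[str, list[LoFVariant]] = {r: [] for r in receptor_lengths}
    for lv in lofs:
        lof_by_rec.setdefault(lv.receptor, []).append(lv)
    cnv_by_rec = {c.receptor: c for c in cnvs}

    rows = []
    for receptor, length in receptor_lengths.items():
        mvs = mv_by_rec[receptor]
        rarity = [classify_rarity(mv.maf, maf_threshold) for mv in mvs]
        rec_lofs = lof_by_rec.get(receptor, [])
        min_carriers = lof_min_carriers(rec_lofs)
        cnv = cnv_by_rec.get(receptor)
        rows.append(
            {
                "receptor": receptor,
                "length": length,
                "n_mv": len(mvs),
                "mv_density": missense_density(len(mvs), length),
                "n_rare": sum(r == "rare" for r in rarity),
                "n_common": sum(r == "common" for r in rarity),
                "n_lof_positions": len({v.residue_index for v in rec_lofs}),
                "lof_min_carriers": min_carriers,
                "lof_min_carrier_fraction": min_carriers / cohort_size,
                "n_deletions": cnv.n_deletions if cnv else 0,
                "n_duplications": cnv.n_duplications if cnv else 0,
            }
        )
    df = pd.DataFrame(rows).sort_values("receptor").reset_index(drop=True)
    if len(df) >= 2:
        for cat in _ZSCORE_CATEGORIES:
            df[f"z_{cat}"] = category_zscores(df[cat].to_numpy())
    return df


# ---------------------------------------------------------------------------
# I/O

_MV_COLUMNS = [
    "receptor", "residue_index", "wt_aa", "mut_aa",
    "allele_count", "allele_number", "hom_count", "sift", "polyphen", "rsid",
]


def read_missense_tsv(path: str | Path) -> list[MissenseVariant]:
    """Read a missense-variant summary table (TSV, columns as written)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_MV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"missense table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            MissenseVariant(
                receptor=str(d["receptor"]),
                residue_index=int(d["residue_index"]),
                wt_aa=str(d["wt_aa"]),
                mut_aa=str(d["mut_aa"]),
                allele_count=int(d["allele_count"]),
                allele_number=int(d["allele_number"]),
                hom_count=int(d.get("hom_count", 0) or 0),
                sift=None if pd.isna(d.get("sift")) else float(d["sift"]),
                polyphen=None if pd.isna(d.get("polyphen")) else float(d["polyphen"]),
                rsid=None if pd.isna(d.get("rsid")) else str(d["rsid"]),
            )
        )
    return out


def write_missense_tsv(variants: Iterable[MissenseVariant], path: str | Path) -> None:
    rows = [
        {
            "receptor": v.receptor,
            "residue_index": v.residue_index,
            "wt_aa": v.wt_aa,
            "mut_aa": v.mut_aa,
            "allele_count": v.allele_count,
            "allele_number": v.allele_number,
            "hom_count": v.hom_count,
            "sift": v.sift,
            "polyphen": v.polyphen,
            "rsid": v.rsid,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=_MV_COLUMNS)
    df.sort_values(["receptor", "residue_index", "mut_aa"]).to_csv(
        path, sep="\t", index=False
    )


def read_missense_vcf(
    path: str | Path,
    receptor_key: str = "GENE",
    position_key: str = "AAPOS",
    wt_key: str = "AAREF",
    mut_key: str = "AAALT",
    ac_key: str = "AC",
    an_key: str = "AN",
    hom_key: str = "Hom",
    sift_key: str = "SIFT",
    polyphen_key: str = "PolyPhen",
) -> list[MissenseVariant]:
    """Read missense summary records from a VCF whose INFO carries the
    per-variant annotations (key names configurable)."""
    from cyvcf2 import VCF

    def _scalar(value):
        if isinstance(value, tuple):
            value = value[0]
        return value

    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        if receptor_key not in info or position_key not in info:
            continue
        sift = _scalar(info.get(sift_key))
        polyphen = _scalar(info.get(polyphen_key))
        out.append(
            MissenseVariant(
                receptor=str(_scalar(info[receptor_key])),
                residue_index=int(_scalar(info[position_key])),
                wt_aa=str(_scalar(info[wt_key])),
                mut_aa=str(_scalar(info[mut_key])),
                allele_count=int(_scalar(info[ac_key])),
                allele_number=int(_scalar(info[an_key])),
                hom_count=int(_scalar(info.get(hom_key, 0)) or 0),
                sift=None if sift is None else float(sift),
                polyphen=None if polyphen is None else float(polyphen),
                rsid=rec.ID,
            )
        )
    return out


def read_lof_tsv(path: str | Path) -> list[LoFVariant]:
    df = pd.read_csv(path, sep="\t")
    return [
        LoFVariant(
            receptor=str(r.receptor),
            residue_index=int(r.residue_index),
            lof_class=str(r.lof_class),
            allele_count=int(r.allele_count),
            hom_count=int(getattr(r, "hom_count", 0) or 0),
        )
        for r in df.itertuples(index=False)
    ]


def read_cnv_tsv(path: str | Path) -> list[CNVRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CNVRecord(str(r.receptor), int(r.n_deletions), int(r.n_duplications))
        for r in df.itertuples(index=False)
    ]
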