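"""Functional-site annotation of GPCRs and variant-to-site classification.

Known functional sites comprise five categories: ligand-binding pocket
residues (atoms within a distance cutoff of a co-crystallized ligand, or
inherited from a crystallized family member), G-protein and arrestin
effector interfaces (unions of per-structure contact sets, expressed as
generic positions), the class A activation micro-switches, the class A
allosteric sodium pocket, and experimentally validated post-translational
modification (PTM) sites.  Putative functional sites are variant positions
flagged damaging by SIFT or PolyPhen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .numbering import (
    ClassOffsetTable,
    DEFAULT_OFFSETS,
    GenericPosition,
    GenericPositionError,
    SegmentMap,
    parse_generic_position,
    translate_class_position,
)
from .variants import MissenseVariant

logger = logging.getLogger(__name__)

__all__ = [
    "ContactRecord",
    "FunctionalSiteAnnotation",
    "PTMRecord",
    "SITE_CATEGORIES",
    "DEFAULT_CONTACT_CUTOFF",
    "contacts_from_structure",
    "read_contacts_tsv",
    "extract_ligand_binding_sites",
    "inherit_family_sites",
    "build_effector_interface",
    "builtin_class_a_registries",
    "MICROSWITCH_POSITIONS",
    "SODIUM_POCKET_POSITIONS",
    "validate_ptm_sites",
    "is_putative_functional",
    "annotate_variant_sites",
    "read_annotations_tsv",
    "write_annotations_tsv",
]

SITE_CATEGORIES = (
    "ligand_binding",
    "g_protein_interface",
    "arrestin_interface",
    "microswitch",
    "sodium_pocket",
    "ptm",
)

PROVENANCES = ("direct_structure", "family_inherited", "registry", "experimental_ptm")

#: annotation pipeline contact cutoff in Angstrom (5.0 is a display-only override)
DEFAULT_CONTACT_CUTOFF = 4.5

# class A reference structures whose contact unions define the effector interfaces
G_PROTEIN_STRUCTURES_A = ("3SN6", "5G53", "3DQB", "3PQR", "4A4M")
ARRESTIN_STRUCTURES_A = ("4ZWJ", "4PXF", "5DGY")
G_PROTEIN_STRUCTURES_B = ("5UZ7", "5VAI")


@dataclass(frozen=True)
class ContactRecord:
    """Minimum inter-atomic distance between one receptor residue and a partner."""

    structure: str
    receptor: str
    residue_index: int
    partner: str  # ligand | g_protein | arrestin
    min_distance: float
    generic_position: GenericPosition | None = None

    def __post_init__(self) -> None:
        if self.min_distance <= 0:
            raise ValueError("distance must be positive")
        if self.partner not in ("ligand", "g_protein", "arrestin"):
            raise ValueError(f"unknown partner {self.partner!r}")


@dataclass(frozen=True)
class FunctionalSiteAnnotation:
    """(receptor, position, category, provenance).

    ``position`` is a generic position for pocket/interface/switch sites and
    a 1-based residue index for PTM sites (which mostly lie in the termini,
    outside the generically numbered region).
    """

    receptor: str
    category: str
    generic_position: GenericPosition | None = None
    residue_index: int | None = None
    provenance: str = "registry"

    def __post_init__(self) -> None:
        if self.category not in SITE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.generic_position is None and self.residue_index is None:
            raise ValueError("annotation needs a generic position or residue index")


@dataclass(frozen=True)
class PTMRecord:
    """One experimentally reported post-translational modification site."""

    receptor: str
    residue_index: int
    amino_acid: str
    ptm_type: str


def _key(pos: GenericPosition) -> tuple[str, int]:
    return (pos.segment_label, pos.index)


# ---------------------------------------------------------------------------
# contact extraction


def contacts_from_structure(
    path: str | Path,
    receptor: str,
    receptor_chain: str,
    partner: str = "ligand",
    partner_chain: str | None = None,
    partner_resnames: Sequence[str] | None = None,
    structure_id: str | None = None,
) -> list[ContactRecord]:
    """Compute per-residue minimum distances to a partner entity from PDB/mmCIF.

    The partner entity is selected either as a named chain (effector
    complexes) or as hetero residues by name (co-crystallized ligands); with
    neither given, all non-water hetero atoms in the receptor chain's model
    count as ligand.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chain = model.find_chain(receptor_chain)
    if chain is None:
        raise ValueError(f"chain {receptor_chain!r} not found in {path}")

    partner_atoms: list[np.ndarray] = []
    for ch in model:
        for res in ch:
            is_water = res.name in ("HOH", "WAT")
            if is_water:
                continue
            if partner_chain is not None:
                selected = ch.name == partner_chain
            elif partner_resnames is not None:
                selected = res.name in partner_resnames
            else:
                selected = ch.name == receptor_chain and res.het_flag == "H"
            if selected:
                partner_atoms.extend(np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res)
    if not partner_atoms:
        logger.warning("no %s entity found in %s; no contacts", partner, path)
        return []
    pxyz = np.vstack(partner_atoms)

    out: list[ContactRecord] = []
    sid = structure_id or Path(path).stem
    for res in chain:
        if res.het_flag == "H" and (partner_resnames is None or res.name in (partner_resnames or ())):
            continue
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
        if coords.size == 0:
            continue
        d = np.sqrt(((coords[:, None, :] - pxyz[None, :, :]) ** 2).sum(-1)).min()
        out.append(
            ContactRecord(
                structure=sid,
                receptor=receptor,
                residue_index=res.seqid.num,
                partner=partner,
                min_distance=float(d),
            )
        )
    return out


def read_contacts_tsv(path: str | Path, receptor: str | None = None) -> list[ContactRecord]:
    """Read precomputed contacts: structure, receptor, residue_index, partner,
    min_distance (TSV)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ContactRecord(
            structure=str(r.structure),
            receptor=str(getattr(r, "receptor", receptor)),
            residue_index=int(r.residue_index),
            partner=str(r.partner),
            min_distance=float(r.min_distance),
        )
        for r in df.itertuples(index=False)
    ]


def extract_ligand_binding_sites(
    contacts: Iterable[ContactRecord],
    segment_map: SegmentMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> set[GenericPosition]:
    """Generic-numbered residues with any atom within ``cutoff`` of the ligand.

    Residues lacking a generic position are excluded (loop pocket residues
    are not transferable between receptors); curated loop exceptions such as
    the ECL2 positions at the top of the 7TM cavity carry inter-helix generic
    numbers (34x..) in their segment maps and enter through the same path.
    """
    sites: set[GenericPosition] = set()
    seen_ligand = False
    for c in contacts:
        if c.partner != "ligand":
            continue
        seen_ligand = True
        if c.min_distance > cutoff:
            continue
        gp = segment_map.generic_of(c.residue_index)
        if gp is not None:
            sites.add(gp)
    if not seen_ligand:
        logger.warning("no ligand contacts for %s", segment_map.receptor)
    return sites


def inherit_family_sites(
    donor_sites: Iterable[GenericPosition],
    member_map: SegmentMap,
    donor_map: SegmentMap | None = None,
    donor_is_ortholog: bool = False,
    human_sequence: str | None = None,
) -> set[GenericPosition]:
    """Transfer a crystallized family member's site set to an uncrystallized member.

    A donor generic position transfers iff the member possesses that generic
    position.  For a non-human (ortholog) donor structure, a position
    transfers only when the human residue at the aligned generic position is
    identical in amino acid to the donor residue.
    """
    member_keys = member_map.generic_position_set
    out: set[GenericPosition] = set()
    for pos in donor_sites:
        if _key(pos) not in member_keys:
            continue
        if donor_is_ortholog:
            if donor_map is None or human_sequence is None:
                raise ValueError(
                    "ortholog inheritance needs the donor map and human sequence"
                )
            donor_idx = donor_map.residue_of(pos)
            if donor_idx is None or donor_map.sequence is None:
                continue
            donor_aa = donor_map.sequence[donor_idx - 1]
            human_idx = member_map.residue_of(pos)
            if human_idx is None:
                continue
            human_aa = human_sequence[human_idx - 1]
            if donor_aa != human_aa:
                continue
        out.add(
            GenericPosition(
                pos.segment_label, pos.index,
                receptor_class=member_map.receptor_class,
            )
        )
    return out


def build_effector_interface(
    contact_sets: Mapping[str, set[GenericPosition]],
    receptor_class: str,
    partner: str = "g_protein",
    class_a_sets: Mapping[str, set[GenericPosition]] | None = None,
    class_b_sets: Mapping[str, set[GenericPosition]] | None = None,
    offsets: ClassOffsetTable = DEFAULT_OFFSETS,
) -> set[GenericPosition]:
    """Effector (G protein / arrestin) interface as a union of per-structure
    contact sets.

    Classes A and B take the union over their own reference complexes.  For
    classes C and F no effector complex exists; the union of the class A and
    class B interface sets is translated into the target class through the
    per-TM offset table, dropping positions whose segment is untranslatable
    or which fall out of range.
    """
    if receptor_class in ("A", "B"):
        out: set[GenericPosition] = set()
        for sites in contact_sets.values():
            out |= sites
        return out
    if receptor_class in ("C", "F"):
        pooled: set[GenericPosition] = set()
        for sets in (class_a_sets or contact_sets, class_b_sets or {}):
            for sites in sets.values():
                pooled |= sites
        translated: set[GenericPosition] = set()
        for pos in pooled:
            try:
                translated.add(translate_class_position(pos, receptor_class, offsets))
            except GenericPositionError:
                logger.warning(
                    "dropping %s (%s): not translatable to class %s",
                    pos.render(), partner, receptor_class,
                )
        return translated
    raise ValueError(f"unknown receptor class {receptor_class!r}")


# ---------------------------------------------------------------------------
# curated class A registries

_MICROSWITCH_TEXT = (
    "3x49", "7x43", "3x50", "5x47", "5x58", "6x30", "6x34", "6x48",
    "6x50", "7x49", "7x50", "7x53", "3x40", "5x50", "6x44", "3x46", "6x37",
)

_SODIUM_POCKET_TEXT = (
    "1x50", "1x53", "2x46", "2x47", "2x49", "2x50", "3x39", "3x43",
    "6x44", "6x48", "7x45", "7x46", "7x49", "7x50", "7x53",
)

MICROSWITCH_POSITIONS = frozenset(
    parse_generic_position(t, "A") for t in _MICROSWITCH_TEXT
)
SODIUM_POCKET_POSITIONS = frozenset(
    parse_generic_position(t, "A") for t in _SODIUM_POCKET_TEXT
)


def builtin_class_a_registries(
    receptor_class: str = "A",
) -> tuple[frozenset[GenericPosition], frozenset[GenericPosition]]:
    """(micro-switch set, sodium-pocket set); class A only, empty otherwise."""
    if receptor_class != "A":
        return frozenset(), frozenset()
    return MICROSWITCH_POSITIONS, SODIUM_POCKET_POSITIONS


# ---------------------------------------------------------------------------
# PTM cross-validation and the SIFT/PolyPhen rule


def validate_ptm_sites(
    records: Iterable[PTMRecord],
    sequences: Mapping[str, str],
) -> list[PTMRecord]:
    """Keep PTM records whose stated amino acid matches the receptor sequence.

    Mismatches and records for unknown receptors are dropped with a log line;
    duplicate reports of one site collapse to a single record.
    """
    kept: dict[tuple[str, int], PTMRecord] = {}
    for rec in records:
        seq = sequences.get(rec.receptor)
        if seq is None:
            logger.warning("PTM record for unknown receptor %s dropped", rec.receptor)
            continue
        if not 1 <= rec.residue_index <= len(seq):
            logger.warning("PTM %s:%d outside sequence; dropped", rec.receptor, rec.residue_index)
            continue
        if seq[rec.residue_index - 1] != rec.amino_acid:
            logger.warning(
                "PTM %s:%d says %s, sequence has %s; dropped",
                rec.receptor, rec.residue_index, rec.amino_acid,
                seq[rec.residue_index - 1],
            )
            continue
        kept.setdefault((rec.receptor, rec.residue_index), rec)
    return list(kept.values())


def is_putative_functional(
    sift: float | None,
    polyphen: float | None,
    sift_max: float = 0.05,
    polyphen_min: float = 0.1,
) -> bool:
    """SIFT/PolyPhen rule for putative functional impact.

    True iff SIFT <= 0.05 (deleterious) or PolyPhen > 0.1 (possibly or
    probably damaging).  A missing score contributes False.
    """
    for name, score in (("sift", sift), ("polyphen", polyphen)):
        if score is not None and not 0.0 <= score <= 1.0:
            raise ValueError(f"{name} score {score} outside [0, 1]")
    if sift is not None and sift <= sift_max:
        return True
    if polyphen is not None and polyphen > polyphen_min:
        return True
    return False


# ---------------------------------------------------------------------------
# variant classification


def annotate_variant_sites(
    variants: Iterable[MissenseVariant],
    annotations: Iterable[FunctionalSiteAnnotation],
    segment_maps: Mapping[str, SegmentMap],
) -> pd.DataFrame:
    """Classify each variant against the functional-site annotation.

    Returns one row per variant with the set of site categories containing
    its position (semicolon-joined), ``known_functional`` (any category) and
    ``putative_functional`` (SIFT/PolyPhen rule).  Generic-position sites
    match through the receptor's segment map; PTM sites match by residue
    index.
    """
    by_generic: dict[tuple[str, str, int], set[str]] = {}
    by_residue: dict[tuple[str, int], set[str]] = {}
    for ann in annotations:
        if ann.generic_position is not None:
            k = (ann.receptor, *_key(ann.generic_position))
            by_generic.setdefault(k, set()).add(ann.category)
        if ann.residue_index is not None:
            by_residue.setdefault((ann.receptor, ann.residue_index), set()).add(
                ann.category
            )

    rows = []
    for v in variants:
        sm = segment_maps.get(v.receptor)
        if sm is not None and v.residue_index > sm.length:
            raise ValueError(
                f"{v.site_id}: residue beyond receptor length {sm.length}"
            )
        cats: set[str] = set(by_residue.get((v.receptor, v.residue_index), set()))
        gp = sm.generic_of(v.residue_index) if sm is not None else None
        if gp is not None:
            cats |= by_generic.get((v.receptor, *_key(gp)), set())
        rows.append(
            {
                "receptor": v.receptor,
                "residue_index": v.residue_index,
                "site_id": v.site_id,
                "generic_position": gp.render() if gp else "",
                "categories": ";".join(sorted(cats)),
                "known_functional": bool(cats),
                "putative_functional": is_putative_functional(v.sift, v.polyphen),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "receptor", "residue_index", "site_id", "generic_position",
            "categories", "known_functional", "putative_functional",
        ],
    )


# ---------------------------------------------------------------------------
# annotation I/O (receptor, position, category, provenance)


def write_annotations_tsv(
    annotations: Iterable[FunctionalSiteAnnotation], path: str | Path
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "receptor": a.receptor,
                "position": a.generic_position.render()
                if a.generic_position is not None
                else str(a.residue_index),
                "category": a.category,
                "provenance": a.provenance,
            }
        )
    pd.DataFrame(rows, columns=["receptor", "position", "category", "provenance"]) \
        .sort_values(["receptor", "category", "position"]) \
        .to_csv(path, sep="\t", index=False)


def read_annotations_tsv(
    path: str | Path, receptor_classes: Mapping[str, str] | None = None
) -> list[FunctionalSiteAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"position": str})
    out = []
    for r in df.itertuples(index=False):
        pos = str(r.position)
        rclass = (receptor_classes or {}).get(str(r.receptor), "A")
        if "x" in pos:
            out.append(
                FunctionalSiteAnnotation(
                    receptor=str(r.receptor),
                    category=str(r.category),
                    generic_position=parse_generic_position(pos, rclass),
                    provenance=str(r.provenance),
                )
            )
        else:
            out.append(
                FunctionalSiteAnnotation(
                    receptor=str(r.receptor),
                    category=str(r.category),
                    residue_index=int(pos),
                    provenance=str(r.provenance),
                )
            )
    return out
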