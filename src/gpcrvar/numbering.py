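"""Structure-based generic residue numbering for GPCRs.

GPCRdb-style generic positions label receptor residues by structural segment
(TM1-7, the inter-helix segments, helix 8) and an index within the segment,
using ``x`` as separator (``3x50``).  The dual notation additionally carries
the sequence-based Ballesteros-Weinstein index before the ``x`` (``5.46x47``).
Because the x.50 anchors differ between receptor classes, a transmembrane
position in one class maps to a shifted index in another; the per-TM offset
tables relative to class A implement that translation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GenericPosition",
    "ClassOffsetTable",
    "SegmentMap",
    "GenericPositionError",
    "parse_generic_position",
    "translate_class_position",
    "assign_structural_segment",
    "read_segment_maps",
    "write_segment_maps",
    "SEGMENT_ORDER",
]

RECEPTOR_CLASSES = ("A", "B", "C", "F")

#: transmembrane helix labels, which are the only cross-class translatable segments
TM_SEGMENTS = frozenset("1234567")

#: valid segment tokens of a generic position: TM1-7, inter-helix 12/23/.../67, helix 8
GENERIC_SEGMENTS = TM_SEGMENTS | {"12", "23", "34", "45", "56", "67", "8"}

#: ordered structural segments covering a full receptor sequence
SEGMENT_ORDER = (
    "N-term",
    "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4", "ECL2",
    "TM5", "ICL3", "TM6", "ECL3", "TM7", "H8", "C-term",
)


class GenericPositionError(ValueError):
    """Raised for malformed generic-position text or invalid translations."""


@dataclass(frozen=True, order=True)
class GenericPosition:
    """A class-aware structure-based residue label such as ``3x50``.

    Parameters
    ----------
    segment_label
        One of ``"1"``..``"7"`` (TM helices), ``"12"``/``"23"``/``"34"``/
        ``"45"``/``"56"``/``"67"`` (inter-helix segments) or ``"8"`` (helix 8).
    index
        Position within the segment under the structure-based x-scheme; >= 1.
    seq_index
        Optional sequence-based (Ballesteros-Weinstein) index, present only in
        dual notation like ``5.46x47``.
    receptor_class
        Receptor class the label refers to (``A``, ``B``, ``C`` or ``F``).
    """

    segment_label: str
    index: int
    seq_index: int | None = None
    receptor_class: str = "A"

    def __post_init__(self) -> None:
        if self.segment_label not in GENERIC_SEGMENTS:
            raise GenericPositionError(
                f"unknown segment label {self.segment_label!r}"
            )
        if self.index < 1:
            raise GenericPositionError(f"index must be >= 1, got {self.index}")
        if self.seq_index is not None and self.seq_index < 1:
            raise GenericPositionError(
                f"seq_index must be >= 1, got {self.seq_index}"
            )
        if self.receptor_class not in RECEPTOR_CLASSES:
            raise GenericPositionError(
                f"unknown receptor class {self.receptor_class!r}"
            )

    def render(self) -> str:
        """Serialize back to x-notation; dual notation when seq_index is set."""
        if self.seq_index is not None:
            return f"{self.segment_label}.{self.seq_index}x{self.index}"
        return f"{self.segment_label}x{self.index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def is_tm(self) -> bool:
        return self.segment_label in TM_SEGMENTS


_POSITION_RE = re.compile(
    r"^(?P<segment>\d{1,2})(?:\.(?P<seq>\d+))?x(?P<index>\d+)$"
)


def parse_generic_position(text: str, receptor_class: str = "A") -> GenericPosition:
    """Parse ``"5x47"``, ``"5.46x47"`` or ``"34x52"`` into a :class:`GenericPosition`.

    Raises
    ------
    GenericPositionError
        If the separator ``x`` is missing, the index is non-numeric, or the
        segment label is not a recognized token.
    """
    if not text:
        raise GenericPositionError("empty generic position")
    text = text.strip()
    if "x" not in text:
        raise GenericPositionError(f"missing 'x' separator in {text!r}")
    m = _POSITION_RE.match(text)
    if m is None:
        raise GenericPositionError(f"malformed generic position {text!r}")
    segment = m.group("segment")
    if segment not in GENERIC_SEGMENTS:
        raise GenericPositionError(f"unknown segment label {segment!r} in {text!r}")
    seq = m.group("seq")
    return GenericPosition(
        segment_label=segment,
        index=int(m.group("index")),
        seq_index=int(seq) if seq is not None else None,
        receptor_class=receptor_class,
    )


# Per-TM index offsets from class A to each other class (TM1..TM7).
_A_TO: dict[str, tuple[int, ...]] = {
    "A": (0, 0, 0, 0, 0, 0, 0),
    "B": (4, 7, 4, 0, -4, 5, 4),
    "C": (4, -4, 4, -10, 0, 2, -5),
    "F": (-3, -1, 0, 0, 4, -1, 0),
}


@dataclass(frozen=True)
class ClassOffsetTable:
    """Signed per-TM offsets between receptor classes, anchored on class A.

    ``offset(from, to, tm)`` satisfies antisymmetry
    (``offset(A→X) = -offset(X→A)``) and pivots through class A when neither
    endpoint is A.
    """

    a_to: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_A_TO)
    )

    def offset(self, from_class: str, to_class: str, tm: str) -> int:
        if tm not in TM_SEGMENTS:
            raise GenericPositionError(
                f"offsets are defined only for TM1-7, not segment {tm!r}"
            )
        for c in (from_class, to_class):
            if c not in self.a_to:
                raise GenericPositionError(f"unknown receptor class {c!r}")
        i = int(tm) - 1
        # compose from→A→to; offset(X→A) = −offset(A→X)
        return -self.a_to[from_class][i] + self.a_to[to_class][i]


DEFAULT_OFFSETS = ClassOffsetTable()


def translate_class_position(
    pos: GenericPosition,
    to_class: str,
    offsets: ClassOffsetTable = DEFAULT_OFFSETS,
) -> GenericPosition:
    """Translate a TM generic position between receptor classes.

    Only TM1-7 positions are translatable; the offset tables do not cover
    loops, helix 8 or the termini.  The sequence-based index, when present,
    is dropped (it is class- and receptor-specific).

    Raises
    ------
    GenericPositionError
        For non-TM segments, unknown classes, or a translated index < 1.
    """
    if not pos.is_tm:
        raise GenericPositionError(
            f"untranslatable segment {pos.segment_label!r}: "
            "cross-class offsets exist only for TM1-7"
        )
    delta = offsets.offset(pos.receptor_class, to_class, pos.segment_label)
    new_index = pos.index + delta
    if new_index < 1:
        raise GenericPositionError(
            f"translated index {new_index} out of range for "
            f"{pos.render()} ({pos.receptor_class}→{to_class})"
        )
    return replace(pos, index=new_index, seq_index=None, receptor_class=to_class)


@dataclass
class SegmentMap:
    """Per-receptor segmentation and generic-position assignment.

    ``ranges`` maps each structural segment to an inclusive 1-based residue
    range; ranges are disjoint, ordered as in :data:`SEGMENT_ORDER`, and cover
    ``1..length``.  ``generic_positions`` maps residue index to its generic
    position where one is defined (TM and helix-8 residues; loop residues
    mostly lack one).
    """

    receptor: str
    length: int
    ranges: dict[str, tuple[int, int]]
    generic_positions: dict[int, GenericPosition] = field(default_factory=dict)
    sequence: str | None = None
    receptor_class: str = "A"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = 0
        for seg in SEGMENT_ORDER:
            if seg not in self.ranges:
                continue
            start, end = self.ranges[seg]
            if start != prev_end + 1:
                raise ValueError(
                    f"{self.receptor}: segment {seg} starts at {start}, "
                    f"expected {prev_end + 1}"
                )
            if end < start:
                raise ValueError(f"{self.receptor}: empty segment {seg}")
            prev_end = end
        if prev_end != self.length:
            raise ValueError(
                f"{self.receptor}: segments cover 1..{prev_end}, "
                f"length is {self.length}"
            )
        for idx in self.generic_positions:
            if not 1 <= idx <= self.length:
                raise ValueError(
                    f"{self.receptor}: generic-numbered residue {idx} outside "
                    f"1..{self.length}"
                )

    def segment_of(self, residue_index: int) -> str:
        return assign_structural_segment(residue_index, self)

    def generic_of(self, residue_index: int) -> GenericPosition | None:
        return self.generic_positions.get(residue_index)

    def residue_of(self, pos: GenericPosition) -> int | None:
        """Inverse lookup: residue index carrying a generic position, if any."""
        key = (pos.segment_label, pos.index)
        for idx, p in self.generic_positions.items():
            if (p.segment_label, p.index) == key:
                return idx
        return None

    @property
    def generic_position_set(self) -> set[tuple[str, int]]:
        return {(p.segment_label, p.index) for p in self.generic_positions.values()}


def assign_structural_segment(residue_index: int, seg_map: SegmentMap) -> str:
    """Assign a residue to exactly one structural segment.

    Residues in a TM range get the helix, residues between helices the loop,
    residues before TM1 the N-terminus and after H8 the C-terminus.
    """
    if not 1 <= residue_index <= seg_map.length:
        raise ValueError(
            f"residue {residue_index} outside 1..{seg_map.length} "
            f"for {seg_map.receptor}"
        )
    for seg in SEGMENT_ORDER:
        rng = seg_map.ranges.get(seg)
        if rng is not None and rng[0] <= residue_index <= rng[1]:
            return seg
    raise AssertionError("segment ranges do not cover the sequence")  # pragma: no cover


def _segments_to_ranges(segments: Iterable[str]) -> dict[str, tuple[int, int]]:
    ranges: dict[str, tuple[int, int]] = {}
    for i, seg in enumerate(segments, start=1):
        if seg in ranges:
            start, end = ranges[seg]
            if i != end + 1:
                raise ValueError(f"segment {seg} is not contiguous")
            ranges[seg] = (start, i)
        else:
            ranges[seg] = (i, i)
    return ranges


def read_segment_maps(
    path: str | Path, receptor_classes: Mapping[str, str] | None = None
) -> dict[str, SegmentMap]:
    """Read per-residue segment maps from TSV.

    Expected columns: ``receptor``, ``residue_index``, ``amino_acid``,
    ``segment``, ``generic_position`` (empty where undefined).
    """
    df = pd.read_csv(path, sep="\t", dtype={"generic_position": "string"})
    required = {"receptor", "residue_index", "amino_acid", "segment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment map missing columns: {sorted(missing)}")
    out: dict[str, SegmentMap] = {}
    for receptor, grp in df.groupby("receptor", sort=False):
        grp = grp.sort_values("residue_index")
        if list(grp["residue_index"]) != list(range(1, len(grp) + 1)):
            raise ValueError(f"{receptor}: residue indices are not 1..length")
        rclass = (receptor_classes or {}).get(str(receptor), "A")
        generic: dict[int, GenericPosition] = {}
        if "generic_position" in grp.columns:
            for idx, text in zip(grp["residue_index"], grp["generic_position"]):
                if pd.notna(text) and str(text).strip():
                    generic[int(idx)] = parse_generic_position(str(text), rclass)
        out[str(receptor)] = SegmentMap(
            receptor=str(receptor),
            length=len(grp),
            ranges=_segments_to_ranges(grp["segment"]),
            generic_positions=generic,
            sequence="".join(grp["amino_acid"].astype(str)),
            receptor_class=rclass,
        )
    return out


def write_segment_maps(maps: Mapping[str, SegmentMap], path: str | Path) -> None:
    """Serialize segment maps to the TSV dialect read by :func:`read_segment_maps`."""
    rows = []
    for receptor in sorted(maps):
        sm = maps[receptor]
        seq = sm.sequence or "X" * sm.length
        for idx in range(1, sm.length + 1):
            gp = sm.generic_positions.get(idx)
            rows.append(
                {
                    "receptor": receptor,
                    "residue_index": idx,
                    "amino_acid": seq[idx - 1],
                    "segment": sm.segment_of(idx),
                    "generic_position": gp.render() if gp else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
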