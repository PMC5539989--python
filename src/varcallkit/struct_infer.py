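"""Annotation transfer across BRCT-domain proteins via sequence alignment.

BRCT domains (tandem repeats in BRCA1, MCPH1, MDC1) are structurally
conserved, so the classification of a residue in a well-characterised
reference protein carries information about the equivalent (aligned)
residue in a paralogue.  This module consumes a pre-computed alignment
(aligned FASTA), maps protein positions through alignment columns, and
transfers class-4/5 ("impact") or class-1/2 ("no impact") annotation to
variants in the target protein.  It also summarizes per-segment
tolerance: the fraction of tested variants in each secondary-structure
segment falling in fClass 4-5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio import AlignIO

from .assay_io import VariantSpec

__all__ = [
    "GAP",
    "AlignedSequence",
    "DomainAlignment",
    "AnnotationTable",
    "read_domain_alignment",
    "map_position",
    "transfer_annotation",
    "segment_tolerance",
    "IMPACT_SUPPORTED",
    "NO_IMPACT_SUPPORTED",
    "UNINFORMATIVE",
]

GAP = "GAP"
GAP_CHARS = "-."

IMPACT_SUPPORTED = "IMPACT_SUPPORTED"
NO_IMPACT_SUPPORTED = "NO_IMPACT_SUPPORTED"
UNINFORMATIVE = "UNINFORMATIVE"

SEGMENT_VOCABULARY = frozenset(
    {"coiled-coil", "alpha-helix", "beta-sheet", "linker", "disordered"}
)


@dataclass(frozen=True)
class AlignedSequence:
    """One row of the alignment: gapped residues plus the full-protein
    position of its first residue (1-based)."""

    protein: str
    residues: str
    start: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.protein}: start position must be >= 1")

    @property
    def positions(self) -> tuple[int | None, ...]:
        """Protein position per alignment column, None at gaps."""
        out: list[int | None] = []
        pos = self.start
        for ch in self.residues:
            if ch in GAP_CHARS:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return tuple(out)


@dataclass(frozen=True)
class DomainAlignment:
    """>= 2 aligned sequences with per-sequence position maps."""

    sequences: tuple[AlignedSequence, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least two sequences")
        lengths = {len(s.residues) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must all have equal length")
        names = [s.protein for s in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("duplicate protein ids in alignment")

    def sequence(self, protein: str) -> AlignedSequence:
        for s in self.sequences:
            if s.protein == protein:
                return s
        raise KeyError(f"protein {protein!r} not in alignment")

    def column_of(self, protein: str, position: int) -> int:
        """0-based alignment column holding the given protein position."""
        for col, p in enumerate(self.sequence(protein).positions):
            if p == position:
                return col
        raise IndexError(
            f"position {position} of {protein!r} is outside the aligned span"
        )


_ID_RANGE = re.compile(r"^(?P<name>.+)/(?P<start>\d+)-(?P<end>\d+)$")


def read_domain_alignment(path, starts: dict[str, int] | None = None) -> DomainAlignment:
    """Read an aligned FASTA into a :class:`DomainAlignment`.

    Start offsets come from ``starts`` (protein -> first residue
    position) or from Stockholm-style ids like ``BRCA1/1646-1859``;
    sequences with neither default to start 1.
    """
    aln = AlignIO.read(str(path), "fasta")
    seqs = []
    for rec in aln:
        name, start = rec.id, 1
        m = _ID_RANGE.match(rec.id)
        if m:
            name = m.group("name")
            start = int(m.group("start"))
        if starts and name in starts:
            start = starts[name]
        seqs.append(AlignedSequence(protein=name, residues=str(rec.seq).upper(), start=start))
    return DomainAlignment(sequences=tuple(seqs))


def map_position(alignment: DomainAlignment, source: str, position: int,
                 target: str) -> int | str:
    """Map a protein position to the equivalent position in another
    protein of the alignment; ``GAP`` if the target is gapped there."""
    col = alignment.column_of(source, position)
    p = alignment.sequence(target).positions[col]
    return GAP if p is None else p


@dataclass(frozen=True)
class AnnotationTable:
    """Per-residue functional classes and structural segment labels.

    ``classes`` maps (protein, position) to a set of class strings such
    as ``"fClass5"`` or ``"IARC4"``; ``segments`` maps (protein,
    position) to a segment label; ``flags`` carries free-text notes
    (phosphopeptide pocket, salt bridge, ...).
    """

    classes: dict[tuple[str, int], frozenset[str]]
    segments: dict[tuple[str, int], str] | None = None
    flags: dict[tuple[str, int], tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        for (_, pos) in self.classes:
            if pos < 1:
                raise ValueError("annotation positions must be positive")
        if self.segments:
            bad = {s for s in self.segments.values() if s not in SEGMENT_VOCABULARY}
            if bad:
                raise ValueError(
                    f"segment labels outside the vocabulary: {sorted(bad)}"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Build from a table with columns protein, position, class
        (semicolon-separated), and optionally segment."""
        classes: dict[tuple[str, int], frozenset[str]] = {}
        segments: dict[tuple[str, int], str] = {}
        for rec in df.to_dict("records"):
            key = (str(rec["protein"]), int(rec["position"]))
            raw = rec.get("class")
            if isinstance(raw, str) and raw.strip():
                classes[key] = frozenset(
                    classes.get(key, frozenset()) | set(raw.split(";"))
                )
            else:
                classes.setdefault(key, frozenset())
            seg = rec.get("segment")
            if isinstance(seg, str) and seg.strip():
                segments[key] = seg
        return cls(classes=classes, segments=segments or None)


_CLASS_NUM = re.compile(r"^(?:fClass|IARC)\s*([1-5])$", re.IGNORECASE)


def _class_numbers(classes: Iterable[str]) -> set[int]:
    out = set()
    for c in classes:
        m = _CLASS_NUM.match(c.strip())
        if m:
            out.add(int(m.group(1)))
    return out


def _verdict_for_position(
    position: int,
    source_protein: str,
    alignment: DomainAlignment,
    annotations: AnnotationTable,
    reference: str,
) -> tuple[str, str]:
    try:
        mapped = map_position(alignment, source_protein, position, reference)
    except IndexError:
        return UNINFORMATIVE, "position outside aligned span"
    if mapped == GAP:
        return UNINFORMATIVE, "reference gapped at equivalent column"
    nums = _class_numbers(annotations.classes.get((reference, mapped), frozenset()))
    if nums & {4, 5}:
        return IMPACT_SUPPORTED, f"reference {reference} position {mapped} class 4/5"
    if nums and nums <= {1, 2}:
        return NO_IMPACT_SUPPORTED, f"reference {reference} position {mapped} class 1/2 only"
    return UNINFORMATIVE, "reference residue unannotated or uncertain"


_VERDICT_RANK = {IMPACT_SUPPORTED: 2, NO_IMPACT_SUPPORTED: 1, UNINFORMATIVE: 0}


def transfer_annotation(
    variants: list[VariantSpec],
    alignment: DomainAlignment,
    annotations: AnnotationTable,
    reference: str,
    target: str,
) -> pd.DataFrame:
    """Infer functional impact of target-protein variants from the
    annotation of the equivalent reference residues.

    A compound variant takes the most impact-supporting verdict across
    its substitutions.  Positions outside the alignment or mapping to a
    gap are flagged UNINFORMATIVE with a reason, never dropped.
    """
    rows = []
    for spec in variants:
        best: tuple[str, str] | None = None
        for _, pos, _ in spec.substitutions:
            verdict = _verdict_for_position(pos, target, alignment, annotations, reference)
            if best is None or _VERDICT_RANK[verdict[0]] > _VERDICT_RANK[best[0]]:
                best = verdict
        assert best is not None  # VariantSpec guarantees >= 1 substitution
        rows.append(
            {"variant": spec.label, "inference": best[0], "reason": best[1]}
        )
    return pd.DataFrame(rows)


def segment_tolerance(
    calls: list[tuple[VariantSpec, int]],
    segments: AnnotationTable,
    protein: str,
    min_variants: int = 3,
) -> pd.DataFrame:
    """Per-segment tolerance to substitution.

    For each structural segment: the number of variants tested, the
    number in fClass 4-5, and their fraction; segments with fewer than
    ``min_variants`` tested are flagged excluded rather than dropped.
    """
    if segments.segments is None:
        raise ValueError("annotation table carries no segment labels")
    per_seg: dict[str, list[int]] = {}
    for spec, fc in calls:
        pos = min(spec.positions)
        key = (protein, pos)
        if key not in segments.segments:
            raise KeyError(
                f"variant {spec.label!r}: no segment label for position {pos}"
            )
        per_seg.setdefault(segments.segments[key], []).append(fc)
    rows = []
    for seg in sorted(set(segments.segments.values())):
        fcs = per_seg.get(seg, [])
        n, n_path = len(fcs), sum(fc in (4, 5) for fc in fcs)
        rows.append(
            {
                "segment": seg,
                "n_tested": n,
                "n_fclass45": n_path,
                "fraction_pathogenic": n_path / n if n else float("nan"),
                "excluded": n < min_variants,
            }
        )
    return pd.DataFrame(rows)
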