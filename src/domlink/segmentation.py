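"""Segment annotated proteins into disjoint domain intervals and inter-domain linkers.

A linker is the sequence strictly between two annotated domains on the same
protein; N- and C-terminal tails (before the first domain, after the last) are
neither domains nor linkers and are excluded from all downstream composition.
Proteins without any annotated domain are discarded from the domain/linker
analysis (they still count for whole-proteome composition).

Overlapping annotations are merged into a single domain interval with the
pooled names, which prevents double-counting residues and guarantees the
partition property (domains + linkers + tails cover the protein exactly once).
Abutting intervals (next.start == current.end + 1) stay distinct; the gap
between them has length zero so they simply yield no linker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seq_io import DomainAnnotation, Proteome

logger = logging.getLogger(__name__)

DOMAIN = "domain"
LINKER = "linker"


@dataclass(frozen=True)
class MergedInterval:
    """A maximal run of overlapping domain annotations, with pooled names."""

    start: int
    end: int
    names: frozenset[str]


@dataclass(frozen=True)
class Segment:
    """A domain or linker interval on one protein (1-based, inclusive).

    ``source_domains`` holds the pooled names of the merged interval for a
    domain segment, and the pair (left flank names, right flank names) for a
    linker segment — a linker always has exactly two flanking intervals.
    """

    species: str
    protein_id: str
    feature_class: str  # DOMAIN or LINKER
    start: int
    end: int
    source_domains: frozenset[str] | tuple[frozenset[str], frozenset[str]]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def flanking_names(self) -> frozenset[str]:
        """Union of names attached to this segment (both flanks for a linker)."""
        if self.feature_class == LINKER:
            left, right = self.source_domains
            return left | right
        return self.source_domains  # type: ignore[return-value]


@dataclass
class SegmentSet:
    """The ordered, disjoint domain and linker segments of one protein."""

    species: str
    protein_id: str
    protein_length: int
    segments: list[Segment] = field(default_factory=list)

    @property
    def domains(self) -> list[Segment]:
        return [s for s in self.segments if s.feature_class == DOMAIN]

    @property
    def linkers(self) -> list[Segment]:
        return [s for s in self.segments if s.feature_class == LINKER]


def merge_intervals(annotations: Sequence[DomainAnnotation]) -> list[MergedInterval]:
    """Merge overlapping domain annotations of one protein into disjoint intervals.

    Intervals are sorted by start; two intervals merge when the next starts at
    or before the current end. Abutting intervals are kept distinct. The names
    of all merged inputs are pooled. Empty input yields an empty list.
    """
    if not annotations:
        return []
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    merged: list[tuple[int, int, set[str]]] = []
    for ann in ordered:
        if merged and ann.start <= merged[-1][1]:
            prev_start, prev_end, names = merged[-1]
            merged[-1] = (prev_start, max(prev_end, ann.end), names | {ann.domain_name})
        else:
            merged.append((ann.start, ann.end, {ann.domain_name}))
    return [MergedInterval(s, e, frozenset(n)) for s, e, n in merged]


def extract_segments(
    protein_length: int,
    merged_intervals: Sequence[MergedInterval],
    species: str = "",
    protein_id: str = "",
) -> SegmentSet:
    """Build the SegmentSet of a protein from its merged domain intervals.

    Each merged interval becomes a domain segment; each gap of length >= 1
    between consecutive intervals becomes a linker spanning
    (prev.end + 1, next.start - 1). Terminal tails produce no segments.
    """
    for iv in merged_intervals:
        if not (1 <= iv.start <= iv.end <= protein_length):
            raise ValueError(
                f"interval ({iv.start}, {iv.end}) out of bounds for protein "
                f"{protein_id!r} of length {protein_length}"
            )
    segset = SegmentSet(species=species, protein_id=protein_id, protein_length=protein_length)
    for i, iv in enumerate(merged_intervals):
        if i > 0:
            prev = merged_intervals[i - 1]
            gap_start, gap_end = prev.end + 1, iv.start - 1
            if gap_start <= gap_end:
                segset.segments.append(
                    Segment(
                        species=species,
                        protein_id=protein_id,
                        feature_class=LINKER,
                        start=gap_start,
                        end=gap_end,
                        source_domains=(prev.names, iv.names),
                    )
                )
        segset.segments.append(
            Segment(
                species=species,
                protein_id=protein_id,
                feature_class=DOMAIN,
                start=iv.start,
                end=iv.end,
                source_domains=iv.names,
            )
        )
    return segset


def segment_proteome(
    proteome: Proteome,
    annotations: Iterable[DomainAnnotation],
) -> dict[str, SegmentSet]:
    """Segment every annotated protein of a proteome; discard the unannotated ones.

    Returns SegmentSets keyed by protein id, only for proteins carrying at
    least one domain annotation. Logs the kept/discarded counts.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        if ann.species != proteome.species:
            continue
        by_protein.setdefault(ann.protein_id, []).append(ann)

    result: dict[str, SegmentSet] = {}
    for protein_id, anns in by_protein.items():
        record = proteome.proteins[protein_id]
        merged = merge_intervals(anns)
        result[protein_id] = extract_segments(
            len(record), merged, species=proteome.species, protein_id=protein_id
        )
    n_discarded = len(proteome) - len(result)
    if not result:
        logger.warning(
            "species %s: no annotated proteins; all %d discarded",
            proteome.species,
            len(proteome),
        )
    else:
        logger.info(
            "species %s: kept %d annotated proteins, discarded %d without domains",
            proteome.species,
            len(result),
            n_discarded,
        )
    return result
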