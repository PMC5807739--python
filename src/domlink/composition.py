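"""Amino-acid usage counting and percentage profiles.

Residues are pooled across all proteins of a species before percentages are
taken (the standard proteome-composition convention, robust to protein length
variation), rather than averaging per-protein percentages. Ambiguity letters
(B, J, O, U, X, Z) are excluded from both the numerator and the denominator,
so the 20 standard percentages of a non-empty profile always sum to 100.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seq_io import STANDARD_AMINO_ACIDS, Proteome
from .segmentation import DOMAIN, LINKER, SegmentSet

logger = logging.getLogger(__name__)

#: Sentinel name filter meaning "every domain name" (the background classes).
ALL = None

PROTEOME = "proteome"
SELECTED_DOMAIN = "selected_domain"
SELECTED_LINKER = "selected_linker"

_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)


@dataclass
class CompositionProfile:
    """Counts and percentages of the 20 standard amino acids for one feature class.

    ``percentages`` is None when no residues were counted (empty profile); the
    enrichment layer decides how to treat empty profiles.
    """

    species: str
    feature_class: str
    counts: dict[str, int]
    total: int
    percentages: dict[str, float] | None

    @property
    def is_empty(self) -> bool:
        return self.total == 0


def count_residues(fragments: Iterable[str]) -> dict[str, int]:
    """Count standard amino acids over a pool of sequence fragments.

    Ambiguity letters are ignored: excluded from the per-letter counts and
    from the total alike.
    """
    raw = Counter()
    for frag in fragments:
        raw.update(frag)
    return {aa: raw.get(aa, 0) for aa in STANDARD_AMINO_ACIDS}


def to_percentages(counts: Mapping[str, int]) -> dict[str, float] | None:
    """Turn counts into percentages of the total; None for an all-zero profile."""
    total = sum(counts.values())
    if total == 0:
        return None
    return {aa: 100.0 * counts[aa] / total for aa in STANDARD_AMINO_ACIDS}


def _profile(species: str, feature_class: str, fragments: Iterable[str]) -> CompositionProfile:
    counts = count_residues(fragments)
    total = sum(counts.values())
    return CompositionProfile(
        species=species,
        feature_class=feature_class,
        counts=counts,
        total=total,
        percentages=to_percentages(counts),
    )


def proteome_composition(proteome: Proteome) -> CompositionProfile:
    """Whole-proteome composition, pooling every protein of the species.

    All sequences count here, including proteins without annotated domains —
    the discard rule applies only to the domain/linker analysis.
    """
    if len(proteome) == 0:
        raise ValueError(f"proteome {proteome.species!r} is empty")
    return _profile(
        proteome.species, PROTEOME, (rec.sequence for rec in proteome)
    )


def _segment_matches(segment, feature_class: str, name_filter) -> bool:
    if segment.feature_class != feature_class:
        return False
    if name_filter is ALL:
        return True
    # a linker belongs to a selection when at least one flank carries a
    # selected name; a domain when its pooled names intersect the selection
    return bool(segment.flanking_names() & frozenset(name_filter))


def feature_composition(
    proteome: Proteome,
    segment_sets: Mapping[str, SegmentSet],
    feature_class: str,
    name_filter: Iterable[str] | None = ALL,
) -> CompositionProfile:
    """Composition of one feature class (domains or linkers) for one species.

    With ``name_filter=ALL`` this is the species background of all domains (or
    all linkers). With a set of selected domain names it is the
    selected_domain (or selected_linker) profile: a domain segment matches
    when its merged names intersect the selection, a linker when at least one
    of its two flanking intervals does. Zero matching segments yield an empty
    profile (flagged, not an error).
    """
    if feature_class not in (DOMAIN, LINKER):
        raise ValueError(f"feature_class must be {DOMAIN!r} or {LINKER!r}")
    fragments = []
    for protein_id, segset in segment_sets.items():
        seq = proteome.proteins[protein_id].sequence
        for seg in segset.segments:
            if _segment_matches(seg, feature_class, name_filter):
                fragments.append(seq[seg.start - 1 : seg.end])
    if name_filter is ALL:
        label = feature_class
    else:
        label = SELECTED_DOMAIN if feature_class == DOMAIN else SELECTED_LINKER
    profile = _profile(proteome.species, label, fragments)
    if profile.is_empty:
        logger.info(
            "species %s: empty %s profile (no matching segments)",
            proteome.species,
            label,
        )
    return profile


def count_matching_segments(
    segment_sets: Mapping[str, SegmentSet],
    feature_class: str,
    name_filter: Iterable[str] | None = ALL,
) -> int:
    """Number of segments of a class matching a selection (for warning colors)."""
    return sum(
        1
        for segset in segment_sets.values()
        for seg in segset.segments
        if _segment_matches(seg, feature_class, name_filter)
    )


def classify_fold(pct_linker: float, pct_domain: float) -> str:
    """Fold class of one (linker %, domain %) dot: strict twofold boundaries."""
    if pct_linker > 2.0 * pct_domain:
        return "above_twofold"
    if pct_domain > 2.0 * pct_linker:
        return "below_twofold"
    return "between"


def pairwise_usage_table(
    profiles: Iterable[CompositionProfile],
) -> list[dict]:
    """Rows of (species, amino acid, % in linkers, % in domains, fold class).

    One row per species and amino acid — the canonical "dots" for the
    linker-versus-domain scatter. Species lacking a non-empty domain or
    linker profile are excluded with a log line. The fold class marks dots
    beyond the twofold guide lines: above_twofold when the amino acid is more
    than twice as abundant in linkers as in domains, below_twofold for the
    converse, between otherwise (boundary points fall between).
    """
    by_species: dict[str, dict[str, CompositionProfile]] = {}
    for p in profiles:
        if p.feature_class in (DOMAIN, LINKER):
            by_species.setdefault(p.species, {})[p.feature_class] = p
    rows: list[dict] = []
    for species in sorted(by_species):
        pair = by_species[species]
        if (
            DOMAIN not in pair
            or LINKER not in pair
            or pair[DOMAIN].is_empty
            or pair[LINKER].is_empty
        ):
            logger.warning(
                "species %s lacks a usable domain or linker profile; excluded "
                "from the pairwise usage table",
                species,
            )
            continue
        dom, lnk = pair[DOMAIN].percentages, pair[LINKER].percentages
        for aa in STANDARD_AMINO_ACIDS:
            rows.append(
                {
                    "species": species,
                    "amino_acid": aa,
                    "pct_linker": lnk[aa],
                    "pct_domain": dom[aa],
                    "fold_class": classify_fold(lnk[aa], dom[aa]),
                }
            )
    return rows


def composition_long_rows(profiles: Iterable[CompositionProfile]) -> list[dict]:
    """Flatten profiles into composition_long table rows (empty profiles skipped)."""
    rows = []
    for p in profiles:
        if p.is_empty:
            logger.warning(
                "species %s: skipping empty %s profile in composition table",
                p.species,
                p.feature_class,
            )
            continue
        for aa in STANDARD_AMINO_ACIDS:
            rows.append(
                {
                    "species": p.species,
                    "feature_class": p.feature_class,
                    "amino_acid": aa,
                    "count": p.counts[aa],
                    "percentage": p.percentages[aa],
                }
            )
    return rows
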