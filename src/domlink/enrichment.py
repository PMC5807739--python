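"""Domain-set selection and the four per-amino-acid enrichment statistics.

A query (exact domain name, or a case-insensitive regular expression searched
over both names and descriptions) selects a set of domains from the
dictionary. For every amino acid, the composition of the selected domains is
compared against the background of all domains, and the composition of the
linkers surrounding the selected domains against the background of all
linkers. Four descriptive statistics summarise each comparison across species:

direction of enrichment
    fraction of species in which the amino acid's percentage in the feature
    strictly exceeds its percentage in the background (1.0 = enriched
    everywhere; ties count as not enriched).
mean fold deviation
    |f/b - 1| with f and b the cross-species mean percentages in feature and
    background; its direction is taken from the direction of enrichment.
mean abundance
    f itself, the mean feature percentage without contrast to the background.
dispersion
    sum of squared Euclidean distances of the per-species points to their
    centroid, a between-species variability measure; reported separately for
    the feature values and the background values (their sum is the dispersion
    of the 2-D (background, feature) point cloud).

Small selections can skew results simply because few protein families are
being looked at, so each species is flagged by its matched-segment count:
green for more than ten matches, red for more than five but at most ten,
yellow otherwise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import STANDARD_AMINO_ACIDS, DictionaryEntry, Proteome
from .segmentation import DOMAIN, LINKER, SegmentSet
from . import composition as comp

logger = logging.getLogger(__name__)

EXACT_NAME = "exact_name"
REGEX = "regex"

FEATURE_ENRICHED = "feature_enriched"
BACKGROUND_ENRICHED = "background_enriched"
TIE = "tie"

GREEN, RED, YELLOW = "green", "red", "yellow"


@dataclass
class QuerySelection:
    """A dictionary query and the domain names it matched.

    Match counts and warning colors are populated per analysed feature
    (selected_domain / selected_linker) and species once statistics run.
    """

    query: str
    mode: str
    matched_names: frozenset[str]
    per_species_match_count: dict[str, dict[str, int]] = field(default_factory=dict)
    warning_color: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.matched_names


@dataclass
class FeatureBackgroundPair:
    """Per-species feature and background percentages of one amino acid."""

    amino_acid: str
    per_species_feature_pct: dict[str, float]
    per_species_background_pct: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.per_species_feature_pct) != set(self.per_species_background_pct):
            raise ValueError("feature and background species sets differ")

    @property
    def species(self) -> list[str]:
        return sorted(self.per_species_feature_pct)

    @property
    def f(self) -> float:
        """Mean feature percentage across species."""
        return float(np.mean([self.per_species_feature_pct[s] for s in self.species]))

    @property
    def b(self) -> float:
        """Mean background percentage across species."""
        return float(np.mean([self.per_species_background_pct[s] for s in self.species]))


@dataclass
class AminoAcidStat:
    """The four statistics for one amino acid in one feature."""

    amino_acid: str
    feature: str  # selected_domain or selected_linker
    direction_of_enrichment: float
    enrichment_sign: str
    mean_fold_deviation: float
    mean_abundance: float
    dispersion_feature: float
    dispersion_background: float
    n_species: int


def select_domains(
    query: str,
    mode: str,
    dictionary: Mapping[str, DictionaryEntry],
) -> QuerySelection:
    """Select dictionary entries by exact name or by regex over name + description.

    Regex matching is case-insensitive and unanchored (substring semantics).
    An empty match yields an empty selection with a warning; downstream
    statistics refuse to run on it.
    """
    if not query:
        raise ValueError("query must be non-empty")
    if mode == EXACT_NAME:
        matched = frozenset(name for name in dictionary if name == query)
    elif mode == REGEX:
        try:
            pattern = re.compile(query, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"invalid regular expression {query!r}: {exc}") from None
        matched = frozenset(
            e.domain_name
            for e in dictionary.values()
            if pattern.search(e.domain_name) or pattern.search(e.description)
        )
    else:
        raise ValueError(f"unknown query mode {mode!r}")
    if not matched:
        logger.warning("query %r (%s) matched no dictionary entries", query, mode)
    return QuerySelection(query=query, mode=mode, matched_names=matched)


def match_count_color(n: int) -> str:
    """Warning color for a matched-segment count.

    More than ten matches: green. More than five but at most ten: red.
    Otherwise: yellow. (Ten itself, unassigned by the verbal rule, takes the
    conservative red.)
    """
    if n < 0:
        raise ValueError(f"match count must be non-negative, got {n}")
    if n > 10:
        return GREEN
    if n > 5:
        return RED
    return YELLOW


def direction_of_enrichment(pair: FeatureBackgroundPair) -> float:
    """Fraction of species where the feature percentage strictly exceeds the background."""
    species = pair.species
    if not species:
        raise ValueError(f"{pair.amino_acid}: no species in pair")
    wins = sum(
        pair.per_species_feature_pct[s] > pair.per_species_background_pct[s]
        for s in species
    )
    return wins / len(species)


def mean_fold_deviation(pair: FeatureBackgroundPair) -> tuple[float, str]:
    """|f/b - 1| plus its direction (from the direction of enrichment).

    The sign is feature_enriched when the direction of enrichment exceeds
    0.5, background_enriched below 0.5, and a tie at exactly 0.5.
    """
    b = pair.b
    if b == 0:
        raise ZeroDivisionError(
            f"mean fold deviation undefined for {pair.amino_acid}: "
            "background mean percentage is zero"
        )
    value = abs(pair.f / b - 1.0)
    direction = direction_of_enrichment(pair)
    if direction > 0.5:
        sign = FEATURE_ENRICHED
    elif direction < 0.5:
        sign = BACKGROUND_ENRICHED
    else:
        sign = TIE
    return value, sign


def mean_abundance(pair: FeatureBackgroundPair) -> float:
    """Mean feature percentage across species (f), no background contrast."""
    if not pair.species:
        raise ValueError(f"{pair.amino_acid}: no species in pair")
    return pair.f


def dispersion(points: Sequence) -> float:
    """Sum of squared Euclidean distances of points to their centroid.

    Accepts 1-D values or d-dimensional points, one per species. Equals
    n times the summed population variance over coordinates.
    """
    arr = np.asarray(points, dtype=float)
    if arr.size == 0:
        raise ValueError("dispersion requires at least one point")
    if arr.ndim == 1:
        arr = arr[:, None]
    centroid = arr.mean(axis=0)
    return float(((arr - centroid) ** 2).sum())


def build_pairs(
    feature_profiles: Mapping[str, comp.CompositionProfile],
    background_profiles: Mapping[str, comp.CompositionProfile],
) -> dict[str, FeatureBackgroundPair]:
    """Assemble one FeatureBackgroundPair per amino acid over the shared species.

    Species with an empty feature (or background) profile are dropped from
    both sides, so f and b always average over the same species set.
    """
    kept, dropped = [], []
    for species in sorted(feature_profiles):
        fp = feature_profiles[species]
        bp = background_profiles.get(species)
        if bp is None or fp.is_empty or bp.is_empty:
            dropped.append(species)
        else:
            kept.append(species)
    if dropped:
        logger.info(
            "dropped %d species with empty profiles from the comparison: %s",
            len(dropped),
            ", ".join(dropped),
        )
    pairs = {}
    for aa in STANDARD_AMINO_ACIDS:
        pairs[aa] = FeatureBackgroundPair(
            amino_acid=aa,
            per_species_feature_pct={
                s: feature_profiles[s].percentages[aa] for s in kept
            },
            per_species_background_pct={
                s: background_profiles[s].percentages[aa] for s in kept
            },
        )
    return pairs


def _stats_for_feature(
    feature_label: str,
    pairs: Mapping[str, FeatureBackgroundPair],
) -> list[AminoAcidStat]:
    stats = []
    for aa in STANDARD_AMINO_ACIDS:
        pair = pairs[aa]
        direction = direction_of_enrichment(pair)
        if pair.b == 0:
            # absent from the whole background, hence from the feature too
            logger.info(
                "%s/%s absent from background; fold deviation reported as 0",
                feature_label,
                aa,
            )
            value, sign = 0.0, TIE
        else:
            value, sign = mean_fold_deviation(pair)
        species = pair.species
        stats.append(
            AminoAcidStat(
                amino_acid=aa,
                feature=feature_label,
                direction_of_enrichment=direction,
                enrichment_sign=sign,
                mean_fold_deviation=value,
                mean_abundance=mean_abundance(pair),
                dispersion_feature=dispersion(
                    [pair.per_species_feature_pct[s] for s in species]
                ),
                dispersion_background=dispersion(
                    [pair.per_species_background_pct[s] for s in species]
                ),
                n_species=len(species),
            )
        )
    return stats


def raccoon_stats(
    selection: QuerySelection,
    proteomes: Mapping[str, Proteome],
    segment_sets: Mapping[str, Mapping[str, SegmentSet]],
) -> dict[str, list[AminoAcidStat]]:
    """Compute all four statistics for the selected domains and their linkers.

    Builds, per species, the selected_domain profile against the all-domain
    background and the selected_linker (surrounding linkers) profile against
    the all-linker background, then applies the statistics per amino acid.
    Match counts and warning colors are recorded on the selection. Raises if
    the selection matches no segments in any species.
    """
    if selection.is_empty:
        raise ValueError(
            f"query {selection.query!r} matched no dictionary entries; "
            "nothing to analyse"
        )
    names = selection.matched_names
    analyses = {
        comp.SELECTED_DOMAIN: (DOMAIN, names, DOMAIN, comp.ALL),
        comp.SELECTED_LINKER: (LINKER, names, LINKER, comp.ALL),
    }
    results: dict[str, list[AminoAcidStat]] = {}
    any_match = False
    for feature_label, (fclass, ffilter, bclass, bfilter) in analyses.items():
        feature_profiles, background_profiles = {}, {}
        counts, colors = {}, {}
        for species in sorted(proteomes):
            segsets = segment_sets.get(species, {})
            feature_profiles[species] = comp.feature_composition(
                proteomes[species], segsets, fclass, ffilter
            )
            background_profiles[species] = comp.feature_composition(
                proteomes[species], segsets, bclass, bfilter
            )
            n = comp.count_matching_segments(segsets, fclass, ffilter)
            counts[species] = n
            colors[species] = match_count_color(n)
        selection.per_species_match_count[feature_label] = counts
        selection.warning_color[feature_label] = colors
        if any(not p.is_empty for p in feature_profiles.values()):
            any_match = True
        pairs = build_pairs(feature_profiles, background_profiles)
        if not pairs[STANDARD_AMINO_ACIDS[0]].species:
            results[feature_label] = []
            continue
        results[feature_label] = _stats_for_feature(feature_label, pairs)
    if not any_match:
        raise ValueError(
            f"selection {sorted(selection.matched_names)} matched zero segments "
            "in every species"
        )
    return results


def dotplot_rows(
    selection: QuerySelection,
    proteomes: Mapping[str, Proteome],
    segment_sets: Mapping[str, Mapping[str, SegmentSet]],
) -> list[dict]:
    """Per-species dot-plot rows: feature vs background percentage with colors."""
    rows: list[dict] = []
    for feature_label, (fclass, ffilter) in {
        comp.SELECTED_DOMAIN: (DOMAIN, selection.matched_names),
        comp.SELECTED_LINKER: (LINKER, selection.matched_names),
    }.items():
        feature_profiles, background_profiles = {}, {}
        for species in sorted(proteomes):
            segsets = segment_sets.get(species, {})
            feature_profiles[species] = comp.feature_composition(
                proteomes[species], segsets, fclass, ffilter
            )
            background_profiles[species] = comp.feature_composition(
                proteomes[species], segsets, fclass, comp.ALL
            )
        pairs = build_pairs(feature_profiles, background_profiles)
        counts = selection.per_species_match_count.get(feature_label, {})
        colors = selection.warning_color.get(feature_label, {})
        for aa in STANDARD_AMINO_ACIDS:
            pair = pairs[aa]
            for species in pair.species:
                rows.append(
                    {
                        "feature": feature_label,
                        "amino_acid": aa,
                        "species": species,
                        "feature_pct": pair.per_species_feature_pct[species],
                        "background_pct": pair.per_species_background_pct[species],
                        "match_count": counts.get(species, 0),
                        "color": colors.get(
                            species, match_count_color(counts.get(species, 0))
                        ),
                    }
                )
    return rows


def stats_rows(
    results: Mapping[str, Sequence[AminoAcidStat]],
    selection: QuerySelection,
) -> list[dict]:
    """Flatten statistics into raccoon_stats table rows."""
    rows = []
    for feature_label, stats in results.items():
        counts = selection.per_species_match_count.get(feature_label, {})
        colors = selection.warning_color.get(feature_label, {})
        color_summary = ";".join(
            f"{c}={sum(1 for v in colors.values() if v == c)}"
            for c in (GREEN, RED, YELLOW)
        )
        min_count = min(counts.values()) if counts else 0
        for st in stats:
            rows.append(
                {
                    "feature": st.feature,
                    "amino_acid": st.amino_acid,
                    "direction_of_enrichment": st.direction_of_enrichment,
                    "enrichment_sign": st.enrichment_sign,
                    "mean_fold_deviation": st.mean_fold_deviation,
                    "mean_abundance": st.mean_abundance,
                    "dispersion_feature": st.dispersion_feature,
                    "dispersion_background": st.dispersion_background,
                    "n_species": st.n_species,
                    "min_match_count": min_count,
                    "warning_color_summary": color_summary,
                }
            )
    return rows
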