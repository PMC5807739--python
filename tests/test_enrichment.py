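import itertools

import numpy as np
import pytest

from domlink import enrichment as enr
from domlink import segmentation as seg
from domlink.enrichment import (
    BACKGROUND_ENRICHED,
    FEATURE_ENRICHED,
    TIE,
    FeatureBackgroundPair,
    direction_of_enrichment,
    dispersion,
    match_count_color,
    mean_abundance,
    mean_fold_deviation,
    select_domains,
)
from domlink.seq_io import DomainAnnotation, ProteinRecord, Proteome


def _pair(feature, background, aa="R"):
    species = [f"sp{i}" for i in range(len(feature))]
    return FeatureBackgroundPair(
        amino_acid=aa,
        per_species_feature_pct=dict(zip(species, feature)),
        per_species_background_pct=dict(zip(species, background)),
    )


class TestSelectDomains:
    def test_regex_searches_descriptions_case_insensitively(self, worked_example):
        _, _, dictionary = worked_example
        sel = select_domains("DNA-binding|DNA binding", enr.REGEX, dictionary)
        assert sel.matched_names == {"HLH", "ZnF"}
        sel2 = select_domains("dna.binding", enr.REGEX, dictionary)
        assert sel2.matched_names == {"HLH", "ZnF"}

    def test_exact_name_never_matches_descriptions(self, worked_example):
        _, _, dictionary = worked_example
        sel = select_domains("PH", enr.EXACT_NAME, dictionary)
        assert sel.matched_names == {"PH"}
        # "domain" appears in several descriptions but exact mode ignores them
        assert select_domains("domain", enr.EXACT_NAME, dictionary).is_empty

    def test_no_match_yields_empty_selection_with_warning(self, worked_example, caplog):
        _, _, dictionary = worked_example
        with caplog.at_level("WARNING"):
            sel = select_domains("zzzz", enr.REGEX, dictionary)
        assert sel.is_empty
        assert "matched no dictionary entries" in caplog.text

    def test_invalid_regex_echoes_pattern(self, worked_example):
        _, _, dictionary = worked_example
        with pytest.raises(ValueError, match=r"\(unclosed"):
            select_domains("(unclosed", enr.REGEX, dictionary)

    def test_empty_query_rejected(self, worked_example):
        with pytest.raises(ValueError):
            select_domains("", enr.REGEX, worked_example[2])


class TestMatchCountColor:
    @pytest.mark.parametrize(
        "n, color",
        [
            (12, "green"),
            (11, "green"),
            (10, "red"),  # ten itself takes the conservative red
            (7, "red"),
            (6, "red"),
            (5, "yellow"),
            (3, "yellow"),
            (0, "yellow"),
        ],
    )
    def test_thresholds(self, n, color):
        assert match_count_color(n) == color

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            match_count_color(-1)


class TestDirectionOfEnrichment:
    def test_matches_exhaustive_enumeration_of_sign_patterns(self):
        """All 3^4 greater/equal/smaller patterns over 4 species."""
        for pattern in itertools.product((-1, 0, 1), repeat=4):
            feature = [5.0 + 0.5 * s for s in pattern]
            background = [5.0] * 4
            expected = sum(1 for s in pattern if s > 0) / 4
            assert direction_of_enrichment(_pair(feature, background)) == expected

    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            direction_of_enrichment(_pair([], []))


class TestMeanFoldDeviation:
    def test_equal_means_give_zero(self):
        value, _ = mean_fold_deviation(_pair([4.0, 6.0], [6.0, 4.0]))
        assert value == 0.0

    def test_doubling_gives_one(self):
        value, sign = mean_fold_deviation(_pair([10.0, 10.0], [5.0, 5.0]))
        assert value == 1.0
        assert sign == FEATURE_ENRICHED

    def test_direct_evaluation_f8_b5(self):
        value, _ = mean_fold_deviation(_pair([8.0], [5.0]))
        assert value == pytest.approx(0.6)

    def test_background_enriched_sign(self):
        value, sign = mean_fold_deviation(_pair([2.0, 2.0], [5.0, 5.0]))
        assert value == pytest.approx(0.6)
        assert sign == BACKGROUND_ENRICHED

    def test_tie_sign_at_half(self):
        _, sign = mean_fold_deviation(_pair([8.0, 2.0], [5.0, 5.0]))
        assert sign == TIE

    def test_invariant_to_common_rescaling(self):
        v1, _ = mean_fold_deviation(_pair([8.0, 4.0], [5.0, 3.0]))
        v2, _ = mean_fold_deviation(_pair([16.0, 8.0], [10.0, 6.0]))
        assert v1 == pytest.approx(v2)

    def test_zero_background_names_amino_acid(self):
        with pytest.raises(ZeroDivisionError, match="R"):
            mean_fold_deviation(_pair([1.0], [0.0], aa="R"))


class TestMeanAbundance:
    @pytest.mark.parametrize(
        "values, expected", [([4.0, 6.0], 5.0), ([7.5], 7.5), ([5, 5, 5], 5.0)]
    )
    def test_is_the_mean_feature_percentage(self, values, expected):
        assert mean_abundance(_pair(values, [1.0] * len(values))) == pytest.approx(
            expected
        )


class TestDispersion:
    def test_identical_points_give_zero(self):
        assert dispersion([(3.0, 4.0)] * 5) == 0.0

    def test_hand_computed_two_point_cloud(self):
        assert dispersion([(0.0, 0.0), (2.0, 2.0)]) == pytest.approx(4.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 2))
        assert dispersion(pts) == pytest.approx(dispersion(pts + [100.0, -40.0]))

    def test_equals_n_times_population_variance(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            pts = rng.normal(scale=3.0, size=(n, 2))
            closed_form = n * (pts[:, 0].var() + pts[:, 1].var())
            assert dispersion(pts) == pytest.approx(closed_form, rel=1e-10)

    def test_zero_points_rejected(self):
        with pytest.raises(ValueError):
            dispersion([])


def _planted_dataset():
    """Two species where family DB1 inflates K and R above every background."""
    all20 = "ACDEFGHIKLMNPQRSTVWY"
    proteomes, annotations = {}, []
    for species, db_seq in (("spX", "KKKKKRRRRR"), ("spY", "KKKRRRKKRR")):
        proteome = Proteome(species)
        seq = db_seq + all20 + all20  # DB1 domain, linker, OTHER domain
        proteome.add(ProteinRecord("p1", species, seq))
        proteomes[species] = proteome
        annotations += [
            DomainAnnotation(species, "p1", "DB1", 1, 10),
            DomainAnnotation(species, "p1", "OTHER", 31, 50),
        ]
    from domlink.seq_io import DictionaryEntry

    dictionary = {
        "DB1": DictionaryEntry("DB1", "basic DNA binding domain"),
        "OTHER": DictionaryEntry("OTHER", "unrelated fold"),
    }
    segsets = {
        s: seg.segment_proteome(proteomes[s], annotations) for s in proteomes
    }
    return proteomes, segsets, dictionary


class TestRaccoonStats:
    def test_planted_enrichment_gives_direction_one_for_k_and_r(self):
        proteomes, segsets, dictionary = _planted_dataset()
        selection = select_domains("DB1", enr.EXACT_NAME, dictionary)
        results = enr.raccoon_stats(selection, proteomes, segsets)
        by_aa = {st.amino_acid: st for st in results["selected_domain"]}
        assert by_aa["K"].direction_of_enrichment == 1.0
        assert by_aa["R"].direction_of_enrichment == 1.0
        assert by_aa["K"].enrichment_sign == FEATURE_ENRICHED

    def test_selecting_all_domains_means_feature_equals_background(self):
        proteomes, segsets, dictionary = _planted_dataset()
        selection = select_domains(".", enr.REGEX, dictionary)
        assert selection.matched_names == {"DB1", "OTHER"}
        results = enr.raccoon_stats(selection, proteomes, segsets)
        for st in results["selected_domain"] + results["selected_linker"]:
            assert st.mean_fold_deviation == pytest.approx(0.0, abs=1e-12)
            assert st.direction_of_enrichment == 0.0  # no strict winners

    def test_match_counts_and_colors_recorded_per_species(self):
        proteomes, segsets, dictionary = _planted_dataset()
        selection = select_domains("DB1", enr.EXACT_NAME, dictionary)
        enr.raccoon_stats(selection, proteomes, segsets)
        assert selection.per_species_match_count["selected_domain"] == {
            "spX": 1,
            "spY": 1,
        }
        assert selection.warning_color["selected_domain"]["spX"] == "yellow"

    def test_empty_selection_refused(self):
        proteomes, segsets, dictionary = _planted_dataset()
        selection = select_domains("zzzz", enr.REGEX, dictionary)
        with pytest.raises(ValueError, match="matched no dictionary entries"):
            enr.raccoon_stats(selection, proteomes, segsets)

    def test_selection_matching_zero_segments_refused(self):
        from domlink.seq_io import DictionaryEntry

        proteomes, segsets, dictionary = _planted_dataset()
        dictionary = dict(dictionary)
        dictionary["GHOST"] = DictionaryEntry("GHOST", "never annotated")
        selection = select_domains("GHOST", enr.EXACT_NAME, dictionary)
        with pytest.raises(ValueError, match="zero segments"):
            enr.raccoon_stats(selection, proteomes, segsets)

    def test_stats_rows_cover_both_features_times_twenty(self, worked_example, worked_segments):
        proteomes, _, dictionary = worked_example
        selection = select_domains("DNA-binding|DNA binding", enr.REGEX, dictionary)
        results = enr.raccoon_stats(selection, proteomes, worked_segments)
        rows = enr.stats_rows(results, selection)
        assert len(rows) == 40
        assert {r["feature"] for r in rows} == {"selected_domain", "selected_linker"}

    def test_dotplot_rows_carry_colors_matching_counts(self, worked_example, worked_segments):
        proteomes, _, dictionary = worked_example
        selection = select_domains("DNA-binding|DNA binding", enr.REGEX, dictionary)
        enr.raccoon_stats(selection, proteomes, worked_segments)
        rows = enr.dotplot_rows(selection, proteomes, worked_segments)
        assert len(rows) == 2 * 20 * 2  # feature x amino acid x species
        for row in rows:
            assert row["color"] == match_count_color(row["match_count"])


class TestBuildPairs:
    def test_species_with_empty_feature_dropped_from_both_sides(self, caplog):
        from domlink.composition import CompositionProfile

        def prof(species, pct_a, empty=False):
            counts = {aa: 0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
            if not empty:
                counts["A"] = 1
            total = sum(counts.values())
            return CompositionProfile(
                species=species,
                feature_class="selected_domain",
                counts=counts,
                total=total,
                percentages=None if empty else {aa: (100.0 if aa == "A" else 0.0) for aa in counts},
            )

        feature = {"spA": prof("spA", 1.0), "spB": prof("spB", 1.0, empty=True)}
        background = {"spA": prof("spA", 1.0), "spB": prof("spB", 1.0)}
        with caplog.at_level("INFO"):
            pairs = enr.build_pairs(feature, background)
        assert pairs["A"].species == ["spA"]
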