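"""The genome-count-difference representation screen and its companions."""

import numpy as np
import pandas as pd
import pytest

from gutnog.annotation import PresenceMatrix
from gutnog.io_formats import GenomeRecord, Habitat, OrthologGroupAnnotation
from gutnog.screen import (
    RepresentationStatus,
    ScreenParams,
    category_composition,
    classify_representation,
    count_representation,
    distribution_grid,
    group_by_description,
    group_presence,
    screen_matrix,
    shared_core,
)

PARAMS_23 = ScreenParams(n_gut=23, n_nongut=23, delta_min=12)


def _genomes(n_gut, n_nongut):
    return [GenomeRecord(f"gut{i:02d}", Habitat.GUT, 10) for i in range(n_gut)] + [
        GenomeRecord(f"nongut{i:02d}", Habitat.NON_GUT, 10) for i in range(n_nongut)
    ]


def _random_matrix(rng, genomes, n_features):
    frame = pd.DataFrame(
        rng.integers(0, 2, size=(len(genomes), n_features)).astype("int8"),
        index=[g.genome_id for g in genomes],
        columns=[f"f{j:03d}" for j in range(n_features)],
    )
    frame = frame.loc[:, frame.sum(axis=0) > 0]  # no all-zero columns
    return PresenceMatrix(frame)


class TestClassifyRepresentation:
    @pytest.mark.parametrize(
        "gut, nongut, status",
        [
            (23, 11, RepresentationStatus.OVERREPRESENTED),   # delta 12, upper corner
            (12, 0, RepresentationStatus.OVERREPRESENTED),    # delta 12, lower corner
            (12, 1, RepresentationStatus.NEITHER),            # delta 11
            (22, 11, RepresentationStatus.NEITHER),
            (1, 21, RepresentationStatus.UNDERREPRESENTED),   # delta -20
            (0, 12, RepresentationStatus.UNDERREPRESENTED),
            (23, 23, RepresentationStatus.NEITHER),
            (0, 0, RepresentationStatus.NEITHER),
        ],
    )
    def test_delta_rule(self, gut, nongut, status):
        record = classify_representation("f", gut, nongut, PARAMS_23)
        assert record.status is status
        assert record.delta == gut - nongut

    def test_abundance_percentages_round_half_up(self):
        record = classify_representation("f", 20, 8, PARAMS_23)
        assert record.gut_abundance_pct == 87.0   # 20/23 -> 86.956...
        assert record.nongut_abundance_pct == 34.8

    def test_counts_outside_cohort_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_representation("f", 24, 0, PARAMS_23)

    def test_features_in_eleven_or_fewer_gut_genomes_never_overrepresented(self):
        for gut in range(0, 12):
            for nongut in range(0, 24):
                record = classify_representation("f", gut, nongut, PARAMS_23)
                assert record.status is not RepresentationStatus.OVERREPRESENTED

    def test_unreachable_delta_min_rejected(self):
        with pytest.raises(ValueError, match="cohort sizes"):
            ScreenParams(n_gut=5, n_nongut=5, delta_min=6)


class TestCountRepresentation:
    def test_counts_are_per_cohort_column_sums(self):
        genomes = _genomes(3, 2)
        matrix = PresenceMatrix.from_dict(
            {
                "gut00": ["n1", "n2"],
                "gut01": ["n1"],
                "gut02": ["n1"],
                "nongut00": ["n2"],
                "nongut01": [],
            },
            genome_order=[g.genome_id for g in genomes],
        )
        assert count_representation(matrix, genomes) == [("n1", 3, 0), ("n2", 1, 1)]

    def test_empty_matrix_gives_empty_list(self):
        genomes = _genomes(1, 1)
        matrix = PresenceMatrix.from_dict({g.genome_id: [] for g in genomes})
        assert count_representation(matrix, genomes) == []

    def test_ambiguous_genome_in_matrix_rejected(self):
        genomes = [GenomeRecord("g1", Habitat.AMBIGUOUS, 10)]
        matrix = PresenceMatrix.from_dict({"g1": ["n1"]})
        with pytest.raises(ValueError, match="ambiguous"):
            count_representation(matrix, genomes)


class TestScreenProperties:
    def test_agrees_with_brute_force_recount_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n_gut, n_nongut = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            genomes = _genomes(n_gut, n_nongut)
            matrix = _random_matrix(rng, genomes, int(rng.integers(1, 21)))
            delta_min = int(rng.integers(1, max(n_gut, n_nongut) + 1))
            records = {r.feature_id: r for r in screen_matrix(matrix, genomes, delta_min=delta_min)}
            habitat = {g.genome_id: g.habitat for g in genomes}
            for feature in matrix.feature_ids:
                gut = sum(
                    int(matrix.frame.loc[g, feature])
                    for g in matrix.genome_ids
                    if habitat[g] is Habitat.GUT
                )
                nongut = sum(
                    int(matrix.frame.loc[g, feature])
                    for g in matrix.genome_ids
                    if habitat[g] is Habitat.NON_GUT
                )
                record = records[feature]
                assert (record.gut_count, record.nongut_count) == (gut, nongut)
                if gut - nongut >= delta_min:
                    assert record.status is RepresentationStatus.OVERREPRESENTED
                elif nongut - gut >= delta_min:
                    assert record.status is RepresentationStatus.UNDERREPRESENTED
                else:
                    assert record.status is RepresentationStatus.NEITHER

    def test_swapping_cohort_labels_swaps_over_and_under(self):
        rng = np.random.default_rng(7)
        genomes = _genomes(6, 6)
        matrix = _random_matrix(rng, genomes, 40)
        flipped = [
            GenomeRecord(
                g.genome_id,
                Habitat.NON_GUT if g.habitat is Habitat.GUT else Habitat.GUT,
                g.total_proteins,
            )
            for g in genomes
        ]
        original = {r.feature_id: r.status for r in screen_matrix(matrix, genomes, delta_min=3)}
        swapped = {r.feature_id: r.status for r in screen_matrix(matrix, flipped, delta_min=3)}
        swap = {
            RepresentationStatus.OVERREPRESENTED: RepresentationStatus.UNDERREPRESENTED,
            RepresentationStatus.UNDERREPRESENTED: RepresentationStatus.OVERREPRESENTED,
            RepresentationStatus.NEITHER: RepresentationStatus.NEITHER,
        }
        assert swapped == {f: swap[s] for f, s in original.items()}

    def test_permuting_genomes_within_a_cohort_changes_nothing(self):
        rng = np.random.default_rng(13)
        genomes = _genomes(5, 5)
        matrix = _random_matrix(rng, genomes, 30)
        baseline = screen_matrix(matrix, genomes, delta_min=3)
        gut_ids = [g.genome_id for g in genomes if g.habitat is Habitat.GUT]
        permuted_gut = list(rng.permutation(gut_ids))
        # permute gut rows of the matrix (same profiles, shuffled owners)
        new_order = permuted_gut + [g.genome_id for g in genomes if g.habitat is Habitat.NON_GUT]
        permuted = PresenceMatrix(matrix.frame.loc[new_order])
        assert screen_matrix(permuted, genomes, delta_min=3) == baseline

    def test_planted_differential_groups_recovered_exactly(self, default_pangenome, default_matrix):
        records = screen_matrix(default_matrix, default_pangenome.genomes)
        over = {r.feature_id for r in records if r.status is RepresentationStatus.OVERREPRESENTED}
        under = {r.feature_id for r in records if r.status is RepresentationStatus.UNDERREPRESENTED}
        assert over == set(default_pangenome.ground_truth.over)
        assert under == set(default_pangenome.ground_truth.under)


class TestGroupByDescription:
    def test_case_insensitive_normalization_and_empty_drop(self):
        annotations = [
            OrthologGroupAnnotation("n1", "Sortase B"),
            OrthologGroupAnnotation("n2", "sortase  b"),
            OrthologGroupAnnotation("n3", ""),
            OrthologGroupAnnotation("n4", "NA"),
        ]
        (group,) = group_by_description(annotations)
        assert group.member_nogs == {"n1", "n2"}

    def test_conjugation_style_shared_description_forms_one_group(self):
        nogs = ["n07070", "n11507", "n08200", "n10025", "n13178", "n26309"]
        annotations = [
            OrthologGroupAnnotation(n, "Protein involved in unidirectional conjugation")
            for n in nogs
        ]
        (group,) = group_by_description(annotations)
        assert group.member_nogs == set(nogs)

    def test_distinct_descriptions_give_singletons(self):
        annotations = [OrthologGroupAnnotation(f"n{i}", f"function {i}") for i in range(4)]
        groups = group_by_description(annotations)
        assert len(groups) == 4
        assert all(len(g.member_nogs) == 1 for g in groups)

    def test_strict_mode_distinguishes_case(self):
        annotations = [
            OrthologGroupAnnotation("n1", "Sortase B"),
            OrthologGroupAnnotation("n2", "sortase b"),
        ]
        assert len(group_by_description(annotations, strict=True)) == 2

    def test_every_described_nog_in_exactly_one_group(self, default_pangenome):
        groups = group_by_description(default_pangenome.annotations)
        seen = [n for g in groups for n in g.member_nogs]
        assert len(seen) == len(set(seen))
        described = {a.nog_id for a in default_pangenome.annotations if a.description}
        assert set(seen) == described


class TestGroupPresence:
    def test_or_semantics(self):
        genomes = _genomes(1, 1)
        matrix = PresenceMatrix.from_dict(
            {"gut00": ["n2"], "nongut00": []},
            genome_order=[g.genome_id for g in genomes],
        )
        groups = group_by_description(
            [
                OrthologGroupAnnotation("n1", "shared func"),
                OrthologGroupAnnotation("n2", "shared func"),
            ]
        )
        with pytest.warns(UserWarning, match="absent"):
            grouped = group_presence(matrix, groups)
        assert grouped.frame.loc["gut00", "shared func"] == 1
        assert grouped.frame.loc["nongut00", "shared func"] == 0

    def test_group_with_no_present_member_excluded_with_warning(self):
        matrix = PresenceMatrix.from_dict({"g1": ["n1"]})
        groups = group_by_description([OrthologGroupAnnotation("nX", "ghost function")])
        with pytest.warns(UserWarning) as caught:
            grouped = group_presence(matrix, groups)
        assert any("excluded" in str(w.message) for w in caught)
        assert grouped.feature_ids == []

    def test_empty_group_list_gives_zero_columns(self):
        matrix = PresenceMatrix.from_dict({"g1": ["n1"]})
        assert group_presence(matrix, []).shape == (1, 0)

    def test_grouped_abundances_match_published_rounding(self):
        # a group present in 20/23 gut and 8/23 non-gut genomes -> 87.0 / 34.8
        genomes = _genomes(23, 23)
        gut_carriers = [f"gut{i:02d}" for i in range(20)]
        nongut_carriers = [f"nongut{i:02d}" for i in range(8)]
        rows = {g.genome_id: [] for g in genomes}
        for gid in gut_carriers:
            rows[gid] = ["n1"]
        for gid in nongut_carriers:
            rows[gid] = ["n2"]
        matrix = PresenceMatrix.from_dict(rows, genome_order=[g.genome_id for g in genomes])
        groups = group_by_description(
            [OrthologGroupAnnotation("n1", "conjugation"), OrthologGroupAnnotation("n2", "conjugation")]
        )
        (record,) = screen_matrix(group_presence(matrix, groups), genomes)
        assert record.gut_abundance_pct == 87.0
        assert record.nongut_abundance_pct == 34.8
        assert record.status is RepresentationStatus.OVERREPRESENTED


class TestSharedCore:
    def test_all_ones_columns_only(self):
        matrix = PresenceMatrix.from_dict(
            {"g1": ["a", "c"], "g2": ["a", "b", "c"], "g3": ["a", "c", "d"]}
        )
        assert shared_core(matrix) == {"a", "c"}

    def test_no_core(self):
        matrix = PresenceMatrix.from_dict({"g1": ["a"], "g2": ["b"]})
        assert shared_core(matrix) == set()

    def test_planted_core_recovered(self, default_pangenome, default_matrix):
        assert shared_core(default_matrix) == set(default_pangenome.ground_truth.core)


class TestDistributionGrid:
    def test_singleton_exclusion(self):
        counts = [("a", 2, 0), ("b", 1, 1), ("c", 1, 0)]
        grid = distribution_grid(counts, n_gut=3, n_nongut=3, exclude_singletons=True)
        assert grid.counts[2, 0] == 1
        assert grid.counts[1, 1] == 1
        assert grid.counts[1, 0] == 0
        assert grid.total() == 2
        grid_all = distribution_grid(counts, 3, 3, exclude_singletons=False)
        assert grid_all.counts[1, 0] == 1
        assert grid_all.total() == 3

    def test_grid_conserves_feature_count(self, default_pangenome, default_matrix):
        counts = count_representation(default_matrix, default_pangenome.genomes)
        n_singletons = sum(1 for _, g, n in counts if g + n == 1)
        grid = distribution_grid(counts, 23, 23, exclude_singletons=True)
        assert grid.total() == len(counts) - n_singletons
        assert grid.counts[0, 0] == 0

    def test_log10_display_marks_empty_cells_nan(self):
        grid = distribution_grid([("a", 2, 2)], 3, 3)
        display = grid.log10_display()
        assert display[2, 2] == 0.0  # log10(1)
        assert np.isnan(display[0, 1])


class TestCategoryComposition:
    ANNS = {
        "f1": OrthologGroupAnnotation("f1", "x", frozenset("J")),
        "f2": OrthologGroupAnnotation("f2", "y", frozenset("J")),
        "f3": OrthologGroupAnnotation("f3", ""),
        "f4": OrthologGroupAnnotation("f4", "z", frozenset("C")),
        "f5": OrthologGroupAnnotation("f5", "w", frozenset("NT")),
    }

    def _records(self, feature_ids):
        return [classify_representation(f, 20, 0, PARAMS_23) for f in feature_ids]

    def test_single_category_percentages(self):
        with pytest.warns(UserWarning, match="all zero"):
            table = category_composition(self._records(["f1", "f2", "f3", "f4"]), self.ANNS)
        row = table.loc["overrepresented"]
        assert row["J"] == 50.0
        assert row["unknown"] == 25.0
        assert row["C"] == 25.0

    def test_multi_category_feature_counts_once_per_letter(self):
        with pytest.warns(UserWarning):
            table = category_composition(self._records(["f1", "f5"]), self.ANNS)
        row = table.loc["overrepresented"]
        # denominator is 3 letter assignments: J, N, T
        assert row["J"] == pytest.approx(33.3)
        assert row["N"] == pytest.approx(33.3)
        assert row["T"] == pytest.approx(33.3)

    def test_first_letter_convention(self):
        with pytest.warns(UserWarning):
            table = category_composition(
                self._records(["f5"]), self.ANNS, multi_category="first_letter"
            )
        assert table.loc["overrepresented", "N"] == 100.0

    def test_rows_sum_to_100_up_to_rounding(self):
        with pytest.warns(UserWarning):
            table = category_composition(self._records(["f1", "f2", "f4", "f5"]), self.ANNS)
        assert table.loc["overrepresented"].sum() == pytest.approx(100.0, abs=0.5)
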