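"""Screen and classification rules on hand-checked count vectors."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoexpand import (
    LABELS,
    Thresholds,
    classify,
    classify_all,
    classify_row,
    fold_change,
    representation_filter,
    screen,
)

from conftest import OUTGROUPS, make_counts, make_row
from orthoexpand import SpeciesRoles

Z13 = [0] * 13
ONES13 = [1] * 13

# module-level panel for @given tests (hypothesis forbids function fixtures)
ROLES = SpeciesRoles(
    focal="Ostrea_edulis",
    sisters=("Crassostrea_gigas", "Crassostrea_virginica"),
    outgroups=OUTGROUPS,
)


class TestFoldChange:
    @pytest.mark.parametrize(
        "numerator, denominators, expected",
        [
            (5, [5, 5, 5], 1.0),
            (41, [2, 2], 20.5),
            (41, [2, 2] + [0] * 13, 153.75),  # 41 / (4/15)
            (0, [0, 0, 0], 0.0),
        ],
    )
    def test_hand_checked_values(self, numerator, denominators, expected):
        assert fold_change(numerator, denominators) == pytest.approx(expected)

    def test_zero_mean_positive_numerator_is_infinite(self):
        assert math.isinf(fold_change(3, [0, 0]))

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1, [])

    @given(
        num=st.integers(0, 50),
        dens=st.lists(st.integers(0, 50), min_size=1, max_size=15),
        k=st.integers(1, 20),
    )
    def test_scale_invariance(self, num, dens, k):
        """Multiplying every count by k > 0 leaves the fold change unchanged."""
        before = fold_change(num, dens)
        after = fold_change(num * k, [d * k for d in dens])
        if math.isinf(before):
            assert math.isinf(after)
        else:
            assert after == pytest.approx(before)


class TestRepresentationFilter:
    @pytest.mark.parametrize(
        "focal, sisters, outgroups, expected",
        [
            # sister rescue: 3/16 represented but both sisters present
            (5, (1, 1), Z13, True),
            # exactly 8 represented (focal + 7 outgroups): 8 is not < 8
            (1, (0, 0), [1] * 7 + [0] * 6, True),
            # 8 represented counting one sister
            (1, (1, 0), [1] * 6 + [0] * 7, True),
            # 7 represented, only one sister: removed
            (1, (1, 0), [1] * 5 + [0] * 8, False),
        ],
    )
    def test_boundary_cases(self, roles, thresholds, focal, sisters,
                            outgroups, expected):
        row = make_row(roles, focal, sisters, outgroups)
        assert representation_filter(row, roles, thresholds) is expected


class TestScreen:
    def test_flat_row_fails(self, roles, thresholds):
        row = make_row(roles, 1, (1, 1), ONES13)
        passed, fc = screen(row, roles, thresholds)
        assert fc == pytest.approx(1.0)
        assert not passed

    def test_family_specific_row_passes_by_sister_rescue(self, roles, thresholds):
        row = make_row(roles, 41, (2, 2), Z13)
        passed, fc = screen(row, roles, thresholds)
        assert fc == pytest.approx(153.75)
        assert passed

    def test_threefold_over_flat_background_passes(self, roles, thresholds):
        row = make_row(roles, 3, (1, 1), ONES13)
        passed, fc = screen(row, roles, thresholds)
        assert fc == pytest.approx(3.0)
        assert passed

    @given(
        focal=st.integers(0, 30),
        sisters=st.tuples(st.integers(0, 10), st.integers(0, 10)),
        outgroups=st.lists(st.integers(0, 10), min_size=13, max_size=13),
        bump=st.integers(1, 30),
    )
    def test_monotone_in_focal_count(self, focal, sisters, outgroups, bump):
        """Raising the focal count never demotes a passing row."""
        base = make_row(ROLES, focal, sisters, outgroups)
        more = make_row(ROLES, focal + bump, sisters, outgroups)
        if screen(base, ROLES)[0]:
            assert screen(more, ROLES)[0]

    @given(
        focal=st.integers(0, 30),
        sisters=st.tuples(st.integers(0, 10), st.integers(0, 10)),
        outgroups=st.lists(st.integers(0, 10), min_size=13, max_size=13),
    )
    def test_sister_rescue_inert_when_well_represented(
        self, focal, sisters, outgroups
    ):
        """For rows at/above the representation floor the rescue clause is
        a no-op: the plain >= min_represented rule alone gives the same
        verdict."""
        row = make_row(ROLES, focal, sisters, outgroups)
        n_present = sum(1 for c in row.values() if c >= 1)
        thr = Thresholds()
        if n_present >= thr.min_represented:
            assert representation_filter(row, ROLES, thr) is True


class TestClassify:
    @pytest.mark.parametrize(
        "focal, sisters, outgroups, expected",
        [
            (41, (2, 2), Z13, "iv"),   # family-specific, strongly expanded
            (31, (1, 2), Z13, "iv"),
            (12, (8, 8), ONES13, "ii"),
            (10, (1, 1), ONES13, "iii"),
            (9, (0, 0), [1] * 8 + [0] * 5, "vi"),
            (4, (4, 4), Z13, "v"),
        ],
    )
    def test_hand_evaluated_vectors(self, roles, thresholds, focal, sisters,
                                    outgroups, expected):
        row = make_row(roles, focal, sisters, outgroups)
        assert classify(row, roles, thresholds) == expected

    def test_category_i_needs_both_ancestral_and_further(self, roles, thresholds):
        # sisters 4x the outgroup mean, focal 4x the sister mean
        row = make_row(roles, 16, (4, 4), ONES13)
        assert classify(row, roles, thresholds) == "i"

    def test_family_specific_single_sister_without_expansion_is_none(self, roles):
        # outgroups absent, one sister lost, no further expansion: not v.
        # Such a row only survives the screen under a lowered
        # representation floor (default 8 would remove it).
        row = make_row(roles, 2, (2, 0), Z13)
        thr = Thresholds(min_represented=2)
        assert classify(row, roles, thr) == "none"

    def test_row_missing_a_species_raises(self, roles, thresholds):
        row = make_row(roles, 5, (1, 1), ONES13)
        del row[roles.sisters[0]]
        with pytest.raises(KeyError, match="Crassostrea_gigas"):
            classify(row, roles, thresholds)

    def test_clade_mean_ancestral_mode_differs_on_skewed_sisters(self, roles):
        # one sister carries the whole ancestral expansion
        row = make_row(roles, 8, (13, 1), ONES13)
        per_species = classify(row, roles, Thresholds())
        clade_mean = classify(
            row, roles, Thresholds(ancestral_mode="clade_mean")
        )
        assert per_species == "iii"  # sister with 1 gene breaks "all members"
        assert clade_mean == "ii"    # mean (8+13+1)/3 exceeds 3x outgroups


class TestThresholdBoundaries:
    def test_screen_fold_exactly_at_threshold_fails(self, roles, thresholds):
        # fc = 5 / mean(2 x 15) = 2.5 exactly: ">2.5" is strict
        row = make_row(roles, 5, (2, 2), [2] * 13)
        passed, fc = screen(row, roles, thresholds)
        assert fc == pytest.approx(2.5)
        assert not passed
        assert classify(row, roles, thresholds) == "screened_out"

    def test_category_fold_exactly_at_threshold_is_not_further(
        self, roles, thresholds
    ):
        # focal/sisters = 6/2 = 3.0 exactly: not a further expansion -> v
        row = make_row(roles, 6, (2, 2), Z13)
        assert classify(row, roles, thresholds) == "v"

    def test_ancestral_boundary_is_strict(self, roles, thresholds):
        # sisters exactly 3x the outgroup mean: "all members" test fails
        at_boundary = make_row(roles, 9, (3, 3), ONES13)
        above = make_row(roles, 9, (4, 4), ONES13)
        assert classify(at_boundary, roles, thresholds) == "iii"
        assert classify(above, roles, thresholds) == "ii"


class TestClassifyAll:
    def test_flat_matrix_all_screened_out(self, roles, thresholds):
        counts = make_counts(
            roles, {f"OG{i}": (1, (1, 1), ONES13) for i in range(10)}
        )
        records, tally = classify_all(counts, roles, thresholds)
        assert tally["screened_out"] == 10
        assert all(r.category == "screened_out" for r in records)

    def test_tally_over_hand_evaluated_vectors(self, roles, thresholds):
        counts = make_counts(
            roles,
            {
                "OG_a": (41, (2, 2), Z13),
                "OG_b": (31, (1, 2), Z13),
                "OG_c": (12, (8, 8), ONES13),
                "OG_d": (10, (1, 1), ONES13),
                "OG_e": (9, (0, 0), [1] * 8 + [0] * 5),
                "OG_f": (4, (4, 4), Z13),
            },
        )
        _, tally = classify_all(counts, roles, thresholds)
        assert tally == {
            "i": 0, "ii": 1, "iii": 1, "iv": 2, "v": 1, "vi": 1,
            "none": 0, "screened_out": 0,
        }

    def test_roles_not_in_matrix_raises(self, thresholds, roles):
        counts = make_counts(roles, {"OG1": (1, (1, 1), ONES13)})
        other = SpeciesRoles("Nobody", roles.sisters, roles.outgroups)
        with pytest.raises(ValueError, match="Nobody"):
            classify_all(counts, other, thresholds)

    @given(
        vectors=st.lists(
            st.tuples(
                st.integers(0, 20),
                st.tuples(st.integers(0, 20), st.integers(0, 20)),
                st.lists(st.integers(0, 20), min_size=13, max_size=13),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=50)
    def test_every_row_gets_exactly_one_label(self, vectors):
        vectors = [v for v in vectors if v[0] + sum(v[1]) + sum(v[2]) > 0]
        if not vectors:
            return
        counts = make_counts(
            ROLES, {f"OG{i}": v for i, v in enumerate(vectors)}
        )
        records, tally = classify_all(counts, ROLES)
        assert len(records) == len(vectors)
        assert sum(tally.values()) == len(vectors)
        assert all(r.category in LABELS for r in records)

    def test_record_consistency_flags(self, roles, thresholds):
        record = classify_row(
            "OG1", make_row(roles, 41, (2, 2), Z13), roles, thresholds
        )
        assert record.passed_screen
        assert record.n_represented == 3
        assert record.fc_focal_vs_others == pytest.approx(153.75)
        assert record.fc_focal_vs_sisters == pytest.approx(20.5)
        assert math.isinf(record.fc_ostreidae_vs_outgroups)


class TestThresholdsValidation:
    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(screen_fold=0)
        with pytest.raises(ValueError):
            Thresholds(min_represented=20, total_species_expected=16)
        with pytest.raises(ValueError):
            Thresholds(ancestral_mode="majority")
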