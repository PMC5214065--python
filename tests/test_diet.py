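"""Stomach-content model: proportions, specialization, piscivory."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophont.diet import (
    DietSpecialization,
    PreyCategoryMap,
    Stomach,
    build_diet_matrix,
    individual_specialization,
    piscivory_flag,
    piscivory_table,
    population_diet,
    prevalence_piscivory,
    prey_proportions,
)
from trophont.exceptions import (
    EmptyStomachError,
    UnmappedPreyError,
    ValidationError,
)

PMAP = PreyCategoryMap.identity(
    ["chironomid", "cladoceran", "stickleback"], fish_prey=["stickleback"]
)


def simplexes(n):
    """Strategy: a simplex vector of length n (normalized positive parts)."""
    return st.lists(
        st.floats(1e-6, 1.0, allow_nan=False), min_size=n, max_size=n
    ).map(lambda v: np.array(v) / np.sum(v))


class TestPreyProportions:
    def test_normalizes_points(self):
        st_ = Stomach("f1", 40.0, {"chironomid": 30, "cladoceran": 10})
        p = prey_proportions(st_, PMAP)
        assert p["chironomid"] == pytest.approx(0.75)
        assert p["cladoceran"] == pytest.approx(0.25)
        assert p.sum() == pytest.approx(1.0)

    def test_single_fish_category(self):
        p = prey_proportions(Stomach("f1", 50.0, {"stickleback": 50}), PMAP)
        assert p["stickleback"] == 1.0

    def test_empty_stomach_signals(self):
        with pytest.raises(EmptyStomachError):
            prey_proportions(Stomach("f1", 0.0, {}), PMAP)

    def test_unmapped_label_named_in_error(self):
        with pytest.raises(UnmappedPreyError, match="mysid"):
            prey_proportions(Stomach("f1", 10.0, {"mysid": 10}), PMAP)

    def test_raw_labels_aggregate_into_standard_category(self):
        pmap = PreyCategoryMap(
            {"chir_larva": "chironomid", "chir_pupa": "chironomid", "daph": "cladoceran"}
        )
        p = prey_proportions(
            Stomach("f1", 40.0, {"chir_larva": 10, "chir_pupa": 20, "daph": 10}), pmap
        )
        assert p["chironomid"] == pytest.approx(0.75)


class TestPopulationDiet:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([[1, 0], [0, 1]], [0.5, 0.5]),
            ([[0.3, 0.7], [0.3, 0.7]], [0.3, 0.7]),
            ([[0.75, 0.25], [0.25, 0.75], [0.5, 0.5]], [0.5, 0.5]),
        ],
    )
    def test_arithmetic_mean(self, rows, expected):
        np.testing.assert_allclose(population_diet(np.array(rows)), expected)

    def test_zero_rows_error(self):
        with pytest.raises(ValidationError):
            population_diet(np.empty((0, 3)))

    def test_pooled_weighting_matches_pooled_points(self):
        # two stomachs, the second three times fuller: pooled q re-normalizes
        # raw points rather than averaging proportions
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        q = population_diet(P, method="pooled", weights=[10.0, 30.0])
        np.testing.assert_allclose(q, [0.25, 0.75])


class TestIndividualSpecialization:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.5, 0.5], [0.5, 0.5], 0.0),
            ([1.0, 0.0], [0.5, 0.5], 0.5),
            ([1.0, 0.0, 0.0], [0.2, 0.3, 0.5], 0.8),
        ],
    )
    def test_worked_examples(self, p, q, expected):
        assert individual_specialization(p, q) == pytest.approx(expected, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            individual_specialization([1.0], [0.5, 0.5])

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            individual_specialization([0.9, 0.3], [0.5, 0.5])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(p=simplexes(5), q=simplexes(5))
    def test_equals_half_l1_distance(self, p, q):
        # independent oracle: elementwise loop, no vectorized shortcut
        l1 = sum(abs(a - b) for a, b in zip(p.tolist(), q.tolist()))
        assert individual_specialization(p, q) == pytest.approx(0.5 * l1, abs=1e-12)
        assert 0.0 <= individual_specialization(p, q) <= 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=simplexes(4), q=simplexes(4), data=st.data())
    def test_permutation_invariance(self, p, q, data):
        perm = data.draw(st.permutations(range(4)))
        perm = np.array(perm)
        assert individual_specialization(p[perm], q[perm]) == pytest.approx(
            individual_specialization(p, q), abs=1e-12
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=simplexes(4), q=simplexes(4))
    def test_padding_with_shared_zero_category(self, p, q):
        p2, q2 = np.append(p, 0.0), np.append(q, 0.0)
        assert individual_specialization(p2, q2) == pytest.approx(
            individual_specialization(p, q), abs=1e-12
        )

    def test_zero_iff_equal(self, rng):
        p = rng.dirichlet(np.ones(6))
        assert individual_specialization(p, p) == 0.0
        q = p.copy()
        q[0] += 1e-6
        q[1] -= 1e-6
        assert individual_specialization(p, q) > 0.0


class TestPiscivory:
    def test_flag_true_with_any_fish_points(self):
        assert piscivory_flag(
            Stomach("f", 100.0, {"stickleback": 5, "chironomid": 95}), PMAP
        )

    def test_flag_false_without_fish(self):
        assert not piscivory_flag(Stomach("f", 100.0, {"chironomid": 100}), PMAP)

    def test_empty_stomach_false_and_excluded(self):
        tbl = piscivory_table([Stomach("f", 0.0, {})], PMAP)
        assert not tbl.loc[0, "piscivory_flag"]
        assert tbl.loc[0, "excluded"]

    @pytest.mark.parametrize(
        "flags, expected",
        [
            ([True] * 3 + [False] * 17, 15.0),
            ([False] * 10, 0.0),
            ([True] * 10, 100.0),
        ],
    )
    def test_prevalence(self, flags, expected):
        assert prevalence_piscivory(flags) == pytest.approx(expected)

    def test_prevalence_excludes_empty(self):
        flags = [True, False, False]
        excluded = [False, False, True]
        assert prevalence_piscivory(flags, excluded) == pytest.approx(50.0)
        with pytest.raises(ValidationError):
            prevalence_piscivory([False], [True])

    def test_prevalence_invariant_to_point_scaling(self):
        stomachs = [
            Stomach("a", 100.0, {"stickleback": 5, "chironomid": 95}),
            Stomach("b", 50.0, {"chironomid": 50}),
        ]
        scaled = [
            Stomach(s.fish_id, s.fullness_pct, {k: v * 0.37 for k, v in s.points.items()})
            for s in stomachs
        ]
        t1 = piscivory_table(stomachs, PMAP)
        t2 = piscivory_table(scaled, PMAP)
        assert prevalence_piscivory(
            t1["piscivory_flag"], t1["excluded"]
        ) == prevalence_piscivory(t2["piscivory_flag"], t2["excluded"])


class TestDietMatrix:
    def test_rows_sum_to_one_and_empty_excluded(self):
        stomachs = [
            Stomach("a", 40.0, {"chironomid": 30, "cladoceran": 10}),
            Stomach("b", 0.0, {}),
            Stomach("c", 60.0, {"stickleback": 60}),
        ]
        dm = build_diet_matrix(stomachs, PMAP)
        assert dm.individuals == ["a", "c"]
        assert dm.excluded == ["b"]
        np.testing.assert_allclose(dm.P.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(dm.q, dm.P.mean(axis=0))


class TestDietSpecializationEstimator:
    def test_matches_function_route(self, rng):
        P = rng.dirichlet(np.ones(5), size=30)
        est = DietSpecialization().fit(P)
        got = est.transform(P)
        q = population_diet(P)
        want = [individual_specialization(p, q) for p in P]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_transform_before_fit_raises(self, rng):
        P = rng.dirichlet(np.ones(3), size=4)
        with pytest.raises(Exception):
            DietSpecialization().transform(P)

    def test_get_set_params_roundtrip(self):
        est = DietSpecialization(method="pooled")
        assert DietSpecialization(**est.get_params()).method == "pooled"
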