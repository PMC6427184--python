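"""Belief-function core: construction, Bel/Pl, combination rules, BetP."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evireg.belief import (
    BBA,
    BeliefError,
    FrameOfDiscernment,
    TotalConflictError,
    belief,
    combine_conjunctive,
    combine_dempster,
    combine_pcr6,
    combine_pcr6_sequential,
    make_bba,
    pignistic,
    plausibility,
    vacuous_bba,
)

from _oracles import bba_to_dict, oracle_dempster, oracle_pcr6, random_bba_dict


def dict_to_bba(fod, d):
    return make_bba(fod, {tuple(sorted(k)): v for k, v in d.items()})


@pytest.fixture
def fod3():
    return FrameOfDiscernment(["a", "b", "c"])


@pytest.fixture
def fod2():
    return FrameOfDiscernment(["a", "b"])


class TestConstruction:
    def test_bayesian_bba(self, fod3):
        m = make_bba(fod3, {("a",): 0.3, ("b",): 0.3, ("c",): 0.4})
        assert m.is_bayesian()
        assert m.mass(("a",)) == 0.3

    def test_vacuous_bba(self, fod2):
        m = vacuous_bba(fod2)
        assert m.mass(("a", "b")) == 1.0
        assert not m.is_bayesian()

    @pytest.mark.parametrize(
        "assignments",
        [
            {("a",): 0.6, ("b",): 0.6},  # sums to 1.2
            {("a",): -0.1, ("b",): 1.1},  # negative mass
            {(): 0.5, ("a",): 0.5},  # empty set with mass
            {("z",): 1.0},  # not in the frame
        ],
    )
    def test_invalid_assignments_rejected(self, fod2, assignments):
        with pytest.raises(BeliefError):
            make_bba(fod2, assignments)

    def test_frame_needs_two_distinct_elements(self):
        with pytest.raises(BeliefError):
            FrameOfDiscernment(["a"])
        with pytest.raises(BeliefError):
            FrameOfDiscernment(["a", "a"])

    def test_json_round_trip(self, fod3):
        m = make_bba(fod3, {("a",): 0.5, ("a", "b"): 0.3, ("a", "b", "c"): 0.2})
        back = BBA.from_json_dict(m.to_json_dict())
        assert bba_to_dict(back) == bba_to_dict(m)


class TestBelPl:
    @pytest.fixture
    def example(self, fod3):
        # m = {{a}: 0.5, {a,b}: 0.3, Theta: 0.2}
        return make_bba(fod3, {("a",): 0.5, ("a", "b"): 0.3, ("a", "b", "c"): 0.2})

    def test_belief_enumeration(self, example):
        assert belief(example, ("a", "b", "c")) == pytest.approx(1.0)
        assert belief(example, ("a", "b")) == pytest.approx(0.8)
        assert belief(example, ("c",)) == 0.0

    def test_plausibility_enumeration(self, example):
        assert plausibility(example, ("a", "b", "c")) == pytest.approx(1.0)
        assert plausibility(example, ("b",)) == pytest.approx(0.5)

    def test_bayesian_singletons_have_bel_equal_pl(self, fod2):
        m = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        for e, v in [("a", 0.6), ("b", 0.4)]:
            assert belief(m, (e,)) == plausibility(m, (e,)) == pytest.approx(v)

    def test_subset_outside_frame_rejected(self, example):
        with pytest.raises(BeliefError):
            belief(example, ("z",))


class TestCombination:
    def test_conjunctive_worked_example(self, fod2):
        m1 = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        m2 = make_bba(fod2, {("a",): 0.7, ("b",): 0.3})
        conj = combine_conjunctive(m1, m2)
        assert conj.mass(("a",)) == pytest.approx(0.42)
        assert conj.mass(("b",)) == pytest.approx(0.12)
        assert conj.conflict == pytest.approx(0.46)

    def test_conjunctive_vacuous_is_neutral(self, fod3):
        m = make_bba(fod3, {("a",): 0.5, ("b", "c"): 0.5})
        conj = combine_conjunctive(vacuous_bba(fod3), m)
        assert conj.conflict == 0.0
        assert conj.mass(("a",)) == pytest.approx(0.5)
        assert conj.mass(("b", "c")) == pytest.approx(0.5)

    def test_dempster_worked_example(self, fod2):
        m1 = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        m2 = make_bba(fod2, {("a",): 0.7, ("b",): 0.3})
        d = combine_dempster(m1, m2)
        assert d.mass(("a",)) == pytest.approx(0.42 / 0.54, abs=1e-12)
        assert d.mass(("b",)) == pytest.approx(0.12 / 0.54, abs=1e-12)

    def test_dempster_total_conflict_raises(self, fod2):
        m1 = make_bba(fod2, {("a",): 1.0})
        m2 = make_bba(fod2, {("b",): 1.0})
        with pytest.raises(TotalConflictError):
            combine_dempster(m1, m2)

    def test_pcr6_worked_example(self, fod2):
        m1 = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        m2 = make_bba(fod2, {("a",): 0.7, ("b",): 0.3})
        p = combine_pcr6([m1, m2])
        # 0.42 + 0.6^2*0.3/0.9 + 0.7^2*0.4/1.1 and the complement
        assert p.mass(("a",)) == pytest.approx(0.7181818181, abs=1e-9)
        assert p.mass(("b",)) == pytest.approx(0.2818181818, abs=1e-9)

    def test_pcr6_total_conflict_splits_evenly(self, fod2):
        m1 = make_bba(fod2, {("a",): 1.0})
        m2 = make_bba(fod2, {("b",): 1.0})
        p = combine_pcr6([m1, m2])
        assert p.mass(("a",)) == pytest.approx(0.5)
        assert p.mass(("b",)) == pytest.approx(0.5)

    def test_pcr6_conflict_free_equals_conjunctive(self, fod3):
        m = make_bba(fod3, {("a",): 1.0})
        p = combine_pcr6([m, m])
        assert p.mass(("a",)) == pytest.approx(1.0)

    def test_pcr6_needs_two_sources(self, fod2):
        with pytest.raises(BeliefError):
            combine_pcr6([make_bba(fod2, {("a",): 1.0})])

    def test_mismatched_fods_rejected(self, fod2, fod3):
        m1 = make_bba(fod2, {("a",): 1.0})
        m2 = make_bba(fod3, {("a",): 1.0})
        with pytest.raises(BeliefError):
            combine_dempster(m1, m2)

    def test_sequential_pcr6_matches_pairwise_for_two_sources(self, fod2):
        m1 = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        m2 = make_bba(fod2, {("a",): 0.7, ("b",): 0.3})
        a = combine_pcr6([m1, m2])
        b = combine_pcr6_sequential([m1, m2])
        assert bba_to_dict(a) == pytest.approx(bba_to_dict(b))


class TestPignistic:
    def test_bayesian_fixed_point(self, fod2):
        m = make_bba(fod2, {("a",): 0.6, ("b",): 0.4})
        assert pignistic(m) == pytest.approx({"a": 0.6, "b": 0.4})

    def test_vacuous_is_uniform(self, fod3):
        assert pignistic(vacuous_bba(fod3)) == pytest.approx(
            {"a": 1 / 3, "b": 1 / 3, "c": 1 / 3}
        )

    def test_worked_example(self, fod3):
        m = make_bba(fod3, {("a",): 0.5, ("a", "b"): 0.3, ("a", "b", "c"): 0.2})
        bet = pignistic(m)
        assert bet["a"] == pytest.approx(0.71667, abs=1e-5)
        assert bet["b"] == pytest.approx(0.21667, abs=1e-5)
        assert bet["c"] == pytest.approx(0.06667, abs=1e-5)


class TestRandomizedOracleProperties:
    """Fast implementations agree with brute-force frozenset enumeration."""

    @pytest.mark.parametrize("q", [2, 3, 4])
    def test_dempster_and_pcr6_match_oracles(self, rng, q):
        elements = [f"T{i}" for i in range(q)]
        fod = FrameOfDiscernment(elements)
        for _ in range(60):
            d1 = random_bba_dict(rng, elements)
            d2 = random_bba_dict(rng, elements)
            m1, m2 = dict_to_bba(fod, d1), dict_to_bba(fod, d2)
            try:
                expect = oracle_dempster(d1, d2)
            except ZeroDivisionError:
                expect = None
            if expect is not None and not math.isclose(
                sum(expect.values()), 1.0, abs_tol=1e-9
            ):
                expect = None  # (near-)total conflict: skip Dempster here
            if expect is not None:
                got = bba_to_dict(combine_dempster(m1, m2))
                for k, v in expect.items():
                    assert got.get(k, 0.0) == pytest.approx(v, abs=1e-10)
            got = bba_to_dict(combine_pcr6([m1, m2]))
            for k, v in oracle_pcr6([d1, d2]).items():
                assert got.get(k, 0.0) == pytest.approx(v, abs=1e-10)

    def test_three_source_pcr6_matches_oracle(self, rng):
        elements = ["T0", "T1", "T2"]
        fod = FrameOfDiscernment(elements)
        for _ in range(40):
            ds = [random_bba_dict(rng, elements) for _ in range(3)]
            got = bba_to_dict(combine_pcr6([dict_to_bba(fod, d) for d in ds]))
            expect = oracle_pcr6(ds)
            for k, v in expect.items():
                assert got.get(k, 0.0) == pytest.approx(v, abs=1e-10)

    def test_dempster_commutative_and_associative(self, rng):
        elements = ["x", "y", "z"]
        fod = FrameOfDiscernment(elements)
        for _ in range(30):
            ms = [
                dict_to_bba(fod, random_bba_dict(rng, elements, compound=True))
                for _ in range(3)
            ]
            try:
                ab = bba_to_dict(combine_dempster(ms[0], ms[1]))
            except TotalConflictError:
                continue
            ba = bba_to_dict(combine_dempster(ms[1], ms[0]))
            assert ab == pytest.approx(ba, abs=1e-12)
            try:
                left = bba_to_dict(
                    combine_dempster(combine_dempster(ms[0], ms[1]), ms[2])
                )
                right = bba_to_dict(
                    combine_dempster(ms[0], combine_dempster(ms[1], ms[2]))
                )
            except TotalConflictError:
                continue
            for k in set(left) | set(right):
                assert left.get(k, 0.0) == pytest.approx(right.get(k, 0.0), abs=1e-9)

    def test_bayesian_inputs_give_bayesian_outputs(self, rng):
        elements = ["x", "y", "z"]
        fod = FrameOfDiscernment(elements)
        for _ in range(20):
            m1 = dict_to_bba(fod, random_bba_dict(rng, elements, compound=False))
            m2 = dict_to_bba(fod, random_bba_dict(rng, elements, compound=False))
            assert combine_pcr6([m1, m2]).is_bayesian()
            try:
                assert combine_dempster(m1, m2).is_bayesian()
            except TotalConflictError:
                pass


@given(
    masses=st.lists(
        st.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=7
    ),
    data=st.data(),
)
def test_mass_conservation_and_pl_dominates_bel(masses, data):
    """Pl >= Bel on random subsets; combination outputs stay normalized."""
    elements = ["a", "b", "c"]
    fod = FrameOfDiscernment(elements)
    import itertools as it

    pool = [
        tuple(c)
        for r in range(1, 4)
        for c in it.combinations(elements, r)
    ]
    idx = data.draw(
        st.lists(
            st.sampled_from(range(len(pool))),
            min_size=len(masses),
            max_size=len(masses),
            unique=True,
        )
    )
    total = sum(masses)
    m = make_bba(fod, {pool[i]: v / total for i, v in zip(idx, masses)})
    subset = data.draw(st.sampled_from(pool))
    assert plausibility(m, subset) >= belief(m, subset) - 1e-12
    assert belief(m, elements) == pytest.approx(1.0, abs=1e-9)
    p = combine_pcr6([m, m])
    assert sum(p.masses.values()) == pytest.approx(1.0, abs=1e-9)
    d = combine_dempster(m, m)
    assert sum(d.masses.values()) == pytest.approx(1.0, abs=1e-9)
    assert d.mass(()) == 0.0


@pytest.fixture
def rng():
    return np.random.default_rng(987)
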