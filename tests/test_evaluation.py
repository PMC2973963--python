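import numpy as np
import pytest

from epiensemble.evaluate import (
    FaultTable,
    IdentificationOutcome,
    RankedCallSet,
    complementarity,
    complementarity_table,
    fault_table,
    fault_table_from_marginals,
    fdr_at,
    fdr_tpr_curve,
    joint_power_pair,
    joint_power_triple,
    power,
    read_outcomes,
    success_from_calls,
    tpr_at,
    write_outcomes,
)
from epiensemble.ranking import CombinationScore


def outcome(bits, name="X"):
    return IdentificationOutcome(name, np.array(bits, dtype=bool))


def callset(ranked_pairs, truth=("s1", "s2"), n=30):
    """ranked_pairs: list of (combination, count); ranks assigned densely."""
    calls = []
    rank = 0
    prev = None
    for combo, count in sorted(ranked_pairs, key=lambda x: -x[1]):
        if count != prev:
            rank += 1
            prev = count
        calls.append(
            CombinationScore(tuple(sorted(combo)), count, count / n, rank, rank)
        )
    return RankedCallSet(tuple(calls), truth)


class TestPower:
    @pytest.mark.parametrize(
        "bits,expected",
        [([1] * 99 + [0], 99.0), ([0] * 10, 0.0), ([1] * 10, 100.0)],
    )
    def test_power_is_the_success_percentage(self, bits, expected):
        assert power(outcome(bits)) == pytest.approx(expected)

    def test_success_requires_true_pair_at_top_rank(self):
        top = callset([(("s1", "s2"), 28), (("s3", "s4"), 10)])
        assert success_from_calls(top)
        second = callset([(("s3", "s4"), 28), (("s1", "s2"), 10)])
        assert not success_from_calls(second)

    def test_rank_one_tie_containing_truth_counts_as_success(self):
        tied = callset([(("s1", "s2"), 20), (("s3", "s4"), 20)])
        assert success_from_calls(tied)


class TestFdrTpr:
    def test_only_truth_accepted_gives_zero_fdr(self):
        calls = [callset([(("s1", "s2"), 29)])]
        assert fdr_at(calls, 1, "rank") == 0.0

    def test_one_true_three_false_gives_three_quarters(self):
        calls = [
            callset(
                [(("s1", "s2"), 20), (("a", "b"), 20), (("c", "d"), 20), (("e", "f"), 20)]
            )
        ]
        assert fdr_at(calls, 1, "rank") == pytest.approx(0.75)

    def test_nothing_accepted_is_zero_by_convention(self):
        calls = [callset([(("s1", "s2"), 10)])]
        assert fdr_at(calls, 0.9, "frequency") == 0.0

    def test_tpr_at_rank_one_equals_power(self):
        replicates = [
            callset([(("s1", "s2"), 25), (("a", "b"), 5)]),
            callset([(("a", "b"), 25), (("s1", "s2"), 5)]),
            callset([(("s1", "s2"), 30)]),
        ]
        successes = [success_from_calls(c) for c in replicates]
        study_power = power(IdentificationOutcome("GE", np.array(successes)))
        assert tpr_at(replicates, 1, "rank") == pytest.approx(study_power / 100.0)

    def test_curves_are_monotone_in_the_cutoff(self):
        rng = np.random.default_rng(0)
        replicates = []
        for _ in range(10):
            pairs = [(("s1", "s2"), int(rng.integers(1, 30)))] + [
                ((f"a{i}", f"b{i}"), int(rng.integers(1, 30))) for i in range(5)
            ]
            replicates.append(callset(pairs))
        curve = fdr_tpr_curve(replicates, np.linspace(1.0, 0.0, 11), "frequency")
        tprs = [row[2] for row in curve]
        assert all(b >= a for a, b in zip(tprs, tprs[1:]))  # looser cutoff, more hits
        ranks = fdr_tpr_curve(replicates, range(1, 11), "rank")
        rank_tprs = [row[2] for row in ranks]
        assert all(b >= a for a, b in zip(rank_tprs, rank_tprs[1:]))


class TestFaultTables:
    def test_identical_outcomes_have_no_single_faults(self):
        a = outcome([1, 0, 1, 0])
        ft = fault_table(a, outcome([1, 0, 1, 0], "Y"))
        assert ft.single_fault == 0 and ft.ss == 2 and ft.ff == 2

    def test_complementary_outcomes_never_double_fault(self):
        ft = fault_table(outcome([1, 0, 1, 0]), outcome([0, 1, 0, 1], "Y"))
        assert ft.ff == 0 and ft.single_fault == 4

    def test_always_failing_pair(self):
        ft = fault_table(outcome([0] * 5), outcome([0] * 5, "Y"))
        assert ft.ff == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fault_table(outcome([1, 0]), outcome([1], "Y"))

    def test_reconstruction_from_marginals(self):
        ft = fault_table_from_marginals(80, 75, 84, 100)
        assert (ft.ss, ft.sf, ft.fs, ft.ff) == (71, 9, 4, 16)
        ft = fault_table_from_marginals(99, 99, 100, 100)
        assert (ft.ss, ft.sf, ft.fs, ft.ff) == (98, 1, 1, 0)

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            fault_table_from_marginals(50, 50, 40, 100)

    def test_reconstruction_matches_direct_tabulation(self):
        rng = np.random.default_rng(1)
        a = outcome(rng.integers(0, 2, 100))
        b = outcome(rng.integers(0, 2, 100), "Y")
        direct = fault_table(a, b)
        union = 100 - direct.ff
        rebuilt = fault_table_from_marginals(a.n_success, b.n_success, union, 100)
        assert rebuilt == direct


class TestComplementarity:
    def test_partial_overlap_example(self):
        ft = FaultTable(ss=71, sf=9, fs=4, ff=16)
        assert round(complementarity(ft), 3) == 0.448

    def test_no_shared_failures_is_full_complementarity(self):
        assert complementarity(FaultTable(10, 3, 2, 0)) == 1.0

    def test_nested_successes_have_none(self):
        assert complementarity(FaultTable(10, 0, 0, 5)) == 0.0

    def test_two_perfect_detectors_are_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            complementarity(FaultTable(10, 0, 0, 0))

    @pytest.mark.parametrize(
        "ff,expected", [(16, 84.0), (0, 100.0), (100, 0.0)]
    )
    def test_joint_power_counts_either_success(self, ff, expected):
        ft = FaultTable(ss=100 - ff, sf=0, fs=0, ff=ff)
        assert joint_power_pair(ft) == pytest.approx(expected)

    def test_joint_power_dominates_both_marginals(self):
        rng = np.random.default_rng(2)
        a = outcome(rng.integers(0, 2, 50))
        b = outcome(rng.integers(0, 2, 50), "Y")
        jp = joint_power_pair(fault_table(a, b))
        assert jp >= max(power(a), power(b))

    def test_triple_joint_power(self):
        a = outcome([1, 0, 0, 0])
        b = outcome([0, 1, 0, 0], "Y")
        c = outcome([0, 0, 1, 0], "Z")
        assert joint_power_triple(a, b, c) == pytest.approx(75.0)
        assert joint_power_triple(a, a, a) == power(a)
        assert joint_power_triple(
            a, b, outcome([0, 0, 1, 1], "Z")
        ) == pytest.approx(100.0)

    def test_triple_dominates_pairwise_joint(self):
        rng = np.random.default_rng(3)
        xs = [outcome(rng.integers(0, 2, 60), n) for n in "XYZ"]
        triple = joint_power_triple(*xs)
        for i in range(3):
            for j in range(i + 1, 3):
                assert triple >= joint_power_pair(fault_table(xs[i], xs[j]))


# Printed per-condition success percentages of the three detectors (GE, PIA,
# MDR) over 100 replicates, with each pair's joint power and complementarity
# degree.  One cell (condition balanced_200_0.2_100, GE+MDR, printed 0.923)
# is arithmetically inconsistent with its own marginals and is excluded.
STUDY_TABLE = {
    "balanced_200_0.2_20": ((99, 97, 99), ((1.000, 100), (1.000, 100), (0.667, 99))),
    "balanced_200_0.1_20": ((80, 75, 81), ((0.448, 84), (0.556, 88), (0.240, 81))),
    "balanced_200_0.05_20": ((45, 43, 43), ((0.303, 54), (0.303, 54), (0.068, 45))),
    "balanced_200_0.2_100": ((95, 93, 93), ((1.000, 100), (None, 99), (0.444, 95))),
    "balanced_200_0.1_100": ((45, 49, 51), ((0.441, 62), (0.400, 61), (0.148, 54))),
    "balanced_200_0.05_100": ((17, 19, 21), ((0.093, 22), (0.116, 24), (0.025, 21))),
    "imbalanced_200_0.2_20": ((92, 90, 95), ((0.714, 96), (0.818, 98), (0.750, 97))),
    "imbalanced_200_0.1_20": ((59, 45, 62), ((0.567, 71), (0.481, 73), (0.475, 68))),
    "imbalanced_200_0.05_20": ((32, 24, 27), ((0.286, 40), (0.301, 42), (0.287, 38))),
}
PAIRS = ((0, 1), (0, 2), (1, 2))


@pytest.mark.parametrize("condition", sorted(STUDY_TABLE))
def test_complementarity_regression_against_study_table(condition):
    """Every arithmetically determined CD cell is reproduced to 3 decimals."""
    (powers, pair_cells) = STUDY_TABLE[condition]
    for (i, j), (cd_expected, joint) in zip(PAIRS, pair_cells):
        ft = fault_table_from_marginals(powers[i], powers[j], joint, 100)
        if cd_expected is None:
            continue
        assert round(complementarity(ft), 3) == pytest.approx(cd_expected)


class TestOutcomeIO:
    def test_roundtrip_and_pairwise_table(self, tmp_path):
        rng = np.random.default_rng(5)
        outs = [
            IdentificationOutcome(name, rng.integers(0, 2, 20).astype(bool))
            for name in ("GE", "PIA", "MDR")
        ]
        path = tmp_path / "outcomes.tsv"
        write_outcomes(outs, path)
        read = read_outcomes(path)
        assert set(read) == {"GE", "PIA", "MDR"}
        for o in outs:
            assert (read[o.algorithm].successes == o.successes).all()
        rows = complementarity_table(outs)
        assert [r["pair"] for r in rows] == ["GE+PIA", "GE+MDR", "PIA+MDR"]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n")
        with pytest.raises(ValueError, match="columns"):
            read_outcomes(path)
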