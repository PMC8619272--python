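"""Experiment table fixture, replicate reconstruction, splitting, CSV I/O."""

import itertools

import numpy as np
import pytest

from disinfopt.dataset import (
    AmbiguousReconstructionError,
    NoSolutionError,
    ReplicateObservation,
    Treatment,
    TreatmentSummary,
    load_table1,
    packaged_csv_path,
    read_experiment_csv,
    reconstruct_replicates,
    replicate_mean_se,
    split_train_test,
    write_experiment_csv,
)


def brute_force_multisets(mean, se, n_reps=3, seeds=5):
    """Independent oracle: scan every replicate multiset for a (mean, SE) match."""
    levels = [100.0 * k / seeds for k in range(seeds + 1)]
    hits = []
    for combo in itertools.combinations_with_replacement(levels, n_reps):
        m = np.mean(combo)
        s = np.std(combo, ddof=1) / np.sqrt(n_reps)
        if abs(m - mean) <= 0.05 and abs(s - se) <= 0.005:
            hits.append(combo)
    return hits


class TestTreatment:
    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            Treatment(-1, 0, 0)
        with pytest.raises(ValueError):
            Treatment(0, float("nan"), 0)

    def test_summary_bounds(self):
        with pytest.raises(ValueError):
            TreatmentSummary(Treatment(0, 0, 0), 101.0, 0.0)
        with pytest.raises(ValueError):
            TreatmentSummary(Treatment(0, 0, 0), 50.0, -1.0)


class TestTable1:
    def test_has_19_unique_treatments(self, table1):
        assert len(table1) == 19
        assert len({s.treatment for s in table1}) == 19

    def test_control_and_cleared_rows(self, table1):
        by_t = {s.treatment: s for s in table1}
        control = by_t[Treatment(0, 0, 0)]
        assert (control.mean_contamination, control.se_contamination) == (100.0, 0.0)
        cleared = by_t[Treatment(5, 0, 15)]
        assert (cleared.mean_contamination, cleared.se_contamination) == (0.0, 0.0)

    def test_packaged_csv_matches_fixture(self, table1):
        table_csv = read_experiment_csv(packaged_csv_path())
        assert table_csv.to_frame().equals(table1.to_frame())


class TestReconstruction:
    @pytest.mark.parametrize(
        "mean, se, expected",
        [
            (100.0, 0.00, (100.0, 100.0, 100.0)),
            (53.3, 17.64, (20.0, 60.0, 80.0)),
            (80.0, 11.55, (60.0, 80.0, 100.0)),
            (6.7, 6.67, (0.0, 0.0, 20.0)),
        ],
    )
    def test_known_multisets(self, mean, se, expected):
        summary = TreatmentSummary(Treatment(1, 2, 3), mean, se)
        got = tuple(sorted(r.contamination for r in reconstruct_replicates(summary)))
        assert got == expected
        # the independent exhaustive scan agrees and finds nothing else
        assert brute_force_multisets(mean, se) == [expected]

    def test_all_rows_unique_and_round_trip(self, table1):
        """Every printed (mean, SE) inverts uniquely and reproduces itself."""
        for summary in table1:
            reps = reconstruct_replicates(summary)
            values = [r.contamination for r in reps]
            mean, se = replicate_mean_se(values)
            assert round(mean, 1) == summary.mean_contamination
            assert round(se, 2) == summary.se_contamination
            assert [tuple(sorted(values))] == brute_force_multisets(
                summary.mean_contamination, summary.se_contamination
            )

    def test_no_solution_raises(self):
        with pytest.raises(NoSolutionError):
            reconstruct_replicates(TreatmentSummary(Treatment(0, 0, 0), 50.0, 0.01))

    def test_ambiguous_reports_candidates(self):
        # a (mean, SE) pair engineered to match several multisets via a huge tolerance
        summary = TreatmentSummary(Treatment(0, 0, 0), 50.0, 10.0)
        with pytest.raises(AmbiguousReconstructionError) as err:
            reconstruct_replicates(summary, mean_tol=50.0, se_tol=50.0)
        assert len(err.value.candidates) > 1

    def test_expand_counts_and_error_names_treatment(self, table1, replicates57):
        assert len(replicates57) == 19 * 3
        by_t = {}
        for r in replicates57:
            by_t.setdefault(r.treatment, []).append(r.contamination)
        assert by_t[Treatment(0, 0, 0)] == [100.0, 100.0, 100.0]
        mean, _ = replicate_mean_se(by_t[Treatment(5, 0, 5)])
        assert round(mean, 1) == 53.3


class TestSplit:
    def test_partition_over_many_seeds(self, replicates57):
        for seed in range(100):
            train, test = split_train_test(replicates57, 0.2, seed)
            assert len(train) + len(test) == 57
            assert 11 <= len(test) <= 12
            merged = sorted((id(o) for o in train + test))
            assert merged == sorted(id(o) for o in replicates57)

    def test_deterministic_and_stratified(self, replicates57):
        a = split_train_test(replicates57, 0.2, 7)
        b = split_train_test(replicates57, 0.2, 7)
        assert [o.contamination for o in a[0]] == [o.contamination for o in b[0]]
        train, _ = a
        assert {o.treatment for o in train} == {o.treatment for o in replicates57}

    def test_extreme_fraction_keeps_all_treatments_in_train(self, replicates57):
        train, _ = split_train_test(replicates57, 0.99, 0)
        assert {o.treatment for o in train} == {o.treatment for o in replicates57}

    def test_invalid_fraction(self, replicates57):
        for frac in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                split_train_test(replicates57, frac, 0)


class TestCsv:
    def test_round_trip(self, table1, tmp_path):
        path = tmp_path / "t.csv"
        write_experiment_csv(table1, path)
        again = read_experiment_csv(path)
        assert again.to_frame().equals(table1.to_frame())

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("naocl,h2o2,time,mean\n0,0,0,100\n")
        with pytest.raises(ValueError, match="se"):
            read_experiment_csv(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("naocl,h2o2,time,mean,se\n0,zero,0,100,0\n")
        with pytest.raises(ValueError, match="h2o2"):
            read_experiment_csv(path)

    def test_negative_concentration_row_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("naocl,h2o2,time,mean,se\n0,0,0,100,0\n-5,0,0,50,0\n")
        with pytest.raises(ValueError, match="row 1"):
            read_experiment_csv(path)

    def test_duplicate_treatment_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("naocl,h2o2,time,mean,se\n0,0,0,100,0\n0,0,0,90,0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_experiment_csv(path)


def test_replicate_observation_holds_lattice_values(replicates57):
    assert all(r.contamination in {0.0, 20.0, 40.0, 60.0, 80.0, 100.0}
               for r in replicates57)
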