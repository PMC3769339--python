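"""Visit-log reduction, HIGH/LOW splitting, pooling and CSV round trips."""

import numpy as np
import pytest

from nmweber.choice_data import (
    ConditionSpec,
    PerformanceRecord,
    VisitRecord,
    discrimination_performance,
    pool_performance,
    read_performance_csv,
    read_visit_csv,
    split_high_low,
    write_performance_csv,
    write_visit_csv,
)
from nmweber.exceptions import (
    ClassificationError,
    DomainError,
    EmptyDataError,
    FormatError,
    PoolingError,
)


def make_visits(n_high, n_total, session="s1", phase="choice", start_t=0.0,
                higher_role="test"):
    other = "standard" if higher_role == "test" else "test"
    visits = []
    for k in range(n_total):
        role = higher_role if k < n_high else other
        side = "left" if role == "test" else "right"
        visits.append(VisitRecord(start_t + k, "bat1", session, phase, role, side))
    return visits


@pytest.fixture
def condition():
    return ConditionSpec(sequence_index=3, test_conc=25.0, standard_conc=20.0)


class TestDiscriminationPerformance:
    def test_counts_pooled_over_presentations(self, condition):
        visits = make_visits(70, 100, "s1") + make_visits(50, 100, "s2", start_t=200)
        rec = discrimination_performance(visits, condition)
        assert (rec.n_high, rec.n_total) == (120, 200)
        assert rec.performance == pytest.approx(0.60)
        assert (rec.x, rec.a) == (25.0, 20.0)

    def test_only_first_hundred_choice_visits_count(self, condition):
        base = make_visits(60, 100, "s1")
        # everything after the first 100 goes to the lower option
        extra = make_visits(0, 80, "s1", start_t=500)
        assert discrimination_performance(base + extra, condition) == \
            discrimination_performance(base, condition)

    def test_alternation_phase_never_counts(self, condition):
        visits = make_visits(50, 100, "s1", phase="alternation")
        with pytest.raises(EmptyDataError, match="choice-phase"):
            discrimination_performance(visits, condition)

    def test_order_invariance_within_counted_window(self, condition, rng):
        visits = make_visits(60, 100, "s1")
        shuffled = list(visits)
        rng.shuffle(shuffled)
        # permuting timestamps within the counted window changes nothing
        assert discrimination_performance(shuffled, condition) == \
            discrimination_performance(visits, condition)

    def test_shortfall_recorded_not_fatal(self, condition):
        rec = discrimination_performance(make_visits(30, 40, "s1"), condition)
        assert rec.n_total == 40
        assert rec.meta["shortfall"] == 60

    def test_equal_concentration_condition_measures_bias_on_test_feeder(self):
        cond = ConditionSpec(sequence_index=10, test_conc=20.0, standard_conc=20.0)
        rec = discrimination_performance(make_visits(55, 100), cond)
        assert rec.performance == pytest.approx(0.55)
        assert rec.x == rec.a == 20.0

    def test_lower_concentration_test_feeder_counts_standard_visits(self):
        cond = ConditionSpec(sequence_index=1, test_conc=12.5, standard_conc=20.0)
        visits = make_visits(60, 100, higher_role="standard")
        rec = discrimination_performance(visits, cond)
        assert rec.n_high == 60
        assert (rec.x, rec.a) == (20.0, 12.5)

    def test_mixed_individuals_rejected(self, condition):
        visits = make_visits(10, 20)
        visits.append(VisitRecord(99.0, "bat2", "s1", "choice", "test", "left"))
        with pytest.raises(DomainError, match="one individual"):
            discrimination_performance(visits, condition)


class TestSplitHighLow:
    def test_design_splits_eight_and_eight(self, table1_group1):
        records = [
            PerformanceRecord(x=max(c, 20.0), a=min(c, 20.0), n_high=60, n_total=100)
            for c, _ in table1_group1
        ]
        low, high = split_high_low(records, 20.0)
        assert (len(low), len(high)) == (8, 8)

    def test_equal_concentration_record_in_both_sets(self):
        rec = PerformanceRecord(x=20.0, a=20.0, n_high=50, n_total=100)
        low, high = split_high_low([rec], 20.0)
        assert low == [rec] and high == [rec]

    def test_all_above_standard(self):
        recs = [PerformanceRecord(x=c, a=20.0, n_high=60, n_total=100) for c in (25.0, 30.0)]
        low, high = split_high_low(recs, 20.0)
        assert low == [] and high == recs

    def test_outputs_cover_input_overlap_only_at_standard(self, table1_group1):
        records = [
            PerformanceRecord(x=max(c, 20.0), a=min(c, 20.0), n_high=60, n_total=100)
            for c, _ in table1_group1
        ]
        low, high = split_high_low(records, 20.0)
        assert set(map(id, low)) | set(map(id, high)) == set(map(id, records))
        overlap = set(map(id, low)) & set(map(id, high))
        assert all(r.x == r.a for r in records if id(r) in overlap)

    def test_foreign_record_rejected(self):
        with pytest.raises(ClassificationError, match="30.0"):
            split_high_low([PerformanceRecord(x=30.0, a=25.0, n_high=60, n_total=100)], 20.0)


class TestPooling:
    def test_visit_weighted_mean(self):
        a = PerformanceRecord(x=30.0, a=20.0, n_high=60, n_total=100)
        b = PerformanceRecord(x=30.0, a=20.0, n_high=80, n_total=100)
        pooled = pool_performance({"i1": [a], "i2": [b]})
        assert len(pooled) == 1
        assert pooled[0].performance == pytest.approx(0.7)
        assert pooled[0].n_total == 200

    def test_total_conservation(self, simulated_records):
        half = len(simulated_records) // 3
        sets = {
            "i1": simulated_records[:half],
            "i2": simulated_records[:half],
        }
        pooled = pool_performance(sets)
        assert sum(r.n_total for r in pooled) == sum(
            r.n_total for rs in sets.values() for r in rs
        )

    def test_single_individual_idempotent(self):
        recs = [PerformanceRecord(x=30.0, a=20.0, n_high=60, n_total=100)]
        pooled = pool_performance({"i1": recs})
        assert [(r.x, r.a, r.n_high, r.n_total) for r in pooled] == [
            (30.0, 20.0, 60, 100)
        ]

    def test_inconsistent_conditions_rejected(self):
        with pytest.raises(PoolingError, match="lacks conditions"):
            pool_performance(
                {
                    "i1": [PerformanceRecord(x=30.0, a=20.0, n_high=6, n_total=10)],
                    "i2": [PerformanceRecord(x=25.0, a=20.0, n_high=6, n_total=10)],
                }
            )

    def test_pooling_heterogeneous_thresholds_attenuates_slope(self):
        """Averaging observers with different thresholds flattens the curve."""
        from nmweber import SimulationScenario, fit_nls
        from nmweber.psychometric import PsychometricParams
        from nmweber.synthetic_data import simulate_performance

        truth = PsychometricParams(m=0.25, s=4.0, lapse=0.05, beta=1.0)
        scenario = SimulationScenario(
            params=truth, n_individuals=8, seed=11, n_choice_visits=500,
            heterogeneity={"log_m_sd": 0.6},
        )
        records = simulate_performance(scenario)
        per_ind: dict[str, list[PerformanceRecord]] = {}
        for rec in records:
            per_ind.setdefault(rec.meta["individual_id"], []).append(rec)
        slopes = [fit_nls(rs, beta_mode=1.0).params.s for rs in per_ind.values()]
        pooled_slope = fit_nls(pool_performance(per_ind), beta_mode=1.0).params.s
        assert pooled_slope <= np.mean(slopes)


class TestCsvRoundTrips:
    def test_performance_round_trip(self, tmp_path, rng):
        records = [
            PerformanceRecord(
                x=float(x), a=float(a), n_high=int(h), n_total=int(t)
            )
            for x, a, h, t in zip(
                rng.uniform(21, 60, 100),
                rng.uniform(1, 20, 100),
                rng.integers(0, 100, 100),
                rng.integers(100, 200, 100),
            )
        ]
        path = tmp_path / "perf.csv"
        write_performance_csv(records, path)
        assert read_performance_csv(path) == records

    def test_minimal_file(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("x_conc,a_conc,n_high,n_total\n25,20,120,200\n")
        (rec,) = read_performance_csv(path)
        assert rec == PerformanceRecord(x=25.0, a=20.0, n_high=120, n_total=200)

    def test_invalid_counts_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x_conc,a_conc,n_high,n_total\n25,20,120,200\n25,20,300,200\n")
        with pytest.raises(FormatError, match="line 3"):
            read_performance_csv(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("x_conc,a_conc,n_high\n25,20,120\n")
        with pytest.raises(FormatError, match="n_total"):
            read_performance_csv(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("x_conc,a_conc,n_high,n_total\n25,twenty,120,200\n")
        with pytest.raises(FormatError, match="line 2"):
            read_performance_csv(path)

    def test_visit_round_trip_and_column_mapping(self, tmp_path):
        visits = make_visits(3, 5)
        path = tmp_path / "visits.csv"
        write_visit_csv(visits, path)
        assert read_visit_csv(path) == visits
        # foreign dialect adapted through a column mapping
        foreign = tmp_path / "foreign.csv"
        foreign.write_text(
            "time,bat,night,stage,role,side\n0,bat1,s1,choice,test,left\n"
        )
        (v,) = read_visit_csv(
            foreign,
            column_mapping={
                "timestamp": "time", "individual_id": "bat", "session_id": "night",
                "phase": "stage", "feeder_role": "role", "feeder_side": "side",
            },
        )
        assert v.individual_id == "bat1" and v.phase == "choice"

    def test_unknown_phase_rejected(self, tmp_path):
        path = tmp_path / "phase.csv"
        path.write_text(
            "timestamp,individual_id,session_id,phase,feeder_role,feeder_side\n"
            "0,bat1,s1,warmup,test,left\n"
        )
        with pytest.raises(FormatError, match="warmup"):
            read_visit_csv(path)
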