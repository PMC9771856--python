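import numpy as np
import pytest

from polyrep.band_model import SegmentKind, SpeedMode, build_paper_int
from polyrep.fork_dynamics import (
    AXIAL_SPEED_FACTORS,
    completion_time,
    edu_pulse_intervals,
    fork_position_stepper,
    make_fork,
    make_record,
    segment_speeds,
    simulate,
)
from polyrep.initiation_scenarios import InitiationScenario, OriginEvent

ORACLE_TOL_KBP = 2e-3  # one dt=1e-3 step at the 2 kbp/min top speed


def record_at(model, g, activation=0.0, speed=2.0, cid=0):
    origin = OriginEvent(cid, g, activation)
    return make_record(model, origin, segment_speeds(model, speed), speed)


class TestSegmentSpeeds:
    def test_dna_mode_constant(self, paper_model):
        assert np.all(segment_speeds(paper_model, 2.0) == 2.0)

    def test_stated_mode_axial_factors(self, paper_model_stated):
        v = segment_speeds(paper_model_stated, 2.0)
        m = paper_model_stated
        # axial speed per segment should follow the printed 1:5:20:50 ratios
        for k, s in enumerate(m.segments):
            axial = v[k] / s.density
            assert axial == pytest.approx(AXIAL_SPEED_FACTORS[s.kind], rel=1e-12)

    def test_invalid_speed(self, paper_model):
        with pytest.raises(ValueError):
            segment_speeds(paper_model, 0.0)


class TestForkPosition:
    def test_dna_2kbp_per_min(self, paper_model):
        # origin at the left edge of the first interband
        rec = record_at(paper_model, 100.0)
        assert rec.right_fork.position(1.0) == pytest.approx(102.0, abs=1e-12)

    def test_zero_elapsed_is_identity(self, paper_model):
        rec = record_at(paper_model, 123.456, activation=2.5)
        assert rec.left_fork.position(2.5) == 123.456
        assert rec.right_fork.position(2.5) == 123.456

    def test_before_activation_errors(self, paper_model):
        rec = record_at(paper_model, 110.0, activation=5.0)
        with pytest.raises(ValueError):
            rec.left_fork.position(4.9)

    def test_stated_interband_axial_speed(self, paper_model_stated):
        m = paper_model_stated
        rec = record_at(m, 100.0)  # left edge of first interband
        x0 = m.genomic_to_axial(rec.right_fork.position(0.0))
        x1 = m.genomic_to_axial(rec.right_fork.position(0.5))
        assert x1 - x0 == pytest.approx(0.5, abs=1e-12)  # V = 1 width/min

    def test_clamped_at_model_end(self, paper_model):
        rec = record_at(paper_model, 100.0)
        assert rec.left_fork.position(1e6) == 0.0
        assert rec.right_fork.position(1e6) == paper_model.total_genomic_kbp

    def test_stop_time_dna(self, paper_model):
        rec = record_at(paper_model, 100.0)
        assert rec.left_fork.stop_time == pytest.approx(50.0)  # 100 kbp / 2
        assert rec.right_fork.stop_time == pytest.approx(76.0)  # 152 kbp / 2

    @pytest.mark.parametrize("mode", [SpeedMode.DNA, SpeedMode.STATED])
    def test_oracle_equivalence_500_cases(self, mode):
        model = build_paper_int(100.0, mode)
        rng = np.random.default_rng(42)
        n = 500
        origins = rng.uniform(0.5, model.total_genomic_kbp - 0.5, n)
        activations = rng.uniform(0.0, 10.0, n)
        directions = rng.choice([-1, 1], n)
        ts = activations + rng.uniform(0.0, 25.0, n)
        expected = fork_position_stepper(
            model, origins, activations, directions, ts, 2.0, dt=1e-3
        )
        for i in range(n):
            origin = OriginEvent(i, float(origins[i]), float(activations[i]))
            fork = make_fork(model, origin, int(directions[i]), 2.0)
            assert fork.position(float(ts[i])) == pytest.approx(
                expected[i], abs=ORACLE_TOL_KBP
            )

    def test_conservation_dna_mode(self, paper_model, rng):
        # replicated length equals the clamped closed form summed over forks
        total = paper_model.total_genomic_kbp
        for _ in range(50):
            g = rng.uniform(100.0, 152.0)
            a = rng.uniform(0.0, 20.0)
            t = a + rng.uniform(0.0, 100.0)
            rec = record_at(paper_model, g, activation=a)
            replicated = rec.right_fork.position(t) - rec.left_fork.position(t)
            expected = min(2.0 * (t - a), g) + min(2.0 * (t - a), total - g)
            assert replicated == pytest.approx(expected, abs=1e-9)

    def test_mirror_symmetry(self, paper_model, rng):
        mirrored = paper_model.mirror()
        total = paper_model.total_genomic_kbp
        for _ in range(30):
            g = rng.uniform(0.5, total - 0.5)
            t = rng.uniform(0.0, 80.0)
            left = make_fork(paper_model, OriginEvent(0, g, 0.0), -1)
            right = make_fork(paper_model, OriginEvent(0, g, 0.0), +1)
            left_m = make_fork(mirrored, OriginEvent(0, total - g, 0.0), -1)
            right_m = make_fork(mirrored, OriginEvent(0, total - g, 0.0), +1)
            assert right_m.position(t) == pytest.approx(
                total - left.position(t), abs=1e-9
            )
            assert left_m.position(t) == pytest.approx(
                total - right.position(t), abs=1e-9
            )


class TestSimulate:
    def test_one_record_per_chromatid(self, sync_records):
        assert len(sync_records) == 1024
        assert [r.chromatid_id for r in sync_records] == list(range(1024))

    def test_deterministic(self, paper_model):
        scen = InitiationScenario.uniform_window(10.0)
        a = simulate(paper_model, scen, 32, 2.0, seed=5)
        b = simulate(paper_model, scen, 32, 2.0, seed=5)
        assert [r.origin for r in a] == [r.origin for r in b]
        assert [r.int_completion_time for r in a] == [r.int_completion_time for r in b]

    def test_completion_finite(self, window60_records):
        assert all(np.isfinite(r.int_completion_time) for r in window60_records)

    def test_centered_origin_completes_in_13(self, paper_model):
        # 26 kbp into the 52-kbp INT; both forks need 26/2 = 13 min
        rec = record_at(paper_model, 126.0)
        assert rec.int_completion_time == pytest.approx(13.0, abs=1e-12)

    def test_edge_origin_worst_case_26(self, paper_model):
        rec = record_at(paper_model, 100.0)
        assert rec.int_completion_time == pytest.approx(26.0, abs=1e-12)
        rec2 = record_at(paper_model, 152.0 - 1e-9)
        assert rec2.int_completion_time <= 26.0 + 1e-6

    def test_synchronous_max_completion_below_26(self, sync_records):
        worst = max(r.int_completion_time for r in sync_records)
        assert worst <= 26.0
        assert worst > 13.0  # some origin is always off-center at N=1024

    def test_window60_completion_bound(self, window60_records):
        worst = max(r.int_completion_time for r in window60_records)
        assert worst <= 60.0 + 26.0


class TestCompletionTime:
    def test_degenerate_region_is_activation(self, paper_model):
        rec = record_at(paper_model, 110.0, activation=3.0)
        assert completion_time(rec, (110.0, 110.0)) == 3.0

    def test_int_region_matches_record(self, paper_model, rng):
        for _ in range(20):
            rec = record_at(paper_model, rng.uniform(100.0, 152.0))
            assert completion_time(rec, paper_model.int_span) == pytest.approx(
                rec.int_completion_time
            )

    def test_region_excluding_origin_errors(self, paper_model):
        rec = record_at(paper_model, 110.0)
        with pytest.raises(ValueError):
            completion_time(rec, (130.0, 150.0))

    def test_monotone_in_region(self, paper_model, rng):
        rec = record_at(paper_model, 120.0)
        prev = 0.0
        for pad in [0.0, 5.0, 10.0, 15.0, 19.0]:
            t = completion_time(rec, (120.0 - pad, 120.0 + pad))
            assert t >= prev
            prev = t


class TestEduPulse:
    def test_pulse_before_activation_empty(self, paper_model):
        rec = record_at(paper_model, 110.0, activation=20.0)
        assert edu_pulse_intervals(rec, 0.0, 10.0) == []

    def test_sync_pulse_two_20kbp_intervals(self, paper_model):
        rec = record_at(paper_model, 126.0)
        intervals = edu_pulse_intervals(rec, 0.0, 10.0)
        assert len(intervals) == 2
        widths = sorted(hi - lo for lo, hi in intervals)
        assert widths == pytest.approx([20.0, 20.0])
        assert intervals[0][1] == pytest.approx(126.0)
        assert intervals[1][0] == pytest.approx(126.0)

    def test_pulse_after_both_forks_stopped(self, paper_model):
        rec = record_at(paper_model, 126.0)
        assert edu_pulse_intervals(rec, 200.0, 10.0) == []

    def test_partition_additivity(self, paper_model, rng):
        rec = record_at(paper_model, 115.0, activation=4.0)
        T = 40.0
        cuts = np.concatenate([[0.0], np.sort(rng.uniform(0, T, 6)), [T]])
        pieces = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            pieces.extend(edu_pulse_intervals(rec, float(lo), float(hi - lo)))
        pieces.sort()
        merged = [list(pieces[0])]
        for lo, hi in pieces[1:]:
            if lo <= merged[-1][1] + 1e-9:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        assert len(merged) == 1
        assert merged[0][0] == pytest.approx(rec.left_fork.position(T))
        assert merged[0][1] == pytest.approx(rec.right_fork.position(T))

    def test_bad_duration(self, paper_model):
        rec = record_at(paper_model, 110.0)
        with pytest.raises(ValueError):
            edu_pulse_intervals(rec, 0.0, 0.0)


class TestTrajectoryStructure:
    def test_exit_times_increase(self, paper_model):
        rec = record_at(paper_model, 110.0)
        for fork in (rec.left_fork, rec.right_fork):
            assert np.all(np.diff(fork.time_knots) >= 0)

    def test_time_to_reach_out_of_path(self, paper_model):
        rec = record_at(paper_model, 110.0)
        with pytest.raises(ValueError):
            rec.left_fork.time_to_reach(150.0)  # right of origin, left fork

    def test_stated_mode_completion_slower_than_dna(self):
        dna = build_paper_int(100.0, SpeedMode.DNA)
        stated = build_paper_int(100.0, SpeedMode.STATED)
        g = 126.0
        assert (
            record_at(stated, g).int_completion_time
            > record_at(dna, g).int_completion_time
        )
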