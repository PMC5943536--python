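"""Control ranges, cloglog intervals, aberrance flags, detection fits."""

import numpy as np
import pytest
from scipy.stats import norm

from splicequant.compare import (
    ABOVE_RANGE,
    BELOW_RANGE,
    NOT_EXPRESSED_IN_CONTROLS,
    WITHIN_RANGE,
    ControlRange,
    RangeCriteria,
    cloglog_ci,
    compare_sample,
    control_ranges,
    detection_depth_fit,
    presence_matrix,
)
from splicequant.errors import ConfigError
from splicequant.gene_model import FULL_LENGTH
from splicequant.quantify import ExpressionProfile


def profile_from_counts(sample_id, counts, gene_total=None, total=None, **meta):
    """ExpressionProfile with explicit included alternative-event counts."""
    total = total or (sum(counts.values()) * 10)
    fl = total - sum(counts.values())
    props = {FULL_LENGTH: fl / total}
    props.update({e: c / total for e, c in counts.items()})
    return ExpressionProfile(
        sample_id=sample_id,
        gene_id="G",
        full_length_count=fl,
        total_reads=total,
        proportion_by_event=props,
        counts_by_event=dict(counts),
        excluded_counts={},
        excluded_reasons={},
        gene_total_reads=gene_total if gene_total is not None else total,
        **meta,
    )


class TestCloglogCI:
    def test_against_grid_inversion_oracle(self):
        """Endpoints must agree with a brute-force inversion of the
        transform: the p whose g-value sits z standard errors away."""
        x, n, level = 50, 100, 0.95
        lo, hi, adj = cloglog_ci(x, n, level)
        assert not adj
        p_hat = x / n
        grid = np.linspace(1e-6, 1 - 1e-6, 2_000_001)
        g = np.log(-np.log(grid))
        se = np.sqrt((1 - p_hat) / (n * p_hat * np.log(p_hat) ** 2))
        z = norm.ppf(0.975)
        target = np.log(-np.log(p_hat))
        lo_oracle = grid[np.argmin(np.abs(g - (target + z * se)))]
        hi_oracle = grid[np.argmin(np.abs(g - (target - z * se)))]
        assert lo == pytest.approx(lo_oracle, abs=1e-6)
        assert hi == pytest.approx(hi_oracle, abs=1e-6)
        assert 0 < lo < p_hat < hi < 1

    def test_zero_level_collapses_to_point(self):
        lo, hi, _ = cloglog_ci(5, 100, level=1e-12)
        assert lo == pytest.approx(0.05, abs=1e-9)
        assert hi == pytest.approx(0.05, abs=1e-9)

    def test_monotone_narrowing_with_n(self):
        lo1, hi1, _ = cloglog_ci(5, 100)
        lo2, hi2, _ = cloglog_ci(5, 100_000)
        assert (hi2 - lo2) < (hi1 - lo1)

    @pytest.mark.parametrize("x,n", [(0, 50), (50, 50)])
    def test_boundary_uses_continuity_adjustment(self, x, n):
        lo, hi, adj = cloglog_ci(x, n)
        assert adj
        assert 0 < lo < hi < 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cloglog_ci(1, 0)
        with pytest.raises(ValueError):
            cloglog_ci(5, 4)

    def test_vectorized_matches_scalar(self):
        xs = np.array([3, 10, 40])
        lo, hi, adj = cloglog_ci(xs, 100)
        for i, x in enumerate(xs):
            slo, shi, _ = cloglog_ci(int(x), 100)
            assert lo[i] == pytest.approx(slo)
            assert hi[i] == pytest.approx(shi)


class TestControlRanges:
    def test_per_event_strict_read_threshold(self):
        """Controls at 11, 12 and 9 reads: only the first two qualify."""
        controls = [
            profile_from_counts("C1", {"Δ4": 11, "Δ5": 50}, gene_total=20_000,
                                total=1100),
            profile_from_counts("C2", {"Δ4": 12, "Δ5": 60}, gene_total=20_000,
                                total=1000),
            profile_from_counts("C3", {"Δ4": 9, "Δ5": 55}, gene_total=20_000,
                                total=1000),
        ]
        ranges = {r.event: r for r in control_ranges(controls)}
        assert ranges["Δ4"].included
        assert ranges["Δ4"].n_controls_used == 2
        assert ranges["Δ4"].mean_proportion == pytest.approx(
            (11 / 1100 + 12 / 1000) / 2
        )
        assert ranges["Δ4"].lower <= ranges["Δ4"].mean_proportion <= ranges["Δ4"].upper

    def test_gene_read_threshold_is_strict_at_10000(self):
        mk = lambda sid, gt: profile_from_counts(
            sid, {"Δ4": 50, "Δ5": 50}, gene_total=gt
        )
        # exactly 10,000 reads fails "more than 10,000"
        with pytest.raises(ConfigError):
            control_ranges([mk("C1", 10_000), mk("C2", 10_000)])
        ranges = control_ranges([mk("C1", 10_001), mk("C2", 10_001)])
        assert all(r.included for r in ranges)

    def test_event_threshold_strict_at_10_reads(self):
        mk = lambda sid, c: profile_from_counts(
            sid, {"Δ4": c, "Δ5": 50, "Δ6": 50}, gene_total=20_000
        )
        ranges = {r.event: r for r in control_ranges([mk("C1", 10), mk("C2", 10)])}
        assert not ranges["Δ4"].included  # 10 reads is not "more than 10"
        ranges = {r.event: r for r in control_ranges([mk("C1", 11), mk("C2", 11)])}
        assert ranges["Δ4"].included

    def test_minor_transcript_criterion_drops_sample(self):
        # C2 expresses a single minor transcript and must be dropped entirely
        c1 = profile_from_counts("C1", {"Δ4": 40, "Δ5": 40}, gene_total=20_000)
        c2 = profile_from_counts("C2", {"Δ4": 40, "Δ5": 5}, gene_total=20_000)
        c3 = profile_from_counts("C3", {"Δ4": 40, "Δ5": 40}, gene_total=20_000)
        ranges = {r.event: r for r in control_ranges([c1, c2, c3])}
        assert ranges["Δ4"].n_controls_used == 2

    def test_no_qualifying_controls_is_an_error(self):
        with pytest.raises(ConfigError):
            control_ranges(
                [profile_from_counts("C1", {"Δ4": 40, "Δ5": 40}, gene_total=9000)]
            )

    def test_coverage_of_control_mean_interval(self):
        """mean ± z·SEM covers the true proportion at ~nominal rate."""
        rng = np.random.default_rng(7)
        p_true, depth, n_ctrl, hits = 0.02, 100_000, 5, 0
        reps = 1000
        for _ in range(reps):
            controls = []
            for i in range(n_ctrl):
                x = rng.binomial(depth, p_true)
                controls.append(
                    profile_from_counts(
                        f"C{i}", {"Δ4": x, "Δ5": 200}, gene_total=depth,
                        total=depth,
                    )
                )
            r = {rr.event: rr for rr in control_ranges(controls)}["Δ4"]
            hits += r.lower <= p_true <= r.upper
        # z-based SEM interval at n=5 undercovers slightly; allow that
        assert hits / reps >= 0.85


class TestCompareSample:
    def _range(self, mean, half, event="Δ4"):
        return ControlRange(event, 5, mean, mean - half, mean + half, True)

    def test_fold_change_arithmetic(self):
        carrier = profile_from_counts("V1", {"Δ4": 8800}, total=100_000,
                                      group="carrier")
        res = compare_sample(carrier, [self._range(0.010, 0.002)])[0]
        assert res.fold_change == pytest.approx(8.8)
        assert res.flag == ABOVE_RANGE

    def test_equal_to_control_mean_is_within_range(self):
        carrier = profile_from_counts("V1", {"Δ4": 1000}, total=100_000)
        res = compare_sample(carrier, [self._range(0.010, 0.002)])[0]
        assert res.fold_change == pytest.approx(1.0)
        assert res.flag == WITHIN_RANGE

    def test_below_range_flag(self):
        carrier = profile_from_counts("V1", {"Δ4": 100}, total=100_000)
        res = compare_sample(carrier, [self._range(0.010, 0.002)])[0]
        assert res.flag == BELOW_RANGE

    def test_event_absent_from_controls(self):
        carrier = profile_from_counts("V1", {"Δ9": 500}, total=100_000)
        not_incl = ControlRange("Δ9", 1, float("nan"), float("nan"),
                                float("nan"), False, "too few controls")
        res = compare_sample(carrier, [not_incl])
        assert len(res) == 1
        assert res[0].flag == NOT_EXPRESSED_IN_CONTROLS
        assert np.isnan(res[0].fold_change)

    def test_flags_invariant_under_count_rescaling(self):
        ranges = [self._range(0.010, 0.002)]
        for scale in (1, 7):
            carrier = profile_from_counts(
                "V1", {"Δ4": 300 * scale}, total=100_000 * scale
            )
            res = compare_sample(carrier, ranges)[0]
            assert res.flag == BELOW_RANGE
        # exactly one flag per (sample, event)
        carrier = profile_from_counts("V1", {"Δ4": 300}, total=100_000)
        assert len(compare_sample(carrier, ranges)) == 1


class TestDetectionDepthFit:
    def test_collinear_points_give_r2_one(self):
        profiles = [
            profile_from_counts(
                f"S{i}",
                {f"E{k}": 100 for k in range(i + 1)},
                gene_total=10_000 * (i + 1),
            )
            for i in range(5)
        ]
        slope, intercept, r2 = detection_depth_fit(profiles)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1 / 10_000)

    def test_null_depth_relation_has_near_zero_r2(self):
        rng = np.random.default_rng(11)
        profiles = []
        for i in range(200):
            k = int(rng.integers(3, 8))  # detection independent of depth
            profiles.append(
                profile_from_counts(
                    f"S{i}", {f"E{j}": 100 for j in range(k)},
                    gene_total=int(rng.integers(20_000, 200_000)),
                )
            )
        _, _, r2 = detection_depth_fit(profiles)
        assert r2 < 0.05

    def test_constant_depth_is_an_error(self):
        profiles = [
            profile_from_counts(f"S{i}", {"E": 100}, gene_total=10_000)
            for i in range(4)
        ]
        with pytest.raises(ConfigError):
            detection_depth_fit(profiles)


class TestPresenceMatrix:
    def test_threshold_application(self):
        profiles = [
            profile_from_counts("S1", {"Δ4": 12}, replicate_id="R1", time_point=1),
            profile_from_counts("S2", {"Δ4": 0, "Δ5": 20}, replicate_id="R2",
                                time_point=1),
            profile_from_counts("S3", {"Δ4": 15}, replicate_id="R3", time_point=1),
        ]
        m = presence_matrix(profiles)
        assert m.loc["Δ4"].tolist() == [True, False, True]

    def test_all_zero_row(self):
        profiles = [
            profile_from_counts("S1", {"Δ4": 0, "Δ5": 20}),
            profile_from_counts("S2", {"Δ4": 0, "Δ5": 20}),
        ]
        m = presence_matrix(profiles)
        assert not m.loc["Δ4"].any()
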