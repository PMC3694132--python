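"""Synthetic-cohort generator: correlation targets, preprocessing, determinism."""

import numpy as np
import pytest

from rsfcnet.synthetic import (
    CohortDesign,
    GroupSpec,
    TimeSeriesMatrix,
    bandpass,
    default_partition,
    generate_cohort,
    generate_subject_timeseries,
    regress_nuisance,
    subject_seed,
)


def two_block_partition(block: int = 10) -> dict[str, int]:
    return {f"n{i}": (1 if i < block else 2) for i in range(2 * block)}


class TestGenerateSubjectTimeseries:
    def test_default_volume_count_is_200(self):
        ts = generate_subject_timeseries(two_block_partition(), seed=0)
        assert ts.n_volumes == 200
        assert ts.tr_seconds == 2.5

    def test_deterministic_for_fixed_seed(self):
        a = generate_subject_timeseries(two_block_partition(), seed=42)
        b = generate_subject_timeseries(two_block_partition(), seed=42)
        assert np.array_equal(a.values, b.values)

    def test_independent_noise_when_no_structure(self):
        ts = generate_subject_timeseries(
            two_block_partition(), n_volumes=5000, within_r=0.0, between_r=0.0, seed=1
        )
        r = np.corrcoef(ts.values)
        off = r[np.triu_indices_from(r, 1)]
        assert abs(off.mean()) < 0.02

    def test_sample_correlations_match_planted_targets(self):
        # Monte-Carlo check of the factor-model mixing coefficients
        ts = generate_subject_timeseries(
            two_block_partition(10), n_volumes=5000, within_r=0.6, between_r=0.1, seed=2
        )
        r = np.corrcoef(ts.values)
        within = np.concatenate([r[:10, :10][np.triu_indices(10, 1)],
                                 r[10:, 10:][np.triu_indices(10, 1)]])
        between = r[:10, 10:].ravel()
        assert 0.57 <= within.mean() <= 0.63
        assert 0.07 <= between.mean() <= 0.13

    def test_null_request_within_equals_between_allowed(self):
        ts = generate_subject_timeseries(
            two_block_partition(), within_r=0.3, between_r=0.3, seed=0
        )
        assert ts.n_nodes == 20

    @pytest.mark.parametrize("within_r,between_r", [(0.2, 0.5), (1.0, 0.1), (0.5, -0.1)])
    def test_infeasible_correlation_targets_rejected(self, within_r, between_r):
        with pytest.raises(ValueError):
            generate_subject_timeseries(
                two_block_partition(), within_r=within_r, between_r=between_r, seed=0
            )


class TestGenerateCohort:
    def test_identical_designs_give_bit_identical_cohorts(self):
        design = CohortDesign(
            groups=[GroupSpec(name="A", n_subjects=3), GroupSpec(name="B", n_subjects=2)],
            master_seed=7,
        )
        c1, c2 = generate_cohort(design), generate_cohort(design)
        for g in c1.subjects:
            for s1, s2 in zip(c1.subjects[g], c2.subjects[g]):
                assert np.array_equal(s1.values, s2.values)

    def test_adding_a_group_preserves_existing_subjects(self):
        base = CohortDesign(groups=[GroupSpec(name="A", n_subjects=2)], master_seed=3)
        extended = CohortDesign(
            groups=[GroupSpec(name="A", n_subjects=2), GroupSpec(name="C", n_subjects=2)],
            master_seed=3,
        )
        c1, c2 = generate_cohort(base), generate_cohort(extended)
        for s1, s2 in zip(c1.subjects["A"], c2.subjects["A"]):
            assert np.array_equal(s1.values, s2.values)

    def test_duplicate_group_names_rejected(self):
        design = CohortDesign(
            groups=[GroupSpec(name="A", n_subjects=2), GroupSpec(name="A", n_subjects=2)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            generate_cohort(design)

    def test_reassignment_must_name_existing_module(self):
        design = CohortDesign(
            groups=[GroupSpec(name="A", n_subjects=2, noi_reassignments={"PreC.L": 99})]
        )
        with pytest.raises(ValueError, match="unknown module"):
            generate_cohort(design)

    def test_reassigned_nodes_correlate_with_new_module(self):
        moved = "Vr8"
        design = CohortDesign(
            groups=[GroupSpec(name="B", n_subjects=1, noi_reassignments={moved: 1})],
            n_volumes=5000,
            master_seed=1,
        )
        ts = generate_cohort(design).subjects["B"][0]
        r = np.corrcoef(ts.values)
        partition = default_partition()
        idx = ts.node_ids.index(moved)
        new_peers = [i for i, nid in enumerate(ts.node_ids)
                     if partition[nid] == 1 and nid != moved]
        old_peers = [i for i, nid in enumerate(ts.node_ids)
                     if partition[nid] == 5 and nid != moved]
        assert r[idx, new_peers].mean() > 0.4
        assert r[idx, old_peers].mean() < 0.2

    def test_seed_fanout_is_stable(self):
        assert subject_seed(1, 0, 0) == subject_seed(1, 0, 0)
        assert subject_seed(1, 0, 0) != subject_seed(1, 0, 1)
        assert subject_seed(1, 0, 0) != subject_seed(1, 1, 0)
        assert 0 <= subject_seed(123, 5, 17) < 2**31


class TestRegressNuisance:
    def test_covariate_row_becomes_zero(self, rng):
        cov = rng.standard_normal((100, 1))
        values = np.vstack([cov.ravel(), rng.standard_normal(100)])
        ts = TimeSeriesMatrix(values)
        out = regress_nuisance(ts, cov)
        assert np.all(np.abs(out.values[0]) < 1e-10)

    def test_empty_covariates_mean_center(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((3, 50)))
        out = regress_nuisance(ts, np.empty((50, 0)))
        expected = ts.values - ts.values.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_residual_recovers_orthogonal_component(self):
        t = np.arange(2000)
        cov = np.sin(2 * np.pi * t / 400)
        sinusoid = np.sin(2 * np.pi * t / 157)  # near-orthogonal to cov
        ts = TimeSeriesMatrix((cov + sinusoid)[None, :])
        out = regress_nuisance(ts, cov[:, None])
        r = np.corrcoef(out.values[0], sinusoid)[0, 1]
        assert r > 0.999

    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = rng.standard_normal((200, 3))
        ts = TimeSeriesMatrix(rng.standard_normal((5, 200)))
        out = regress_nuisance(ts, cov)
        assert np.all(np.abs(out.values @ cov) < 1e-8)

    def test_shared_covariate_removed_from_correlation(self, rng):
        shared = rng.standard_normal(2000)
        a = shared + rng.standard_normal(2000)
        b = shared + rng.standard_normal(2000)
        out = regress_nuisance(TimeSeriesMatrix(np.vstack([a, b])), shared[:, None])
        assert abs(np.corrcoef(out.values)[0, 1]) < 0.05

    def test_collinear_covariates_rejected(self, rng):
        c = rng.standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            regress_nuisance(
                TimeSeriesMatrix(rng.standard_normal((2, 100))),
                np.column_stack([c, 2 * c]),
            )


class TestBandpass:
    def make_sine(self, hz: float, n: int = 2000, tr: float = 2.5) -> TimeSeriesMatrix:
        t = np.arange(n) * tr
        return TimeSeriesMatrix(np.sin(2 * np.pi * hz * t)[None, :], tr_seconds=tr)

    def test_dc_removed(self):
        ts = TimeSeriesMatrix(np.full((1, 500), 3.7))
        out = bandpass(ts)
        assert np.all(np.abs(out.values) < 1e-6)

    def test_passband_center_retained(self):
        out = bandpass(self.make_sine(0.05))
        ratio = out.values.std() / self.make_sine(0.05).values.std()
        assert ratio >= 0.9

    def test_stopband_attenuated(self):
        out = bandpass(self.make_sine(0.18))
        ratio = out.values.std() / self.make_sine(0.18).values.std()
        assert ratio <= 0.1

    def test_zero_phase_no_peak_shift(self):
        ts = self.make_sine(0.05)
        out = bandpass(ts)
        # ignore filter edge transients
        inner = slice(200, 1800)
        orig_peak = np.argmax(ts.values[0, inner])
        filt_peak = np.argmax(out.values[0, inner])
        assert abs(int(orig_peak) - int(filt_peak)) <= 1

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(self.make_sine(0.05), low_hz=0.01, high_hz=0.25)
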