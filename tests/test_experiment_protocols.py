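"""Experiment protocol arithmetic and toy end-to-end execution."""

import numpy as np
import pytest
from scipy import stats as sps

from groupvar import (
    CohortParams,
    Diagnosis,
    PipelineOptions,
    RegParams,
    generate_cohort,
    make_exp1_spec,
    make_exp2_spec,
    make_exp3_spec,
    make_exp4_spec,
    make_exp5_spec,
    make_exp6_specs,
    voxelwise_sd,
)
from groupvar.core import CardinalityError
from groupvar.experiment_protocols import execute_experiment

TOY_REG = RegParams(n_iterations=6)


class TestExp1:
    def test_shape_and_constants(self, replica_cohort):
        spec = make_exp1_spec(replica_cohort, seed=5)
        assert len(spec.runs) == 20
        assert len(spec.constant_ids) == 3
        for run in spec.runs:
            assert len(run.subject_ids) == 15
            assert set(spec.constant_ids) <= set(run.subject_ids)
            stats = run.age_stats(replica_cohort)
            assert stats["n_asd"] == 0

    def test_seed_determinism(self, replica_cohort):
        a = make_exp1_spec(replica_cohort, seed=5)
        b = make_exp1_spec(replica_cohort, seed=5)
        assert a == b
        c = make_exp1_spec(replica_cohort, seed=6)
        assert c != a

    def test_sampling_is_uniform(self, replica_cohort):
        """Across many spec draws, each non-constant control appears with
        frequency consistent with uniform 12-of-21 sampling (chi-square)."""
        counts: dict[str, int] = {}
        n_draws = 400
        for seed in range(n_draws):
            spec = make_exp1_spec(replica_cohort, seed=1000 + seed)
            for run in spec.runs:
                for sid in run.subject_ids:
                    if sid not in spec.constant_ids:
                        counts[sid] = counts.get(sid, 0) + 1
        observed = np.array(list(counts.values()), dtype=float)
        # constants differ per seed, so pool over all 24 core controls
        expected = observed.sum() / observed.size
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = sps.chi2.sf(chi2, df=observed.size - 1)
        assert p > 1e-4

    def test_insufficient_pool(self):
        small = generate_cohort(CohortParams(n_tdc=10, n_asd=0, n_extension=0))
        with pytest.raises(CardinalityError):
            make_exp1_spec(small, seed=0)


class TestExp2:
    def test_window_arithmetic(self, replica_cohort):
        spec = make_exp2_spec(replica_cohort)
        assert len(spec.runs) == 15
        assert all(len(r.subject_ids) == 15 for r in spec.runs)
        tdcs = sorted(replica_cohort.group(Diagnosis.TDC), key=lambda s: s.age)
        assert set(spec.constant_ids) == {s.subject_id for s in tdcs[:3]}

    def test_consecutive_overlap_is_nine_of_twelve(self, replica_cohort):
        spec = make_exp2_spec(replica_cohort)
        for prev, cur in zip(spec.runs, spec.runs[1:]):
            varying_prev = set(prev.subject_ids) - set(spec.constant_ids)
            varying_cur = set(cur.subject_ids) - set(spec.constant_ids)
            assert len(varying_prev & varying_cur) == 9

    def test_mean_age_strictly_increases(self, replica_cohort):
        spec = make_exp2_spec(replica_cohort)
        means = [r.age_stats(replica_cohort)["mean"] for r in spec.runs]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_last_run_contains_oldest_subject(self, replica_cohort):
        spec = make_exp2_spec(replica_cohort)
        oldest = max(replica_cohort.group(Diagnosis.TDC), key=lambda s: s.age)
        assert oldest.subject_id in spec.runs[-1].subject_ids


class TestExp3:
    def test_asd_count_increments(self, replica_cohort):
        spec = make_exp3_spec(replica_cohort, seed=2)
        assert len(spec.runs) == 20
        for run in spec.runs:
            stats = run.age_stats(replica_cohort)
            assert len(run.subject_ids) == 24
            assert stats["n_asd"] == run.run_id
            assert stats["n_tdc"] == 24 - run.run_id
        # run 20: 3 constants + 1 varying control remain
        assert spec.runs[-1].age_stats(replica_cohort)["n_tdc"] == 4

    def test_age_matching_keeps_mean_age_stable(self, replica_cohort):
        spec = make_exp3_spec(replica_cohort, seed=2)
        base = spec.runs[0].age_stats(replica_cohort)["mean"]
        for run in spec.runs[1:]:
            assert abs(run.age_stats(replica_cohort)["mean"] - base) < 0.5

    def test_seed_determinism(self, replica_cohort):
        assert make_exp3_spec(replica_cohort, seed=2) == make_exp3_spec(replica_cohort, seed=2)


def test_exp4_exp5_exp6_derivations(replica_cohort):
    e4 = make_exp4_spec(replica_cohort)
    assert len(e4.runs) == 1 and len(e4.runs[0].subject_ids) == 48
    assert e4.normalize_all

    e2 = make_exp2_spec(replica_cohort)
    e5 = make_exp5_spec(replica_cohort)
    assert [r.subject_ids for r in e5.runs] == [r.subject_ids for r in e2.runs]
    assert e5.options.modulate is False and e2.options.modulate is True

    e6a, e6b = make_exp6_specs(replica_cohort)
    assert (e6a.options.fwhm_mm, e6b.options.fwhm_mm) == (4.0, 8.0)
    assert [r.subject_ids for r in e6a.runs] == [r.subject_ids for r in e2.runs]


class TestExecution:
    def test_unknown_subject_rejected(self, tiny_cohort):
        from groupvar.experiment_protocols import ExperimentSpec, RunSpec
        spec = ExperimentSpec("E1", (RunSpec(1, ("TDC01", "nope")),), ("TDC01",))
        with pytest.raises(KeyError):
            execute_experiment(spec, tiny_cohort, TOY_REG, n_outer=1)

    def test_two_runs_differing_by_one_subject_produce_variability(self, tiny_cohort):
        """The serendipitous observation that started it all: swap one group
        member and the constant subject's normalized map changes."""
        from groupvar.experiment_protocols import ExperimentSpec, RunSpec
        ids = [s.subject_id for s in tiny_cohort.subjects]
        spec = ExperimentSpec(
            "E1", (RunSpec(1, tuple(ids[:5])), RunSpec(2, tuple(ids[:4] + [ids[5]]))),
            constant_ids=tuple(ids[:2]),
            options=PipelineOptions(fwhm_mm=4.0))
        results = execute_experiment(spec, tiny_cohort, TOY_REG, n_outer=2)
        for sid in spec.constant_ids:
            res = voxelwise_sd([results[1][sid], results[2][sid]])
            assert res.summary["max_sd"] > 0

    def test_rerun_is_bit_identical(self, tiny_cohort):
        from groupvar.experiment_protocols import ExperimentSpec, RunSpec
        ids = [s.subject_id for s in tiny_cohort.subjects]
        spec = ExperimentSpec("E1", (RunSpec(1, tuple(ids[:4])),),
                              constant_ids=(ids[0],))
        a = execute_experiment(spec, tiny_cohort, TOY_REG, n_outer=1)
        b = execute_experiment(spec, tiny_cohort, TOY_REG, n_outer=1)
        np.testing.assert_array_equal(a[1][ids[0]].gm, b[1][ids[0]].gm)
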