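"""The six resampling experiments, declaratively specified and executed.

Each experiment fixes a few *constant subjects* whose raw maps never
change, and varies the rest of the group across runs.  Per run, a fresh
group template is built from that run's subjects only, and the constant
subjects' final normalized maps are produced against it.  Variability of
those maps across runs then isolates the influence of group composition.

Protocols:

* **E1** — 20 runs of 15 same-diagnosis subjects with similar demographics
  (3 constants + 12 drawn uniformly without replacement from the rest):
  the baseline variability of resampling alone.
* **E2** — 15 runs of 15; constants are the 3 youngest controls, and the
  12 varying members slide up a list sorted by age (drop the youngest 3,
  add the next oldest 3), so mean group age increases run over run.
* **E3** — 20 runs of 24; starting from 20 varying controls + 1 case, each
  run swaps one randomly chosen control for its age-matched case, so the
  case/control ratio grows while mean age stays put.
* **E4** — one run of all 48 subjects; every subject is normalized, to
  compare case-vs-control differences with the variability of E1-E3.
* **E5** — E2's runs without modulation.
* **E6a/E6b** — E2's runs at 4 mm and 8 mm smoothing instead of 6 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import CardinalityError, Diagnosis, PairingError, SubjectRecord
from .groupwise_template import build_template
from .normalization import FINTM, PipelineOptions, normalize_subject
from .registration_engine import RegParams
from .synthetic_cohort import Cohort

__all__ = [
    "RunSpec",
    "ExperimentSpec",
    "make_exp1_spec",
    "make_exp2_spec",
    "make_exp3_spec",
    "make_exp4_spec",
    "make_exp5_spec",
    "make_exp6_specs",
    "execute_experiment",
]


@dataclass(frozen=True)
class RunSpec:
    run_id: int
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError(f"duplicate subject ids in run {self.run_id}")

    def age_stats(self, cohort: Cohort) -> dict:
        ages = np.array([cohort.by_id(s).age for s in self.subject_ids])
        diags = [cohort.by_id(s).diagnosis for s in self.subject_ids]
        return {
            "mean": float(ages.mean()),
            "sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
            "range": (float(ages.min()), float(ages.max())),
            "n_asd": sum(d is Diagnosis.ASD for d in diags),
            "n_tdc": sum(d is Diagnosis.TDC for d in diags),
        }


@dataclass(frozen=True)
class ExperimentSpec:
    experiment_id: str
    runs: tuple[RunSpec, ...]
    constant_ids: tuple[str, ...]
    options: PipelineOptions = field(default_factory=PipelineOptions)
    seed: int = 0
    normalize_all: bool = False  # E4 normalizes every subject, not just constants

    def __post_init__(self) -> None:
        for run in self.runs:
            missing = set(self.constant_ids) - set(run.subject_ids)
            if missing:
                raise ValueError(
                    f"constant subjects {sorted(missing)} absent from run {run.run_id}")


def _core_tdc(pool: Cohort) -> list[SubjectRecord]:
    """Controls in the core age band (excludes the older extension pool)."""
    p = pool.params
    return [s for s in pool.group(Diagnosis.TDC)
            if p.age_min <= s.age <= p.age_max and not s.subject_id.startswith("TDCX")]


def make_exp1_spec(pool: Cohort, seed: int = 0, n_runs: int = 20,
                   n_constants: int = 3, n_varying: int = 12,
                   options: PipelineOptions | None = None) -> ExperimentSpec:
    """Similar-demographics baseline: random resampling of controls.

    ``n_runs`` runs of ``n_constants + n_varying`` controls; the varying
    members of each run are drawn uniformly without replacement from the
    non-constant core controls.  Reproducible from ``seed``.
    """
    core = _core_tdc(pool)
    if len(core) < n_constants + n_varying + 1:
        raise CardinalityError(
            f"need > {n_constants + n_varying} core controls, have {len(core)}")
    rng = np.random.default_rng(seed)
    ids = [s.subject_id for s in core]
    constants = tuple(sorted(rng.choice(ids, size=n_constants, replace=False)))
    remaining = [i for i in ids if i not in constants]
    runs = []
    for r in range(1, n_runs + 1):
        varying = rng.choice(remaining, size=n_varying, replace=False)
        runs.append(RunSpec(run_id=r, subject_ids=constants + tuple(sorted(varying))))
    return ExperimentSpec("E1", tuple(runs), constants,
                          options or PipelineOptions(), seed)


def make_exp2_spec(pool: Cohort, n_window: int = 12, window_step: int = 3,
                   n_constants: int = 3, max_runs: int | None = None,
                   options: PipelineOptions | None = None) -> ExperimentSpec:
    """Sliding-age protocol: deterministic, no randomness.

    Constants are the ``n_constants`` youngest controls.  The remaining
    controls (core plus the older extension pool) are sorted by age; run 1
    takes the youngest ``n_window`` of them, and each later run drops its
    ``window_step`` youngest varying members and appends the next
    ``window_step`` oldest unused, so mean group age rises monotonically.
    """
    tdcs = sorted(pool.group(Diagnosis.TDC), key=lambda s: s.age)
    if len(tdcs) < n_constants + n_window + window_step:
        raise CardinalityError("control pool too small for the sliding window")
    constants = tuple(s.subject_id for s in tdcs[:n_constants])
    varying_pool = [s.subject_id for s in tdcs[n_constants:]]
    n_runs = (len(varying_pool) - n_window) // window_step + 1
    if max_runs is not None:
        n_runs = min(n_runs, max_runs)
    runs = []
    for r in range(n_runs):
        window = varying_pool[r * window_step: r * window_step + n_window]
        runs.append(RunSpec(run_id=r + 1, subject_ids=constants + tuple(window)))
    return ExperimentSpec("E2", tuple(runs), constants,
                          options or PipelineOptions(), seed=0)


def age_matched_pairs(pool: Cohort, tdc_ids: list[str],
                      max_age_gap: float = 1.0) -> dict[str, str]:
    """Greedy nearest-age pairing of each listed control with a distinct case."""
    asds = sorted(pool.group(Diagnosis.ASD), key=lambda s: s.age)
    if not asds:
        raise PairingError("no cases available for age matching")
    tdcs = sorted((pool.by_id(t) for t in tdc_ids), key=lambda s: s.age)
    unused = list(asds)
    pairs: dict[str, str] = {}
    for t in tdcs:
        if not unused:
            raise PairingError(f"no case left to pair with {t.subject_id}")
        best = min(unused, key=lambda a: abs(a.age - t.age))
        if abs(best.age - t.age) > max_age_gap:
            raise PairingError(
                f"nearest case to {t.subject_id} is {abs(best.age - t.age):.2f} y away")
        pairs[t.subject_id] = best.subject_id
        unused.remove(best)
    return pairs


def make_exp3_spec(pool: Cohort, seed: int = 0, n_runs: int = 20,
                   n_constants: int = 3,
                   options: PipelineOptions | None = None) -> ExperimentSpec:
    """Case/control-ratio sweep at constant group size and mean age.

    Run 1's varying members are all non-constant core controls except one,
    which is already replaced by its age-matched case; each subsequent run
    removes one more randomly chosen control and adds that control's
    matched case, so run *r* contains *r* cases.
    """
    core = _core_tdc(pool)
    rng = np.random.default_rng(seed)
    ids = [s.subject_id for s in core]
    constants = tuple(sorted(rng.choice(ids, size=n_constants, replace=False)))
    varying_tdc = [i for i in ids if i not in constants]
    if n_runs > len(varying_tdc):
        raise CardinalityError(
            f"{n_runs} runs need {n_runs} swappable controls, have {len(varying_tdc)}")
    pairs = age_matched_pairs(pool, varying_tdc)
    removal_order = list(rng.permutation(varying_tdc))
    runs = []
    for r in range(1, n_runs + 1):
        removed = removal_order[:r]
        kept = [i for i in varying_tdc if i not in removed]
        added = [pairs[i] for i in removed]
        runs.append(RunSpec(run_id=r, subject_ids=constants + tuple(kept + added)))
    return ExperimentSpec("E3", tuple(runs), constants,
                          options or PipelineOptions(), seed)


def make_exp4_spec(pool: Cohort,
                   options: PipelineOptions | None = None) -> ExperimentSpec:
    """Single run containing every core case and control; all are normalized."""
    core = _core_tdc(pool) + pool.group(Diagnosis.ASD)
    if len(core) < 2:
        raise CardinalityError("need at least two subjects")
    ids = tuple(s.subject_id for s in core)
    return ExperimentSpec("E4", (RunSpec(run_id=1, subject_ids=ids),),
                          constant_ids=(), options=options or PipelineOptions(),
                          normalize_all=True)


def make_exp5_spec(pool: Cohort, **exp2_kwargs) -> ExperimentSpec:
    """E2's exact run lists, without modulation."""
    base = make_exp2_spec(pool, **exp2_kwargs)
    opts = replace(base.options, modulate=False)
    return replace(base, experiment_id="E5", options=opts)


def make_exp6_specs(pool: Cohort, fwhms_mm: tuple[float, float] = (4.0, 8.0),
                    **exp2_kwargs) -> tuple[ExperimentSpec, ExperimentSpec]:
    """E2's exact run lists at alternative smoothing kernels (default 4 and 8 mm)."""
    base = make_exp2_spec(pool, **exp2_kwargs)
    out = []
    for label, fwhm in zip(("E6a", "E6b"), fwhms_mm):
        opts = replace(base.options, fwhm_mm=fwhm)
        out.append(replace(base, experiment_id=label, options=opts))
    return tuple(out)


def execute_run(run: RunSpec, spec: ExperimentSpec, cohort: Cohort,
                reg_params: RegParams | None = None, n_outer: int = 6,
                ) -> dict[str, FINTM]:
    """Build this run's template and normalize its target subjects.

    Runs are independent: nothing is cached across runs, so results are
    invariant to execution order and runs may execute concurrently.
    """
    reg_params = reg_params or RegParams()
    records = [cohort.by_id(sid) for sid in run.subject_ids]
    template, velocities = build_template([r.maps for r in records],
                                          n_outer=n_outer, params=reg_params)
    targets = run.subject_ids if spec.normalize_all else spec.constant_ids
    out: dict[str, FINTM] = {}
    for sid in targets:
        i = run.subject_ids.index(sid)
        out[sid] = normalize_subject(
            records[i].maps, velocities[i], spec.options,
            provenance={"experiment_id": spec.experiment_id,
                        "run_id": run.run_id, "subject_id": sid})
    return out


def execute_run_variants(run: RunSpec, constant_ids: tuple[str, ...],
                         variants: dict[str, PipelineOptions], cohort: Cohort,
                         reg_params: RegParams | None = None, n_outer: int = 6,
                         ) -> dict[str, dict[str, FINTM]]:
    """Build one run's template and normalize constants under several options.

    The modulation and smoothing-kernel experiments are re-normalizations
    of the sliding-age runs: the group template and velocities are shared
    and only the normalization options differ, so the expensive
    registration work is done once per run.  Returns
    ``{variant_label: {subject_id: FINTM}}``.
    """
    reg_params = reg_params or RegParams()
    records = [cohort.by_id(sid) for sid in run.subject_ids]
    _, velocities = build_template([r.maps for r in records],
                                   n_outer=n_outer, params=reg_params)
    out: dict[str, dict[str, FINTM]] = {}
    for label, opts in variants.items():
        out[label] = {}
        for sid in constant_ids:
            i = run.subject_ids.index(sid)
            out[label][sid] = normalize_subject(
                records[i].maps, velocities[i], opts,
                provenance={"experiment_id": label, "run_id": run.run_id,
                            "subject_id": sid})
    return out


def execute_experiment(spec: ExperimentSpec, cohort: Cohort,
                       reg_params: RegParams | None = None, n_outer: int = 6,
                       ) -> dict[int, dict[str, FINTM]]:
    """Execute every run of an experiment.

    Returns ``{run_id: {subject_id: FINTM}}`` covering the constant
    subjects (every subject for a ``normalize_all`` spec).  Unresolvable
    subject ids raise ``KeyError`` before any computation.
    """
    for run in spec.runs:
        for sid in run.subject_ids:
            cohort.by_id(sid)
    return {run.run_id: execute_run(run, spec, cohort, reg_params, n_outer)
            for run in spec.runs}
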