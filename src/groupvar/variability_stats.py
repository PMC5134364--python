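"""Variability and group-difference statistics over normalized tissue maps.

The unit of analysis is the across-run voxel-wise sample standard deviation
of a constant subject's normalized GM concentration, restricted to voxels
whose across-run mean GM exceeds a threshold (default 0.1 — voxels with
under 10% GM content carry little cortical signal).  Summaries, the SD
histogram and the sorted mean/SD profile mirror the standard reporting of
such sensitivity analyses; a case-vs-control mean-difference map with
exceedance fractions covers the group-contrast side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CardinalityError, check_same_lattice
from .normalization import FINTM

__all__ = [
    "VariabilityResult",
    "DifferenceResult",
    "voxelwise_sd",
    "group_difference",
    "summarize_experiments",
    "age_ttest",
]

HIST_BIN_WIDTH = 0.002  # resolves SD modes around 0.01-0.02 without over-binning
PROFILE_STRIDE = 100    # sample every 100th mask voxel for the sorted profile


@dataclass(frozen=True)
class VariabilityResult:
    """Across-run variability of one constant subject's normalized GM."""

    sd_map: np.ndarray
    mean_map: np.ndarray
    mask: np.ndarray
    summary: dict            # mean_sd / median_sd / max_sd over the mask
    histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, fractions)
    profile: np.ndarray      # (k, 2) sampled (mean, sd) sorted by mean
    n_runs: int


@dataclass(frozen=True)
class DifferenceResult:
    """Voxel-wise mean GM difference between two groups over a shared mask."""

    diff_map: np.ndarray
    mask: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]
    fractions: dict          # frac_abs_gt_005 / frac_abs_gt_01


def _gm_stack(fintms: list[FINTM]) -> np.ndarray:
    check_same_lattice(*[f.shape for f in fintms])
    return np.stack([f.gm for f in fintms])


def voxelwise_sd(fintms: list[FINTM], gm_threshold: float = 0.1,
                 profile_stride: int = PROFILE_STRIDE) -> VariabilityResult:
    """Per-voxel sample SD (n-1 denominator) of GM across runs.

    The analysis mask is defined on the across-run *mean* GM exceeding
    ``gm_threshold``: a per-run mask would make the analysis domain itself
    depend on run order, while the mean-based rule is stable and
    order-invariant.  Summary statistics, the SD histogram (bin width
    0.002) and the sorted mean/SD profile (every ``profile_stride``-th
    voxel in ascending mean order) are computed over the mask only.
    """
    if len(fintms) < 2:
        raise CardinalityError("need >= 2 runs to compute an SD")
    stack = _gm_stack(fintms)
    mean_map = stack.mean(axis=0)
    sd_map = stack.std(axis=0, ddof=1)
    # identical runs must give exactly zero, not the ~1e-16 residue the
    # two-pass mean leaves behind
    sd_map[np.ptp(stack, axis=0) == 0] = 0.0
    mask = mean_map > gm_threshold

    sds = sd_map[mask]
    if sds.size:
        summary = {"mean_sd": float(sds.mean()),
                   "median_sd": float(np.median(sds)),
                   "max_sd": float(sds.max())}
        hi = max(float(sds.max()), HIST_BIN_WIDTH)
        edges = np.arange(0.0, hi + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
        counts, edges = np.histogram(sds, bins=edges)
        fractions = counts / sds.size
        order = np.argsort(mean_map[mask], kind="stable")
        means_sorted = mean_map[mask][order]
        sds_sorted = sds[order]
        idx = np.arange(0, sds.size, profile_stride)
        profile = np.column_stack([means_sorted[idx], sds_sorted[idx]])
    else:
        summary = {"mean_sd": 0.0, "median_sd": 0.0, "max_sd": 0.0}
        edges, fractions = np.array([0.0, HIST_BIN_WIDTH]), np.array([0.0])
        profile = np.empty((0, 2))

    return VariabilityResult(sd_map=sd_map, mean_map=mean_map, mask=mask,
                             summary=summary, histogram=(edges, fractions),
                             profile=profile, n_runs=len(fintms))


def group_difference(group_a: list[FINTM], group_b: list[FINTM],
                     gm_threshold: float = 0.1) -> DifferenceResult:
    """Mean GM of group A minus group B per voxel, within the joint mask.

    The mask keeps voxels whose mean GM over *all* subjects exceeds the
    threshold.  Reported fractions are the shares of masked voxels with
    absolute difference above 0.05 and above 0.1.
    """
    if not group_a or not group_b:
        raise CardinalityError("both groups must be non-empty")
    stack_a = _gm_stack(group_a)
    stack_b = _gm_stack(group_b)
    check_same_lattice(stack_a.shape[1:], stack_b.shape[1:])
    mean_all = np.concatenate([stack_a, stack_b]).mean(axis=0)
    mask = mean_all > gm_threshold
    diff_map = np.where(mask, stack_a.mean(axis=0) - stack_b.mean(axis=0), 0.0)

    vals = diff_map[mask]
    if vals.size:
        lim = max(float(np.abs(vals).max()), HIST_BIN_WIDTH)
        edges = np.arange(-lim - HIST_BIN_WIDTH, lim + 2 * HIST_BIN_WIDTH,
                          HIST_BIN_WIDTH)
        counts, edges = np.histogram(vals, bins=edges)
        fractions_hist = counts / vals.size
        fractions = {
            "frac_abs_gt_005": float(np.mean(np.abs(vals) > 0.05)),
            "frac_abs_gt_01": float(np.mean(np.abs(vals) > 0.1)),
        }
    else:
        edges, fractions_hist = np.array([0.0, HIST_BIN_WIDTH]), np.array([0.0])
        fractions = {"frac_abs_gt_005": 0.0, "frac_abs_gt_01": 0.0}

    return DifferenceResult(diff_map=diff_map, mask=mask,
                            histogram=(edges, fractions_hist),
                            fractions=fractions)


def summarize_experiments(results: dict[str, dict[str, VariabilityResult]],
                          ) -> pd.DataFrame:
    """Assemble the per-condition summary table.

    ``results`` maps condition label -> {constant subject id -> result}.
    Rows are conditions; the first constant subject contributes mean,
    median and max SD columns, later ones their mean SD, mirroring the
    conventional compact layout of such summaries.
    """
    rows = {}
    for condition, per_subject in results.items():
        row = {}
        for j, (sid, res) in enumerate(sorted(per_subject.items()), start=1):
            row[f"subject{j}_mean"] = res.summary["mean_sd"]
            if j == 1:
                row["subject1_median"] = res.summary["median_sd"]
                row["subject1_max"] = res.summary["max_sd"]
        rows[condition] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    lead = [c for c in ("subject1_mean", "subject1_median", "subject1_max")
            if c in frame.columns]
    rest = sorted(c for c in frame.columns if c not in lead)
    return frame[lead + rest]


def age_ttest(ages_a: list[float], ages_b: list[float],
              welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test on ages; pooled-variance by default.

    Degenerate zero-variance inputs with equal means return ``(0.0, 1.0)``
    rather than NaN.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if min(a.size, b.size) < 2:
        raise CardinalityError("each sample needs >= 2 ages")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
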