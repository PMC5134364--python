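"""Iterative study-specific group template construction.

The template starts as the voxel-wise mean of the raw tissue maps; each
outer iteration registers every subject to the current template (warm
starting from its previous velocity), warps them, and replaces the
template by the mean of the warped maps.  As alignment improves across
iterations the mean sharpens, which is tracked as the mean absolute
per-voxel template change per iteration.

Because the template is an average of the very subjects being normalized,
it — and with it every subject's final normalized map — depends on the
group composition.  That dependence is the phenomenon the experiment
protocols measure.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CardinalityError,
    GroupTemplate,
    TISSUES,
    TissueMapSet,
    check_same_lattice,
)
from .registration_engine import RegParams, VelocityField, exponentiate, register, warp

__all__ = ["build_template"]


def _mean_template(map_sets: list[dict[str, np.ndarray]],
                   spacing: tuple[float, ...], iteration: int,
                   history: list[float]) -> GroupTemplate:
    means = {t: np.mean([m[t] for m in map_sets], axis=0) for t in TISSUES}
    return GroupTemplate(gm=means["gm"], wm=means["wm"], csf=means["csf"],
                         spacing=spacing, iteration_index=iteration,
                         history=history)


def build_template(subjects: list[TissueMapSet], n_outer: int = 6,
                   params: RegParams | None = None,
                   ) -> tuple[GroupTemplate, list[VelocityField]]:
    """Build the group template and the per-subject final velocities.

    Deterministic given inputs, and order-invariant up to floating-point
    summation order: the mean is symmetric in the subjects and each
    registration sees only its own subject and the shared template.

    Parameters
    ----------
    subjects:
        At least two tissue map sets on a shared lattice.
    n_outer:
        Number of averaging/re-registration iterations (>= 1).  Six mirrors
        the conventional number of template stages in groupwise VBM
        pipelines.
    """
    if len(subjects) < 2:
        raise CardinalityError("template construction needs >= 2 subjects")
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    params = params or RegParams()
    check_same_lattice(*[s.shape for s in subjects])
    for s in subjects:
        s.validate()

    spacing = subjects[0].spacing
    history: list[float] = []
    raw = [{t: s.tissue(t) for t in TISSUES} for s in subjects]
    template = _mean_template(raw, spacing, 0, history)

    velocities: list[VelocityField | None] = [None] * len(subjects)
    for it in range(1, n_outer + 1):
        warped = []
        for i, subj in enumerate(subjects):
            velocities[i] = register(subj, template, params, init=velocities[i])
            phi = exponentiate(velocities[i])
            warped.append({t: warp(subj.tissue(t), phi) for t in TISSUES})
        new_template = _mean_template(warped, spacing, it, history)
        change = float(np.mean([np.abs(new_template.tissue(t) - template.tissue(t))
                                for t in TISSUES]))
        history.append(change)
        template = new_template

    return template, [v for v in velocities if v is not None]
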