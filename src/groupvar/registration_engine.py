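"""Pairwise diffeomorphic registration via stationary velocity fields.

A deliberately small log-demons engine: each subject-to-template match is
parameterized by a stationary velocity field ``v`` whose exponential
(scaling and squaring) gives a diffeomorphic deformation ``phi`` mapping
template coordinates to source coordinates (pull-back convention).  The
optimizer is greedy demons with Gaussian fluid (update) and diffusion
(total field) regularization and accept-if-improved stepping, so the
multichannel sum-of-squared-differences never increases over a call.

This replaces a full multigrid DARTEL-style optimizer.  The analyses the
package exists for concern how the *output* depends on the group used to
build the template, not on a particular optimizer; what matters is that
registrations are diffeomorphic, driven by a shared template, and
deterministic, all of which hold here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import (
    DataError,
    GroupTemplate,
    ShapeError,
    TissueMapSet,
    check_same_lattice,
)

__all__ = [
    "RegParams",
    "VelocityField",
    "DeformationField",
    "register",
    "exponentiate",
    "warp",
    "jacobian_determinant",
]


@dataclass(frozen=True)
class RegParams:
    """Demons optimizer settings (lengths in voxels)."""

    n_iterations: int = 30
    step_size: float = 0.4
    fluid_sigma: float = 1.0
    diffusion_sigma: float = 1.0
    squaring_steps: int = 6
    channels: tuple[str, ...] = ("gm", "wm")

    def __post_init__(self) -> None:
        if not (0 < self.step_size <= 1):
            raise ValueError("step_size must lie in (0, 1]")
        if min(self.n_iterations, self.squaring_steps) < 1:
            raise ValueError("iteration counts must be positive")
        if min(self.fluid_sigma, self.diffusion_sigma) <= 0:
            raise ValueError("regularization sigmas must be positive")


@dataclass(frozen=True)
class VelocityField:
    """Stationary velocity field, channel-first ``(ndim, *grid)`` in voxels."""

    v: np.ndarray
    squaring_steps: int = 6

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.v.shape[1:]

    def validate(self) -> None:
        if self.v.shape[0] != self.v.ndim - 1:
            raise ShapeError("velocity vector axis does not match lattice dimension")
        if not np.all(np.isfinite(self.v)):
            raise DataError("non-finite velocity")

    def negated(self) -> "VelocityField":
        return replace(self, v=-self.v)

    @classmethod
    def zero(cls, grid_shape: tuple[int, ...], squaring_steps: int = 6) -> "VelocityField":
        return cls(v=np.zeros((len(grid_shape), *grid_shape)), squaring_steps=squaring_steps)


@dataclass(frozen=True)
class DeformationField:
    """Map from template voxel coordinates to source coordinates.

    ``phi[i]`` holds the i-th coordinate of the pulled-back sample point,
    i.e. ``phi = identity + displacement``.
    """

    phi: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.phi.shape[1:]

    @property
    def displacement(self) -> np.ndarray:
        return self.phi - _identity_grid(self.grid_shape)


def _identity_grid(shape: tuple[int, ...]) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                                indexing="ij"))


def _sample_vector_field(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    # Displacements are extended by nearest-edge values outside the lattice;
    # images, by contrast, are zero-filled (see warp).
    return np.stack([
        ndimage.map_coordinates(field[i], coords, order=1, mode="nearest")
        for i in range(field.shape[0])
    ])


def exponentiate(v: VelocityField) -> DeformationField:
    """Integrate a stationary velocity by scaling and squaring.

    ``phi_0 = id + v / 2**K``, then ``phi_{k+1} = phi_k o phi_k`` applied K
    times.  Exponentiating ``-v`` yields the approximate inverse map.
    """
    v.validate()
    ident = _identity_grid(v.grid_shape)
    disp = v.v / (2.0 ** v.squaring_steps)
    for _ in range(v.squaring_steps):
        disp = disp + _sample_vector_field(disp, ident + disp)
    return DeformationField(phi=ident + disp)


def warp(image: np.ndarray, phi: DeformationField) -> np.ndarray:
    """Pull-back resampling of a concentration grid with linear interpolation.

    Samples outside the lattice read as background (0); output is clipped
    to [0, 1].
    """
    if image.shape != phi.grid_shape:
        raise ShapeError(f"image {image.shape} vs deformation {phi.grid_shape}")
    out = ndimage.map_coordinates(image, phi.phi, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def jacobian_determinant(phi: DeformationField) -> np.ndarray:
    """Per-voxel determinant of the spatial gradient of ``phi``.

    Central differences in the interior, one-sided at boundaries (the
    ``np.gradient`` scheme).  Positive everywhere for fields produced by
    ``exponentiate`` at realistic velocity magnitudes.
    """
    if not np.all(np.isfinite(phi.phi)):
        raise DataError("non-finite deformation")
    ndim = phi.phi.shape[0]
    jac = np.empty(phi.grid_shape + (ndim, ndim))
    for i in range(ndim):
        grads = np.gradient(phi.phi[i])
        if ndim == 1:
            grads = [grads]
        for j in range(ndim):
            jac[..., i, j] = grads[j]
    return np.linalg.det(jac)


def _warp_channels(moving: TissueMapSet, phi: DeformationField,
                   channels: tuple[str, ...]) -> list[np.ndarray]:
    return [warp(moving.tissue(c), phi) for c in channels]


def _ssd(warped: list[np.ndarray], fixed: list[np.ndarray]) -> float:
    return float(sum(np.sum((w - f) ** 2) for w, f in zip(warped, fixed)))


def register(moving: TissueMapSet, fixed_template: GroupTemplate | TissueMapSet,
             params: RegParams | None = None,
             init: VelocityField | None = None) -> VelocityField:
    """Estimate the velocity field matching ``moving`` to the template.

    Greedy demons over the selected channels: per iteration a demons force
    is computed from the SSD gradient between the template and the
    currently warped moving image, smoothed with ``fluid_sigma``, scaled by
    ``step_size`` and added to ``v``, which is then smoothed with
    ``diffusion_sigma``.  Updates that would raise the multichannel SSD are
    rejected (with step halving), so the returned velocity never fits worse
    than the initial one.

    ``init`` warm-starts the optimization, as used by iterative template
    building.
    """
    params = params or RegParams()
    check_same_lattice(moving.shape, fixed_template.shape)
    moving.validate()

    fixed = [np.asarray(fixed_template.tissue(c), dtype=float) for c in params.channels]
    for f in fixed:
        if not np.all(np.isfinite(f)):
            raise DataError("non-finite template")

    if init is not None:
        check_same_lattice(init.grid_shape, moving.shape)
        v = init.v.astype(float).copy()
    else:
        v = np.zeros((moving.ndim, *moving.shape))

    def evaluate(vel: np.ndarray) -> tuple[list[np.ndarray], float]:
        phi = exponentiate(VelocityField(vel, params.squaring_steps))
        warped = _warp_channels(moving, phi, params.channels)
        return warped, _ssd(warped, fixed)

    warped, current_ssd = evaluate(v)
    step = params.step_size
    rejections = 0
    for _ in range(params.n_iterations):
        force = np.zeros_like(v)
        for w, f in zip(warped, fixed):
            diff = f - w
            grads = np.gradient(w)
            if moving.ndim == 1:
                grads = [grads]
            gnorm2 = sum(g * g for g in grads)
            denom = gnorm2 + diff * diff
            scale = np.where(denom > 1e-9, diff / np.where(denom > 1e-9, denom, 1.0), 0.0)
            for i, g in enumerate(grads):
                force[i] += scale * g
        force = np.stack([ndimage.gaussian_filter(force[i], params.fluid_sigma)
                          for i in range(force.shape[0])])
        candidate = v + step * force
        candidate = np.stack([ndimage.gaussian_filter(candidate[i], params.diffusion_sigma)
                              for i in range(candidate.shape[0])])
        cand_warped, cand_ssd = evaluate(candidate)
        if cand_ssd <= current_ssd:
            v, warped, current_ssd = candidate, cand_warped, cand_ssd
            rejections = 0
        else:
            step *= 0.5
            rejections += 1
            if rejections >= 3:
                break
    return VelocityField(v=v, squaring_steps=params.squaring_steps)
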