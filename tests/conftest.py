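import numpy as np
import pytest

from groupvar import CohortParams, RegParams, generate_cohort

# Desk-scale analysis settings shared by the heavier tests: fewer demons
# iterations and outer template stages than the library defaults, purely to
# keep runtimes short.  All scientific conclusions tested here are about
# orderings and invariants, which are insensitive to this scaling.
FAST_REG = RegParams(n_iterations=12)
FAST_N_OUTER = 4


@pytest.fixture(scope="session")
def replica_cohort():
    """Full study-layout cohort: 24+24 core subjects plus the older extension pool."""
    return generate_cohort(CohortParams(master_seed=11))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small all-control cohort for fast pipeline-level tests."""
    return generate_cohort(CohortParams(n_tdc=10, n_asd=0, n_extension=0,
                                        master_seed=7))


def smooth_velocity(shape, max_norm, seed, squaring_steps=6,
                    margin=8, grad_cap=0.35):
    """Random smooth stationary velocity with a prescribed max vector norm.

    The field vanishes identically within ``margin`` voxels of the lattice
    boundary (so the flow never leaves the domain — the same interior-
    support convention the phantoms use) and its displacement gradient is
    capped at ``grad_cap`` so the field stays safely diffeomorphic; the
    overall magnitude is then scaled up to ``max_norm`` where that cap
    allows.
    """
    from scipy import ndimage

    from groupvar import VelocityField

    rng = np.random.default_rng(seed)
    v = rng.standard_normal((len(shape), *shape))
    v = np.stack([ndimage.gaussian_filter(v[i], 4.0) for i in range(len(shape))])
    window = np.ones(shape)
    for ax, n in enumerate(shape):
        x = np.arange(n, dtype=float)
        ramp = np.clip((np.minimum(x, n - 1 - x) - margin) / margin, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * ramp)  # C1 ramp from 0 to 1
        window *= w.reshape([-1 if a == ax else 1 for a in range(len(shape))])
    v *= window
    gmax = max(np.abs(g).max() for comp in v for g in np.gradient(comp))
    norm_max = np.sqrt((v ** 2).sum(axis=0)).max()
    v *= min(max_norm / norm_max, grad_cap / gmax)
    return VelocityField(v=v, squaring_steps=squaring_steps)
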