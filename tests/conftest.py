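"""Shared fixtures: digital shapes and rendered phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from panicle3d import NodeSpec, PhantomSpec, generate_phantom


def digital_ellipsoid(axes, rotation=None, center=(20.3, 20.1, 19.8), n=41):
    """Voxel coordinates of a digital solid ellipsoid (off-grid center)."""
    rotation = np.eye(3) if rotation is None else rotation
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    pts = np.stack([zz - center[0], yy - center[1], xx - center[2]], -1).astype(float)
    inside = (((pts @ rotation) / np.asarray(axes, float)) ** 2).sum(-1) <= 1.0
    return np.argwhere(inside)


def digital_ball_mask(radius, center, shape):
    zz, yy, xx = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
            + (xx - center[2]) ** 2) <= radius**2


def small_phantom_spec(rng_seed=1, **overrides):
    """A modest open-architecture phantom: 6 nodes, 5 seeds per branch."""
    kwargs = dict(
        height=40.0,
        nodes=[NodeSpec(float(a), branch_length=18.0) for a in np.linspace(8, 34, 6)],
        seeds_per_branch=5,
        touching_prob=0.0,
        noise_sd=0.0,
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    """Rendered noiseless phantom plus its ground truth (session cached)."""
    return generate_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def small_phantom_record(small_phantom):
    """Full pipeline output on the small phantom."""
    from panicle3d import extract_all_features
    from panicle3d.pipeline import PipelineConfig

    vol, truth = small_phantom
    record, details = extract_all_features(vol, PipelineConfig(), return_details=True)
    return record, details, truth
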