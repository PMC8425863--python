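"""Shared fixtures: phantom anatomy and (expensive) registrations are
session-scoped so recovery properties are exercised once and inspected by
several tests."""

import warnings

import numpy as np
import pytest

import ddalab as dl
from ddalab.registration import (RegistrationConfig, register_bspline,
                                 register_linear, resolve_dvf)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def spec():
    return dl.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def anatomy(spec):
    return dl.build_anatomy(spec)


@pytest.fixture(scope="session")
def noiseless_styles():
    return (dl.ReconStyle("fdk_like", 0.0), dl.ReconStyle("iterative_like", 0.0))


@pytest.fixture(scope="session")
def noiseless_day(spec, noiseless_styles):
    """A deformed day rendered without noise or artifacts."""
    return dl.make_daily_instance(spec, 1, styles=noiseless_styles)


@pytest.fixture(scope="session")
def registered_noiseless(spec, anatomy, noiseless_day):
    """Full four-stage chain run once on the noiseless deformed day."""
    pct, _ = anatomy
    day = noiseless_day
    fixed = day.images["iterative_like"]
    cfg = RegistrationConfig()
    chain = register_linear(fixed, pct, "translation", None, cfg, day.fov_mask)
    chain = register_linear(fixed, pct, "euler", chain, cfg, day.fov_mask)
    chain = register_linear(fixed, pct, "affine", chain, cfg, day.fov_mask)
    chain = register_bspline(fixed, pct, chain, cfg, day.fov_mask)
    dvf = resolve_dvf(chain, fixed)
    return {"chain": chain, "dvf": dvf, "fixed": fixed, "cfg": cfg}


def landmark_errors(day, dvf, n_points=50, seed=1):
    """Displacement errors (mm) vs the analytic truth at random in-FOV points."""
    rng = np.random.default_rng(seed)
    pts = dvf.grid.voxel_centers()[day.fov_mask]
    pts = pts[rng.choice(len(pts), size=n_points, replace=False)]
    truth = day.truth_dvf.analytic(pts)
    est = dvf.sample(pts, fill=np.nan)
    return np.linalg.norm(truth - est, axis=-1)
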