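import numpy as np
import pytest

from codasurv import Composition, PooledModel
from codasurv.survival import StudyFit


# Wald SEs backed out of the printed 95% CI half-widths of the pooled
# hip- and wrist-stratum coefficient tables.
HIP_GAMMA = {"z2": -0.073, "z3": -0.681}
HIP_SE = {"z2": (0.143 - 0.003) / (2 * 1.959963984540054),
          "z3": (0.875 - 0.486) / (2 * 1.959963984540054)}
WRIST_GAMMA = {"z1": -0.144, "z2": -0.465, "z3": -0.041}
WRIST_SE = {"z1": (0.402 + 0.114) / (2 * 1.959963984540054),
            "z2": (0.588 - 0.342) / (2 * 1.959963984540054),
            "z3": (0.415 + 0.333) / (2 * 1.959963984540054)}


@pytest.fixture(scope="session")
def hip_model() -> PooledModel:
    """Pooled hip-stratum model built from the published coefficient table."""
    return PooledModel(
        gamma=dict(HIP_GAMMA),
        vcov_gamma=np.diag([HIP_SE["z2"] ** 2, HIP_SE["z3"] ** 2]),
        psi=np.zeros((2, 2)),
        k_studies=4,
        stratum="hip",
    )


@pytest.fixture(scope="session")
def wrist_model() -> PooledModel:
    return PooledModel(
        gamma=dict(WRIST_GAMMA),
        vcov_gamma=np.diag([WRIST_SE[k] ** 2 for k in ("z1", "z2", "z3")]),
        psi=np.zeros((3, 3)),
        k_studies=2,
        stratum="wrist",
    )


@pytest.fixture
def hip_reference() -> Composition:
    """Reference waking composition used for the hip-stratum displays."""
    return Composition(mvpa=2, lipa=229, sb=729, total=960)


def make_fit(name, gamma, ses, *, placement="hip", corr=0.0, n=1000, n_events=100):
    """StudyFit fixture from coefficient dict + per-coordinate SEs."""
    names = list(gamma)
    k = len(names)
    se = np.array([ses[n_] for n_ in names])
    v = np.outer(se, se) * (np.full((k, k), corr) + (1 - corr) * np.eye(k))
    return StudyFit(
        study_name=name,
        gamma=dict(gamma),
        beta={},
        vcov_gamma=v,
        n=n,
        n_events=n_events,
        measures_sleep="z1" in gamma,
        device_placement=placement,
    )
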