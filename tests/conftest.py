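import numpy as np
import pytest

from mtbond import (
    AnisotropicBond,
    MotorLinkage,
    PullingProtocol,
    RateLaw,
    TrapConfig,
)


@pytest.fixture
def nominal_trap() -> TrapConfig:
    """Weak-binding operating point: 0.025 pN/nm x 225 nm/s = 5.625 pN/s."""
    return TrapConfig(k_trap=0.025, v_stage=225.0, f_sample=2000.0,
                      sigma_noise=0.08, tau_bead=0.005)


@pytest.fixture
def noiseless_trap() -> TrapConfig:
    return TrapConfig(k_trap=0.025, v_stage=225.0, f_sample=2000.0,
                      sigma_noise=0.0, tau_bead=0.005)


@pytest.fixture
def rigid_link() -> MotorLinkage:
    return MotorLinkage()


@pytest.fixture
def constant_pull() -> PullingProtocol:
    return PullingProtocol(mode="constant_pull", sweep_duration=10.0)


@pytest.fixture
def ideal_bond() -> AnisotropicBond:
    """Force-independent bond with a high force cap (negligible censoring)."""
    law = RateLaw.ideal(1.0, F_max=120.0)
    return AnisotropicBond(forward=law, backward=law)


@pytest.fixture
def wt_like_bond() -> AnisotropicBond:
    """Slip forward / slip-ideal backward, the anisotropy seen in the motor."""
    return AnisotropicBond(
        forward=RateLaw.bell_slip(0.9, 1.0),
        backward=RateLaw.slip_ideal(0.5, 1.2, 2.0),
    )


def match_events_by_time(truth_events, detected_events, tol=0.05):
    """Pair truth and detected events whose rupture times agree within tol."""
    pairs = []
    used = set()
    for te in truth_events:
        best, best_dt = None, tol
        for j, de in enumerate(detected_events):
            if j in used:
                continue
            dt = abs(de.t_unbind - te.t_unbind)
            if dt <= best_dt:
                best, best_dt = j, dt
        if best is not None:
            used.add(best)
            pairs.append((te, detected_events[best]))
    return pairs
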