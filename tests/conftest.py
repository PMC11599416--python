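import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spectkin as sk
from spectkin.synthetic_data import MYOCARDIUM_PARAMS, SHEET_PARAMS

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol_schedule():
    """The study's two-phase acquisition: 8 x 2.5 min + 8 x 20 min."""
    return sk.build_frame_schedule([(8, 2.5), (8, 20.0)])


@pytest.fixture(scope="session")
def default_aif():
    return sk.simulate_aif()


@pytest.fixture(scope="session")
def sheet_params():
    return SHEET_PARAMS


@pytest.fixture(scope="session")
def myocardium_params():
    return MYOCARDIUM_PARAMS


@pytest.fixture(scope="session")
def sheet_tac(sheet_params, default_aif, protocol_schedule):
    """Noiseless sheet-region TAC on the study protocol."""
    return sk.simulate_tissue_tac(sheet_params, default_aif, protocol_schedule)


def brute_force_tissue_curve(params, aif, eval_times, dt=0.001, va_formulation="standard"):
    """Independent oracle: trapezoidal convolution on a fine grid.

    Interpolates the plasma curve onto a dt-spaced grid and evaluates
    K1 * INT_0^T Cp(s) exp(-k2 (T - s)) ds by the trapezoid rule for each
    requested T, then adds the blood-volume term.
    """
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    out = np.empty(eval_times.size)
    tf = np.arange(0.0, eval_times.max() + dt, dt)
    cp = np.interp(tf, aif.times_min, aif.cp, left=0.0)
    cb_at = np.interp(eval_times, aif.times_min, aif.cb, left=0.0)
    for i, T in enumerate(eval_times):
        m = tf <= T + 1e-12
        integrand = cp[m] * np.exp(-params.k2 * (T - tf[m]))
        ct = params.k1 * np.trapezoid(integrand, tf[m])
        if va_formulation == "standard":
            out[i] = (1.0 - params.va) * ct + params.va * cb_at[i]
        else:
            out[i] = ct + params.va * cb_at[i]
    return out
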