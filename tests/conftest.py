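"""Shared fixtures: constructed pulse shapes with known fiducial geometry."""

import numpy as np
import pytest

from nirspulse.signals import ArterialPulsationSignal

FS_ACQ = 39.0625  # acquisition sampling rate used across tests (Hz)


def piecewise_two_cycle(decline: str = "linear", fs: float = FS_ACQ,
                        ) -> tuple[ArterialPulsationSignal, dict]:
    """Two-cycle pulse with exactly known diastolic minima and systolic peak.

    Cycle 1 dips to the diastolic minimum, rises to a systolic peak of 1.0,
    then declines to 0.0 at the cycle-2 diastolic minimum with a chosen
    profile (linear / convex / concave); the epoch ends on a partial rise.
    Breakpoints sit exactly on samples so trapezoidal integration of the
    linear profile is exact.
    """
    n = int(round(1.8 * fs))            # 1.8 s epoch at 1.0 s median R-R
    n_cycle = int(round(fs))
    i_d1, i_s = 2, max(6, int(round(0.2 * fs)))
    i_d2 = n_cycle + max(2, int(round(0.18 * fs)))
    s = np.empty(n)
    s[: i_d1 + 1] = np.linspace(0.1, -0.5, i_d1 + 1)
    s[i_d1: i_s + 1] = np.linspace(-0.5, 1.0, i_s - i_d1 + 1)
    u = np.linspace(0.0, 1.0, i_d2 - i_s + 1)
    profile = {
        "linear": 1.0 - u,
        "convex": (1.0 - u) ** 2,
        "concave": 1.0 - u ** 2,
    }[decline]
    s[i_s: i_d2 + 1] = profile
    s[i_d2:] = np.linspace(0.0, 0.4, n - i_d2)
    sig = ArterialPulsationSignal(samples=s, fs=fs, epoch_length=n / fs,
                                  n_epochs_averaged=1, median_rr=1.0,
                                  channel_id="constructed")
    truth = {"i_d1": i_d1, "i_s": i_s, "i_d2": i_d2,
             "t_d1": i_d1 / fs, "t_s": i_s / fs, "t_d2": i_d2 / fs}
    return sig, truth


@pytest.fixture
def two_cycle_linear():
    return piecewise_two_cycle("linear")


@pytest.fixture
def two_cycle_convex():
    return piecewise_two_cycle("convex", fs=250.0)


@pytest.fixture
def two_cycle_concave():
    return piecewise_two_cycle("concave", fs=250.0)
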