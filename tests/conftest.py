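"""Shared fixtures: analytic beats, loops and feature tables with known truth."""

import numpy as np
import pytest

from vcglvh import Fiducials, MedianBeat12, default_beat_spec, make_beat
from vcglvh.beats import INDEPENDENT_LEADS, LEAD_NAMES
from vcglvh.loops import Loop


@pytest.fixture
def fid600():
    """Standard fiducials for a 600-sample beat at 500 Hz."""
    return Fiducials(p_on=40, p_off=100, qrs_on=150, qrs_off=200, t_off=380)


@pytest.fixture
def zero_beat(fid600):
    return MedianBeat12(np.zeros((12, 600)), fs=500.0, fiducials=fid600)


def build_beat(lead_values: dict, n: int = 600, fs: float = 500.0,
               fiducials=None) -> MedianBeat12:
    """Beat with the given per-lead sample arrays (uV); others zero."""
    samples = np.zeros((12, n))
    for name, vals in lead_values.items():
        samples[LEAD_NAMES.index(name)] = vals
    return MedianBeat12(samples, fs=fs, fiducials=fiducials)


@pytest.fixture
def clean_beat():
    """Noise-free default template beat with ground-truth fiducials."""
    spec = default_beat_spec(noise_sd_uv=0.0)
    beat, fid = make_beat(spec, rng=0)
    return beat, fid, spec


def circle_loop(r: float = 100.0, m: int = 100, dt_ms: float = 2.0,
                center=(0.0, 0.0, 0.0), plane: str = "xy",
                revolutions: float = 1.0) -> Loop:
    """Planar circle of radius r traversed at constant angular velocity.

    Endpoint excluded so that closing the polygon completes the revolution.
    """
    theta = np.linspace(0.0, 2 * np.pi * revolutions, m, endpoint=False)
    u = r * np.cos(theta)
    v = r * np.sin(theta)
    zeros = np.zeros(m)
    planes = {"xy": (u, v, zeros), "xz": (u, zeros, v), "yz": (zeros, u, v)}
    pts = np.column_stack(planes[plane]) + np.asarray(center, dtype=float)
    return Loop(points=pts, dt_ms=dt_ms, wave="QRS")


def impulse_beat(lead: str, amplitude_uv: float = 1000.0,
                 n: int = 600) -> MedianBeat12:
    """Constant (step) signal on one independent lead, zero elsewhere."""
    assert lead in INDEPENDENT_LEADS
    return build_beat({lead: np.full(n, amplitude_uv)}, n=n)
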