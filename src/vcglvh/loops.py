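"""P/QRS/T loop segmentation and geometric loop features.

A *loop* is the ordered 3-D curve traced by the cardiac electrical vector
during one wave.  This module delineates the wave windows from the spatial
velocity of the Kors-synthesized VCG (user-supplied fiducials always win),
cuts the loops out of any VCG signal, and computes:

* per-decile features — mean vector magnitude, mean speed, and orbital
  frequency (revolutions per ms of the vector about the loop centroid) in
  each temporal tenth of the wave;
* global features — the dimensionless geometric area vector (GAV), the
  rotation-angle range in the loop's least-squares plane, speed extrema, and
  the terminal-vector magnitude.

Angles are handled internally in radians; the rotation-angle range is
reported in degrees, matching the conventional printed unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import Fiducials, MedianBeat12
from .transforms import VcgSignal, synthesize

#: spatial-velocity threshold for wave delineation, fraction of window max
VELOCITY_THRESHOLD = 0.10

#: terminal-vector averaging window, ms (conventional terminal-conduction span)
TERMINAL_MS = 40.0

WAVES = ("P", "QRS", "T")


class NoQrsError(RuntimeError):
    """Raised when the spatial velocity never rises above threshold."""


@dataclass
class Loop:
    """Ordered M x 3 point sequence (uV) for one wave of one method."""

    points: np.ndarray
    dt_ms: float
    wave: str
    method: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be M x 3, got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite loop point")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# Delineation
# ---------------------------------------------------------------------------

def _spatial_velocity(sig: VcgSignal) -> np.ndarray:
    """Per-step speed ||dxyz||/dt in uV/ms; length N-1."""
    d = np.diff(sig.xyz, axis=0)
    return np.linalg.norm(d, axis=1) / sig.dt_ms


def _threshold_window(sv: np.ndarray, lo: int, hi: int) -> tuple[int, int] | None:
    """First/last index in [lo, hi) where sv exceeds 10% of its local max."""
    seg = sv[lo:hi]
    if seg.size == 0 or seg.max() <= 0:
        return None
    above = np.nonzero(seg >= VELOCITY_THRESHOLD * seg.max())[0]
    return lo + int(above[0]), lo + int(above[-1]) + 1


def detect_fiducials(beat: MedianBeat12,
                     fiducials: Fiducials | None = None) -> Fiducials:
    """Delineate P, QRS and T by spatial-velocity thresholding on the Kors VCG.

    QRS on/off bracket the contiguous region around the global speed maximum
    where speed exceeds 10% of that maximum; P and T bounds apply the same
    10%-of-local-max rule to the pre-/post-QRS windows.  Fiducials supplied on
    the beat or as an argument are returned unchanged.
    """
    if fiducials is not None:
        return fiducials
    if beat.fiducials is not None:
        return beat.fiducials

    sig = synthesize(beat, "kors")
    sv = _spatial_velocity(sig)
    if sv.size == 0 or sv.max() <= 0:
        raise NoQrsError("no QRS detected: spatial velocity is identically zero")

    peak = int(np.argmax(sv))
    thr = VELOCITY_THRESHOLD * sv[peak]
    on = peak
    while on > 0 and sv[on - 1] >= thr:
        on -= 1
    off = peak
    while off < sv.size - 1 and sv[off + 1] >= thr:
        off += 1
    qrs_on, qrs_off = on, min(off + 2, beat.n_samples - 1)
    if qrs_on < 2:
        raise NoQrsError(
            "QRS onset abuts the window start; no room for a P wave")

    p_win = _threshold_window(sv, 0, max(qrs_on - 1, 0))
    if p_win is None:
        p_on, p_off = max(qrs_on - 2, 0), max(qrs_on - 1, 1)
    else:
        p_on, p_off = p_win[0], p_win[1] + 1
    p_off = min(p_off, qrs_on)
    p_on = min(p_on, p_off - 1)

    t_win = _threshold_window(sv, qrs_off, sv.size)
    if t_win is None:
        t_off = min(qrs_off + 2, beat.n_samples)
    else:
        t_off = min(t_win[1] + 1, beat.n_samples)
    if t_off <= qrs_off:
        t_off = qrs_off + 1

    return Fiducials(p_on=p_on, p_off=p_off, qrs_on=qrs_on,
                     qrs_off=qrs_off, t_off=t_off)


def segment_loops(sig: VcgSignal, fid: Fiducials) -> dict[str, Loop]:
    """Cut the P, QRS and T loops out of a VCG signal at the wave windows."""
    fid.validate_against(sig.n_samples)
    windows = {"P": (fid.p_on, fid.p_off),
               "QRS": (fid.qrs_on, fid.qrs_off),
               "T": (fid.qrs_off, fid.t_off)}
    loops = {}
    for wave, (on, off) in windows.items():
        if off - on < 2:
            raise ValueError(f"{wave} window [{on}, {off}) has < 2 samples")
        loops[wave] = Loop(points=sig.xyz[on:off], dt_ms=sig.dt_ms,
                           wave=wave, method=sig.method)
    return loops


# ---------------------------------------------------------------------------
# Decile features
# ---------------------------------------------------------------------------

def _decile_slices(m: int) -> list[tuple[int, int]]:
    return [(int(np.floor((d - 1) * m / 10)), int(np.floor(d * m / 10)))
            for d in range(1, 11)]


def decile_features(loop: Loop) -> dict[str, np.ndarray]:
    """Per-decile magnitude (uV), speed (uV/ms) and orbital frequency (1/ms).

    Decile d holds the samples with index in [floor((d-1)M/10), floor(dM/10)).
    Magnitude averages ||p||; speed averages forward-difference step speeds;
    orbital frequency is the unsigned angle (in revolutions) swept about the
    loop centroid across the decile, per ms of decile duration.  The angular
    sweep treats the loop as closed (last point joined to first).
    """
    m = loop.n_points
    if m < 10:
        raise ValueError(f"decile features need >= 10 points, got {m}")
    pts = loop.points
    mags = np.linalg.norm(pts, axis=1)
    step = np.linalg.norm(np.diff(pts, axis=0), axis=1) / loop.dt_ms  # M-1

    centroid = pts.mean(axis=0)
    rel = pts - centroid
    nxt = np.roll(rel, -1, axis=0)              # closed polygon: wrap last->first
    cross = np.linalg.norm(np.cross(rel, nxt), axis=1)
    dot = np.einsum("ij,ij->i", rel, nxt)
    angles = np.abs(np.arctan2(cross, dot))     # M step angles, radians

    mag = np.empty(10)
    vel = np.empty(10)
    orb = np.empty(10)
    for i, (lo, hi) in enumerate(_decile_slices(m)):
        mag[i] = mags[lo:hi].mean()
        v_hi = min(hi, m - 1)
        vel[i] = step[lo:v_hi].mean() if v_hi > lo else step[m - 2]
        revs = angles[lo:hi].sum() / (2 * np.pi)
        orb[i] = revs / ((hi - lo) * loop.dt_ms)
    return {"Mag": mag, "Vel": vel, "OrbFrq": orb}


# ---------------------------------------------------------------------------
# Global features
# ---------------------------------------------------------------------------

def global_features(loop: Loop) -> dict[str, float]:
    """GAV, rotation-angle range (degrees), speed extrema and terminal vector.

    * vector area A = 1/2 sum(p_i x p_{i+1}) over the closed polygon;
      GAV = ||A|| / max||p||^2 (dimensionless); the raw area magnitude in
      uV^2 is emitted as ``GAV_raw``;
    * RangeAng = range of the unwrapped rotation angle of the points
      projected on the least-squares plane, about the centroid, in degrees;
    * VelMin/VelMax = extrema of the forward-difference speed, uV/ms;
    * TermMag = mean vector over the final 40 ms, magnitude in mV.
    """
    pts = loop.points
    m = loop.n_points
    if m < 3:
        raise ValueError("global features need >= 3 points")

    nxt = np.roll(pts, -1, axis=0)
    area_vec = 0.5 * np.cross(pts, nxt).sum(axis=0)
    area_mag = float(np.linalg.norm(area_vec))
    max_mag = float(np.linalg.norm(pts, axis=1).max())
    gav = area_mag / max_mag ** 2 if max_mag > 0 else 0.0

    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0):
        range_ang = 0.0
    else:
        # least-squares plane via SVD; in-plane coordinates are the first
        # two principal directions
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        uv = centered @ vt[:2].T
        theta = np.unwrap(np.arctan2(uv[:, 1], uv[:, 0]))
        range_ang = float(np.degrees(theta.max() - theta.min()))

    step = np.linalg.norm(np.diff(pts, axis=0), axis=1) / loop.dt_ms
    vel_min = float(step.min())
    vel_max = float(step.max())

    n_term = max(1, int(round(TERMINAL_MS / loop.dt_ms)))
    term_mag = float(np.linalg.norm(pts[-n_term:].mean(axis=0))) / 1000.0

    return {"GAV": gav, "GAV_raw": area_mag, "RangeAng": range_ang,
            "VelMin": vel_min, "VelMax": vel_max, "TermMag": term_mag}
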