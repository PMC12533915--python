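"""12-lead median-beat data model, I/O, and scalar ECG measurements.

A *median beat* is one representative averaged cardiac cycle.  The package
stores it as a 12 x N matrix of amplitudes in microvolts (uV) with a declared
sampling rate.  Voltages handed to the LVH criteria are expressed in
millivolts (mV); the conversion happens only at this module's boundary.

Windows are half-open ``[on, off)`` on 0-based sample indices throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: the eight linearly independent leads, in the order the VCG transforms expect
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: one Ashman unit of ECG area = 40 ms x 0.1 mV = 4 ms*mV
ASHMAN_MS_MV = 4.0

#: baseline window length preceding P onset, ms
BASELINE_MS = 20.0


class BeatFormatError(ValueError):
    """Raised for malformed beat files or invalid beat matrices."""


@dataclass(frozen=True)
class Fiducials:
    """Wave boundaries as 0-based sample indices, half-open segments.

    ``[p_on, p_off)`` is the P wave, ``[qrs_on, qrs_off)`` the QRS complex and
    ``[qrs_off, t_off)`` the T wave (ST segment included with the T window).
    """

    p_on: int
    p_off: int
    qrs_on: int
    qrs_off: int
    t_off: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_on < self.p_off <= self.qrs_on
                < self.qrs_off < self.t_off):
            raise ValueError(
                f"fiducials must satisfy 0 <= p_on < p_off <= qrs_on < "
                f"qrs_off < t_off, got {self}")

    def validate_against(self, n_samples: int) -> None:
        if self.t_off > n_samples:
            raise ValueError(
                f"t_off={self.t_off} exceeds beat length {n_samples}")


@dataclass
class MedianBeat12:
    """One averaged cardiac cycle across the standard 12 leads.

    Attributes
    ----------
    samples : (12, N) float array, amplitudes in uV, row order ``LEAD_NAMES``.
    fs : sampling rate in Hz.
    fiducials : optional wave boundaries.
    """

    samples: np.ndarray
    fs: float
    fiducials: Fiducials | None = None
    lead_names: tuple[str, ...] = field(default=LEAD_NAMES)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 12:
            raise BeatFormatError(
                f"expected a 12 x N sample matrix, got shape "
                f"{self.samples.shape}")
        if self.samples.shape[1] < 2:
            raise BeatFormatError("beat must have at least 2 samples per lead")
        if not np.all(np.isfinite(self.samples)):
            bad = np.argwhere(~np.isfinite(self.samples))[0]
            raise BeatFormatError(
                f"non-finite amplitude in lead {LEAD_NAMES[bad[0]]} "
                f"at sample {bad[1]}")
        if self.fs <= 0:
            raise BeatFormatError(f"sampling rate must be positive, got {self.fs}")
        if tuple(self.lead_names) != LEAD_NAMES:
            raise BeatFormatError(f"lead names must be {LEAD_NAMES}")
        if self.fiducials is not None:
            self.fiducials.validate_against(self.n_samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.samples[LEAD_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown lead {name!r}") from None

    def independent_leads(self) -> np.ndarray:
        """The (8, N) submatrix of leads I, II, V1..V6 feeding VCG transforms."""
        idx = [LEAD_NAMES.index(n) for n in INDEPENDENT_LEADS]
        return self.samples[idx]

    @classmethod
    def from_independent(cls, leads8: Mapping[str, np.ndarray], fs: float,
                         fiducials: Fiducials | None = None) -> "MedianBeat12":
        """Build a full beat from the 8 independent leads.

        III, aVR, aVL, aVF follow from I and II by the Einthoven/Goldberger
        relations: III = II - I, aVR = -(I + II)/2, aVL = I - II/2,
        aVF = II - I/2.
        """
        missing = [n for n in INDEPENDENT_LEADS if n not in leads8]
        if missing:
            raise BeatFormatError(f"missing independent leads: {missing}")
        one = np.asarray(leads8["I"], dtype=float)
        two = np.asarray(leads8["II"], dtype=float)
        derived = {
            "III": two - one,
            "aVR": -(one + two) / 2.0,
            "aVL": one - two / 2.0,
            "aVF": two - one / 2.0,
        }
        rows = []
        for name in LEAD_NAMES:
            rows.append(derived[name] if name in derived
                        else np.asarray(leads8[name], dtype=float))
        return cls(np.vstack(rows), fs=fs, fiducials=fiducials)

    def scaled(self, k: float) -> "MedianBeat12":
        return replace(self, samples=self.samples * k)


@dataclass
class LeadMeasurements:
    """Scalar per-lead measurements feeding the classical LVH criteria.

    Amplitudes are positive magnitudes in mV (R = tallest positive deflection
    above baseline, S = deepest negative deflection below baseline within the
    QRS window; R'/S' are secondary deflections).  ``t_area_au`` holds signed
    T-wave areas in Ashman units (1 AU = 40 ms x 0.1 mV).
    """

    r: dict[str, float]
    s: dict[str, float]
    r_prime: dict[str, float]
    s_prime: dict[str, float]
    qrs_duration_ms: float
    t_area_au: dict[str, float]
    t_polarity: dict[str, int]
    frontal_axis_deg: float
    ptf_v1_mm_s: float
    intrinsicoid_ms: dict[str, float]

    def __post_init__(self) -> None:
        for d in (self.r, self.s, self.r_prime, self.s_prime):
            for lead, v in d.items():
                if v < 0:
                    raise ValueError(f"negative amplitude magnitude for {lead}")
        if self.qrs_duration_ms <= 0:
            raise ValueError("QRS duration must be positive")

    # -- criterion symbols -------------------------------------------------
    @property
    def RaVL(self) -> float:
        return self.r["aVL"]

    @property
    def SV1(self) -> float:
        return self.s["V1"]

    @property
    def SV3(self) -> float:
        return self.s["V3"]

    @property
    def SV4(self) -> float:
        return self.s["V4"]

    @property
    def RV5(self) -> float:
        return self.r["V5"]

    @property
    def RV6(self) -> float:
        return self.r["V6"]

    @property
    def deepest_s_lead(self) -> str:
        return max(self.s, key=lambda k: self.s[k])

    @property
    def SD(self) -> float:
        """Deepest S amplitude across all 12 leads (mV)."""
        return max(self.s.values())

    def symbols(self) -> dict[str, float]:
        """Flat symbol table used by the declarative criteria registry."""
        out: dict[str, float] = {}
        for lead in LEAD_NAMES:
            out[f"R{lead}"] = self.r[lead]
            out[f"S{lead}"] = self.s[lead]
        out["SD"] = self.SD
        out["QRSd"] = self.qrs_duration_ms
        out["PTFV1"] = self.ptf_v1_mm_s
        out["Axis"] = self.frontal_axis_deg
        for lead in LEAD_NAMES:
            out[f"Tarea{lead}"] = self.t_area_au[lead]
        return out

    def to_flat_dict(self) -> dict[str, float]:
        flat = self.symbols()
        flat.update({f"Rp{k}": v for k, v in self.r_prime.items()})
        flat.update({f"Sp{k}": v for k, v in self.s_prime.items()})
        return flat


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_metadata_line(line: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for tok in line.lstrip("#").replace(",", " ").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k.strip().lower()] = v.strip()
    return meta


def read_median_beat(path: str | Path, format_hint: str = "csv") -> MedianBeat12:
    """Read a median beat from disk and return it in canonical uV.

    The CSV dialect is: optional leading ``#``-comment metadata lines
    declaring ``fs=<Hz>`` and ``units=<uV|mV>`` (alternatively a JSON sidecar
    ``<path>.meta.json`` with keys ``fs`` and ``units``), then a header row of
    lead names, then one row per sample with one column per lead.
    """
    path = Path(path)
    if format_hint == "waveform_record":
        raise BeatFormatError(
            "waveform_record input is not supported in this build; "
            "convert the record to the documented CSV dialect")
    if format_hint != "csv":
        raise BeatFormatError(f"unknown format hint {format_hint!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict[str, str] = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta.update({k.lower(): str(v)
                     for k, v in json.loads(sidecar.read_text()).items()})

    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            meta.update(_parse_metadata_line(line))
            body_start = i + 1
        else:
            break

    if "fs" not in meta:
        raise BeatFormatError(f"{path}: no sampling rate declared (fs=...)")
    if "units" not in meta:
        raise BeatFormatError(f"{path}: no amplitude units declared (units=...)")
    units = meta["units"].lower()
    if units in ("uv", "µv", "microvolt", "microvolts"):
        scale = 1.0
    elif units in ("mv", "millivolt", "millivolts"):
        scale = 1000.0
    else:
        raise BeatFormatError(f"{path}: unknown units {meta['units']!r}")
    fs = float(meta["fs"])

    header = [h.strip() for h in lines[body_start].split(",")]
    missing = [n for n in LEAD_NAMES if n not in header]
    if missing:
        raise BeatFormatError(f"{path}: missing lead column(s) {missing}")
    data = np.genfromtxt(lines[body_start + 1:], delimiter=",", dtype=float)
    data = np.atleast_2d(data)
    cols = {name: data[:, header.index(name)] for name in LEAD_NAMES}
    samples = np.vstack([cols[n] for n in LEAD_NAMES]) * scale

    fid = None
    fid_keys = ("p_on", "p_off", "qrs_on", "qrs_off", "t_off")
    if all(k in meta for k in fid_keys):
        fid = Fiducials(**{k: int(meta[k]) for k in fid_keys})
    return MedianBeat12(samples, fs=fs, fiducials=fid)


def write_median_beat(beat: MedianBeat12, path: str | Path,
                      units: str = "uV") -> None:
    """Write a beat to the CSV dialect read back by :func:`read_median_beat`."""
    path = Path(path)
    scale = 1.0 if units.lower() == "uv" else 1e-3
    meta = f"# fs={beat.fs} units={units}"
    if beat.fiducials is not None:
        f = beat.fiducials
        meta += (f" p_on={f.p_on} p_off={f.p_off} qrs_on={f.qrs_on}"
                 f" qrs_off={f.qrs_off} t_off={f.t_off}")
    with path.open("w") as fh:
        fh.write(meta + "\n")
        fh.write(",".join(LEAD_NAMES) + "\n")
        for row in (beat.samples.T * scale):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def _baseline(sig: np.ndarray, fid: Fiducials, fs: float) -> float:
    """Mean amplitude over the 20 ms preceding P onset, clamped to the start.

    If P onset sits at the very first sample the window is empty and the
    onset sample itself serves as the baseline.
    """
    start = max(0, fid.p_on - int(round(BASELINE_MS / 1000.0 * fs)))
    if start >= fid.p_on:
        return float(sig[fid.p_on])
    return float(np.mean(sig[start:fid.p_on]))


def _secondary_deflections(seg: np.ndarray, base: float) -> tuple[float, float]:
    """Secondary positive (R') and negative (S') QRS deflections, in uV.

    A secondary deflection is a local extremum of the same polarity occurring
    after the primary one, separated from it by a baseline crossing.
    """
    from scipy.signal import find_peaks

    x = seg - base
    r_prime = s_prime = 0.0
    pos, _ = find_peaks(x)
    pos = [i for i in pos if x[i] > 0]
    if len(pos) >= 2:
        main = max(pos, key=lambda i: x[i])
        later = [i for i in pos if i > main and np.any(x[main:i] < 0)]
        if later:
            r_prime = float(max(x[i] for i in later))
    neg, _ = find_peaks(-x)
    neg = [i for i in neg if x[i] < 0]
    if len(neg) >= 2:
        main = max(neg, key=lambda i: -x[i])
        later = [i for i in neg if i > main and np.any(x[main:i] > 0)]
        if later:
            s_prime = float(max(-x[i] for i in later))
    return r_prime, s_prime


def measure_amplitudes(beat: MedianBeat12, fid: Fiducials) -> LeadMeasurements:
    """Extract R/S amplitudes, QRS duration, T areas and auxiliary scalars.

    All amplitudes are baseline-corrected positive magnitudes in mV; the
    baseline is the mean over the 20 ms preceding P onset.
    """
    fid.validate_against(beat.n_samples)
    if fid.qrs_off - fid.qrs_on < 2:
        raise ValueError("QRS window must span at least 2 samples")

    r: dict[str, float] = {}
    s: dict[str, float] = {}
    rp: dict[str, float] = {}
    sp: dict[str, float] = {}
    t_area: dict[str, float] = {}
    t_pol: dict[str, int] = {}
    qrs_net_area: dict[str, float] = {}

    for name in LEAD_NAMES:
        sig = beat.lead(name)
        base = _baseline(sig, fid, beat.fs)
        qrs = sig[fid.qrs_on:fid.qrs_off]
        r[name] = max(0.0, float(qrs.max()) - base) / 1000.0
        s[name] = max(0.0, base - float(qrs.min())) / 1000.0
        rprime, sprime = _secondary_deflections(qrs, base)
        rp[name] = rprime / 1000.0
        sp[name] = sprime / 1000.0
        qrs_net_area[name] = float(np.trapezoid(qrs - base, dx=beat.dt_ms))
        t_area[name] = t_wave_area(beat, name, fid)
        twin = sig[fid.qrs_off:fid.t_off] - base
        t_pol[name] = 0 if twin.size == 0 or np.all(twin == 0) else (
            1 if twin[np.argmax(np.abs(twin))] > 0 else -1)

    qrs_duration_ms = (fid.qrs_off - fid.qrs_on) / beat.fs * 1000.0

    # frontal-plane QRS axis from the net areas in leads I and aVF
    axis = float(np.degrees(np.arctan2(qrs_net_area["aVF"], qrs_net_area["I"])))

    # P terminal force in V1: depth (mm) x duration (s) of the terminal
    # negative P portion; 1 mm = 0.1 mV at standard gain
    v1 = beat.lead("V1")
    base_v1 = _baseline(v1, fid, beat.fs)
    p_seg = v1[fid.p_on:fid.p_off] - base_v1
    ptf = 0.0
    neg = np.nonzero(p_seg < 0)[0]
    if neg.size:
        # terminal contiguous negative run
        end = neg[-1]
        start = end
        while start > 0 and p_seg[start - 1] < 0:
            start -= 1
        depth_mm = -p_seg[start:end + 1].min() / 1000.0 * 10.0
        dur_s = (end - start + 1) / beat.fs
        ptf = depth_mm * dur_s

    # intrinsicoid deflection (R-peak time from QRS onset) in V5/V6, ms
    intr: dict[str, float] = {}
    for name in ("V5", "V6"):
        seg = beat.lead(name)[fid.qrs_on:fid.qrs_off]
        intr[name] = float(np.argmax(seg)) / beat.fs * 1000.0

    return LeadMeasurements(
        r=r, s=s, r_prime=rp, s_prime=sp,
        qrs_duration_ms=qrs_duration_ms,
        t_area_au=t_area, t_polarity=t_pol,
        frontal_axis_deg=axis, ptf_v1_mm_s=ptf,
        intrinsicoid_ms=intr,
    )


def t_wave_area(beat: MedianBeat12, lead: str, fid: Fiducials) -> float:
    """Signed T-wave area in Ashman units (1 AU = 40 ms x 0.1 mV).

    The T window is ``[qrs_off, t_off)``; the signed trapezoidal integral of
    the baseline-corrected signal in ms*mV is divided by 4 ms*mV per AU.
    """
    fid.validate_against(beat.n_samples)
    sig = beat.lead(lead)
    base = _baseline(sig, fid, beat.fs)
    twin = sig[fid.qrs_off:fid.t_off]
    if twin.size < 2:
        raise ValueError("empty or single-sample T window")
    area_ms_uv = float(np.trapezoid(twin - base, dx=beat.dt_ms))
    return area_ms_uv / 1000.0 / ASHMAN_MS_MV
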