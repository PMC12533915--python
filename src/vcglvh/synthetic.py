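"""Synthetic 12-lead median beats, cohorts and feature tables.

The beat model is a sum of Gaussian wavelets per wave and lead — chosen for
analytic ground truth: peak amplitudes, areas and wave windows are known in
closed form, so the generator doubles as the oracle in tests.  The default
template produces a physiologic precordial R progression (V1 through V6) with
limb leads III/aVR/aVL/aVF derived from I and II by the Einthoven/Goldberger
relations.

The cohort generator emulates the study conditions the analysis assumes: 664
patients at 42.8% LVH prevalence, LVH beats carrying amplified QRS voltages
(multiplicative lognormal gain), optional lateral T-wave inversion (strain)
and shrunken T areas, plus covariates (sex, age, BMI, hypertension, ischemic
heart disease, LV geometry, severity) drawn from the cohort's marginal rates.
Covariates are independent of the waveform given the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .beats import INDEPENDENT_LEADS, Fiducials, MedianBeat12, write_median_beat

LATERAL_LEADS = ("I", "V5", "V6")  # aVL follows from I and II


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian wavelet: amplitude * exp(-(t - center)^2 / (2 width^2))."""
    center_ms: float
    width_ms: float
    amplitude_uv: float

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("wavelet width must be positive")


@dataclass
class BeatSpec:
    """Per-lead Gaussian components for each wave, plus noise and timing."""

    p: dict[str, list[WaveComponent]]
    qrs: dict[str, list[WaveComponent]]
    t: dict[str, list[WaveComponent]]
    fs: float = 500.0
    length_ms: float = 1000.0
    noise_sd_uv: float = 6.0

    def wave_window_ms(self, wave: str) -> tuple[float, float]:
        """Ground-truth window: +/- 3 sigma around the wave's components."""
        comps = [c for lead in getattr(self, wave).values() for c in lead]
        comps = [c for c in comps if c.amplitude_uv != 0] or comps
        lo = min(c.center_ms - 3 * c.width_ms for c in comps)
        hi = max(c.center_ms + 3 * c.width_ms for c in comps)
        return lo, hi

    def scaled_qrs(self, k: float) -> "BeatSpec":
        return self.scaled(k, waves=("qrs",))

    def scaled(self, k: float,
               waves: tuple[str, ...] = ("p", "qrs", "t")) -> "BeatSpec":
        """Multiply the amplitudes of the named waves by ``k``."""
        updates = {}
        for wave in waves:
            updates[wave] = {
                lead: [replace(c, amplitude_uv=c.amplitude_uv * k)
                       for c in comps]
                for lead, comps in getattr(self, wave).items()}
        return replace(self, **updates)


def default_beat_spec(noise_sd_uv: float = 6.0) -> BeatSpec:
    """The template non-LVH beat: P at 180 ms, QRS around 400 ms, T at 650 ms."""
    # small per-lead activation-time offsets keep the loops open curves
    # (perfectly synchronous single wavelets would collapse them to lines)
    lag = (0.0, 2.0, -6.0, -4.0, -2.0, 0.0, 2.0, 4.0)

    def wave(center, width, amps):
        return {lead: [WaveComponent(center + dl, width, a)]
                for lead, a, dl in zip(INDEPENDENT_LEADS, amps, lag)}

    #                I     II    V1     V2     V3     V4    V5    V6
    p = wave(180, 20, (60, 100, 40, 50, 50, 60, 60, 50))
    t = wave(650, 45, (250, 300, 50, 300, 350, 350, 300, 250))
    r_amp = (700, 1000, 200, 400, 700, 1300, 1600, 1200)
    s_amp = (-150, -200, -1100, -1500, -1100, -600, -300, -150)
    qrs = {lead: [WaveComponent(400 + dl, 10, r), WaveComponent(418 + dl, 8, s)]
           for lead, r, s, dl in zip(INDEPENDENT_LEADS, r_amp, s_amp, lag)}
    return BeatSpec(p=p, qrs=qrs, t=t, noise_sd_uv=noise_sd_uv)


def make_beat(spec: BeatSpec,
              rng: np.random.Generator | int | None = None
              ) -> tuple[MedianBeat12, Fiducials]:
    """Render a beat from its spec; returns the beat and true fiducials.

    Each independent lead is its Gaussian components plus seeded white noise;
    the derived limb leads follow from the (noisy) I and II.  The returned
    fiducials are the +/- 3 sigma ground-truth windows, clipped to keep the
    P/QRS/T ordering invariant.
    """
    rng = np.random.default_rng(rng)
    n = int(round(spec.length_ms / 1000.0 * spec.fs))
    t_ms = np.arange(n) / spec.fs * 1000.0

    leads8: dict[str, np.ndarray] = {}
    for lead in INDEPENDENT_LEADS:
        sig = np.zeros(n)
        for wave in ("p", "qrs", "t"):
            for c in getattr(spec, wave).get(lead, []):
                sig += c.amplitude_uv * np.exp(
                    -((t_ms - c.center_ms) ** 2) / (2 * c.width_ms ** 2))
        if spec.noise_sd_uv > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd_uv, size=n)
        leads8[lead] = sig

    def to_idx(ms: float) -> int:
        return int(np.clip(round(ms / 1000.0 * spec.fs), 0, n))

    p_lo, p_hi = spec.wave_window_ms("p")
    q_lo, q_hi = spec.wave_window_ms("qrs")
    t_lo, t_hi = spec.wave_window_ms("t")
    if not (p_lo < p_hi <= q_lo < q_hi <= t_lo < t_hi):
        raise ValueError("ground-truth wave windows overlap or are unordered")
    fid = Fiducials(p_on=to_idx(p_lo), p_off=to_idx(p_hi),
                    qrs_on=to_idx(q_lo), qrs_off=to_idx(q_hi),
                    t_off=min(to_idx(t_hi), n))
    beat = MedianBeat12.from_independent(leads8, fs=spec.fs, fiducials=fid)
    return beat, fid


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the cohort the analysis assumes: n = 664 at 42.8% LVH
    prevalence; LVH beats get a lognormal QRS amplitude multiplier (median
    1.5), lateral T inversion with probability 0.35 and T areas shrunk to
    0.6; covariate marginals follow the cohort table (42.9% female, age
    64.2 +/- 15.1 y, BMI 28 +/- 5.2, hypertension 57.8%, IHD 17.5%;
    geometry/severity strata at the observed proportions).
    """

    n: int = 664
    prevalence: float = 0.428
    qrs_mult_log_mean: float = float(np.log(1.5))
    qrs_mult_log_sd: float = 0.18
    t_flip_prob: float = 0.35
    t_shrink: float = 0.6
    #: per-patient lognormal gain on all waves (biological amplitude spread)
    global_gain_log_sd: float = 0.20
    #: extra per-patient lognormal gain on the T wave only
    t_gain_log_sd: float = 0.30
    noise_sd_uv: float = 6.0
    seed: int | None = None
    female_rate: float = 0.429
    age_mean: float = 64.2
    age_sd: float = 15.1
    bmi_mean: float = 28.0
    bmi_sd: float = 5.2
    hypertension_rate: float = 0.578
    ihd_rate: float = 0.175
    #: severity proportions among LVH cases (mild, moderate, severe)
    severity_probs: tuple[float, float, float] = (108 / 284, 66 / 284, 110 / 284)
    #: geometry proportions: normal/remodeling among non-LVH,
    #: concentric/eccentric hypertrophy among LVH
    geometry_neg_probs: tuple[float, float] = (146 / 379, 233 / 379)
    geometry_pos_probs: tuple[float, float] = (232 / 285, 53 / 285)

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class Patient:
    beat: MedianBeat12
    fiducials: Fiducials
    label: int
    covariates: dict[str, object] = field(default_factory=dict)


def _lvh_spec(base: BeatSpec, mult: float, flip_lateral: bool,
              t_shrink: float) -> BeatSpec:
    spec = base.scaled_qrs(mult)
    t = {}
    for lead, comps in spec.t.items():
        k = t_shrink * (-1.0 if flip_lateral and lead in LATERAL_LEADS else 1.0)
        t[lead] = [replace(c, amplitude_uv=c.amplitude_uv * k) for c in comps]
    return replace(spec, t=t)


def make_cohort(spec: CohortSpec | None = None,
                seed: int | None = None) -> list[Patient]:
    """Draw a fully seeded cohort of labelled beats with covariates."""
    spec = spec or CohortSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    base = default_beat_spec(noise_sd_uv=spec.noise_sd_uv)

    patients: list[Patient] = []
    for _ in range(spec.n):
        label = int(rng.random() < spec.prevalence)
        if label:
            mult = float(np.exp(rng.normal(spec.qrs_mult_log_mean,
                                           spec.qrs_mult_log_sd)))
            flip = bool(rng.random() < spec.t_flip_prob)
            bspec = _lvh_spec(base, mult, flip, spec.t_shrink)
        else:
            bspec = base
        if spec.global_gain_log_sd > 0:
            bspec = bspec.scaled(
                float(np.exp(rng.normal(0.0, spec.global_gain_log_sd))))
        if spec.t_gain_log_sd > 0:
            bspec = bspec.scaled(
                float(np.exp(rng.normal(0.0, spec.t_gain_log_sd))),
                waves=("t",))
        beat, fid = make_beat(bspec, rng)

        if label:
            geometry = rng.choice(
                ["concentric_hypertrophy", "eccentric_hypertrophy"],
                p=spec.geometry_pos_probs)
            severity = rng.choice(["mild", "moderate", "severe"],
                                  p=spec.severity_probs)
        else:
            geometry = rng.choice(["normal", "concentric_remodeling"],
                                  p=spec.geometry_neg_probs)
            severity = "none"
        cov = {
            "sex": "F" if rng.random() < spec.female_rate else "M",
            "age": float(rng.normal(spec.age_mean, spec.age_sd)),
            "bmi": float(rng.normal(spec.bmi_mean, spec.bmi_sd)),
            "hypertension": int(rng.random() < spec.hypertension_rate),
            "ihd": int(rng.random() < spec.ihd_rate),
            "geometry": str(geometry),
            "severity": str(severity),
        }
        patients.append(Patient(beat=beat, fiducials=fid, label=label,
                                covariates=cov))
    return patients


def write_cohort(patients: list[Patient], out_dir: str | Path) -> Path:
    """Write a cohort directory: beat CSVs plus a manifest of labels/covariates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, p in enumerate(patients):
        fname = f"beat_{i:04d}.csv"
        write_median_beat(p.beat, out / fname)
        rows.append({"patient": i, "beat_file": fname, "lvh": p.label,
                     **p.covariates})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Direct feature tables (fast fixtures bypassing signal synthesis)
# ---------------------------------------------------------------------------

def make_feature_table(n: int,
                       informative: dict[str, float] | None = None,
                       noise_features: int = 20,
                       prevalence: float = 0.428,
                       missing_rate: float = 0.0,
                       seed: int | None = None,
                       group: str = "VCG") -> "pd.DataFrame":
    """A labelled Gaussian feature table with stated effect sizes.

    ``informative`` maps feature name -> standardized mean difference between
    the LVH and non-LVH classes; ``noise_features`` unit-variance columns
    carry no signal.  Missing entries are introduced completely at random.
    Column group tags are stored in ``df.attrs['groups']``.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    rng = np.random.default_rng(seed)
    informative = informative or {}
    y = (rng.random(n) < prevalence).astype(int)
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for name, smd in informative.items():
        cols[name] = rng.normal(0.0, 1.0, n) + smd * y
        groups[name] = group
    for j in range(noise_features):
        name = f"noise_{j:02d}"
        cols[name] = rng.normal(0.0, 1.0, n)
        groups[name] = group
    df = pd.DataFrame(cols)
    if missing_rate > 0:
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    df["lvh"] = y
    df.attrs["groups"] = groups
    return df
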