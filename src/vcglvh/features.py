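"""End-to-end feature extraction: beats -> named VCG + ECG feature columns.

Every (transform method x wave x raw/Fourier-smoothed) combination yields its
decile and global loop features, named ``<Wave><Metric><MethodTag><f?><d?>``
(method tags D = inverse Dower, K = Kors, Q = QLSV, P = PLSV; suffix ``f``
marks the Fourier-smoothed variant), e.g. ``QRSMagK3`` or ``TVelQf5``.  The
handful of predictors with an established printed abbreviation keep it
(``GAV_K``, ``RangeAngR``, ``Vel_Min_Kf_T``, ``Ang_Term_Num``, ``PMagP2`` ...),
so the pinned tree models can address them by name.  ECG-group columns come
from the scalar lead measurements and the continuous criterion values
(``ECG_21`` = Cornell voltage, ``T_AREA_DI`` = T area in lead I, ...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .beats import Fiducials, MedianBeat12, measure_amplitudes
from .criteria import continuous_features
from .loops import Loop, decile_features, detect_fiducials, global_features, \
    segment_loops
from .synthetic import Patient
from .transforms import DEFAULT_HARMONICS, METHODS, load_matrix, synthesize, \
    truncate_fourier

#: printed abbreviations for specific (wave, metric, tag[, decile]) features
_ALIASES: dict[tuple, str] = {
    ("QRS", "GAV", "K"): "GAV_K",
    ("QRS", "RangeAng", "D"): "RangeAngR",
    ("T", "VelMin", "Kf"): "Vel_Min_Kf_T",
    ("QRS", "TermMag", "K"): "Ang_Term_Num",
}

#: the pinned predictor whitelists of the three tree models
PINNED_VCG = ("GAV_K", "RangeAngR", "PMagP2", "POrbFrqD5", "Vel_Min_Kf_T")
PINNED_VCG_ECG = ("Ang_Term_Num", "T_AREA_DI", "ECG_21",
                  "QRSMagP1", "TVelQ5", "QRSMagPf9")


def _name(wave: str, metric: str, tag: str, decile: int | None = None) -> str:
    alias = _ALIASES.get((wave, metric, tag))
    if alias is not None:
        return alias
    suffix = "" if decile is None else str(decile)
    return f"{wave}{metric}{tag}{suffix}"


def extract_features(beat: MedianBeat12,
                     fiducials: Fiducials | None = None,
                     harmonics: int = DEFAULT_HARMONICS,
                     matrix_dir=None) -> dict[str, float]:
    """All VCG loop features plus the ECG measurement features for one beat."""
    fid = detect_fiducials(beat, fiducials)
    feats: dict[str, float] = {}

    for method, (tag, _) in METHODS.items():
        matrix = load_matrix(method, matrix_dir)
        sig = synthesize(beat, matrix)
        loops = segment_loops(sig, fid)
        for wave, loop in loops.items():
            for smoothed in (False, True):
                mtag = tag + ("f" if smoothed else "")
                if smoothed:
                    h = min(harmonics, (loop.n_points - 1) // 2)
                    if h < 1:
                        continue
                    loop = Loop(points=truncate_fourier(loop.points, h),
                                dt_ms=loop.dt_ms, wave=wave,
                                method=loop.method)
                dec = decile_features(loop)
                for metric in ("Mag", "Vel", "OrbFrq"):
                    for d in range(10):
                        feats[_name(wave, metric, mtag, d + 1)] = \
                            float(dec[metric][d])
                for metric, value in global_features(loop).items():
                    feats[_name(wave, metric, mtag)] = float(value)

    m = measure_amplitudes(beat, fid)
    feats.update(continuous_features(m))
    return feats


def feature_groups(columns) -> dict[str, str]:
    """Group tag per feature column: ECG for measurement-derived, VCG else."""
    return {c: ("ECG" if c.startswith(("ECG_", "T_AREA")) else "VCG")
            for c in columns}


def cohort_feature_table(patients: list[Patient],
                         harmonics: int = DEFAULT_HARMONICS,
                         use_true_fiducials: bool = True) -> pd.DataFrame:
    """FeatureTable for a synthetic cohort: one row per patient plus the
    ``lvh`` label; column group tags in ``df.attrs['groups']`` and the
    covariates in ``df.attrs['covariates']``."""
    rows = []
    for p in patients:
        fid = p.fiducials if use_true_fiducials else None
        rows.append(extract_features(p.beat, fid, harmonics=harmonics))
    df = pd.DataFrame(rows)
    df["lvh"] = [p.label for p in patients]
    df.attrs["groups"] = feature_groups(c for c in df.columns if c != "lvh")
    df.attrs["covariates"] = pd.DataFrame([p.covariates for p in patients])
    return df
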