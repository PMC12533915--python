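"""The 23 classical ECG-LVH criteria with sex-specific cut-offs.

Most criteria are simple voltage sums compared against a threshold; they are
driven by a declarative YAML registry so the catalogue can be corrected
without touching code.  Cornell voltage and Peguero-Lo Presti carry their
canonical comparators and sex-specific thresholds pinned in code as well
(Cornell strictly greater than 2.8 mV in men / 2.0 mV in women; Peguero
non-strict at 2.8 / 2.3 mV).  The Romhilt-Estes point score and the
sex-adjusted Cornell voltage-duration product are registered
programmatically.  Every mV criterion also spawns a voltage-duration-product
variant (value x QRS duration; threshold scaled by a nominal 100 ms QRS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import yaml

from .beats import LeadMeasurements

_COMPARATORS: dict[str, Callable[[float, float], bool]] = {
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
}

#: Table-pinned sex-specific cut-offs (mV)
CORNELL_THRESHOLDS = {"M": 2.8, "F": 2.0}
PEGUERO_THRESHOLDS = {"M": 2.8, "F": 2.3}


@dataclass(frozen=True)
class CriterionResult:
    name: str
    value: float
    unit: str
    comparator: str            # "gt" or "ge"
    threshold: float
    positive: bool
    sex: str | None = None

    def __post_init__(self) -> None:
        expected = _COMPARATORS[self.comparator](self.value, self.threshold)
        if expected != self.positive:
            raise ValueError(
                f"{self.name}: call {self.positive} inconsistent with "
                f"{self.value} {self.comparator} {self.threshold}")


def _result(name: str, value: float, unit: str, comparator: str,
            threshold: float, sex: str | None = None) -> CriterionResult:
    return CriterionResult(name=name, value=float(value), unit=unit,
                           comparator=comparator, threshold=float(threshold),
                           positive=_COMPARATORS[comparator](value, threshold),
                           sex=sex)


def _require_sex(sex: str | None, criterion: str) -> str:
    if sex not in ("M", "F"):
        raise ValueError(
            f"{criterion} is sex-specific; sex must be 'M' or 'F', got {sex!r}")
    return sex


# ---------------------------------------------------------------------------
# Pinned criteria
# ---------------------------------------------------------------------------

def cornell_voltage(m: LeadMeasurements, sex: str) -> CriterionResult:
    """Cornell voltage RaVL + SV3, positive strictly above 2.8 mV (men) /
    2.0 mV (women)."""
    sex = _require_sex(sex, "cornell_voltage")
    return _result("cornell_voltage", m.RaVL + m.SV3, "mV", "gt",
                   CORNELL_THRESHOLDS[sex], sex)


def peguero_lo_presti(m: LeadMeasurements, sex: str) -> CriterionResult:
    """Peguero-Lo Presti: deepest S in any lead + SV4, positive at or above
    2.8 mV (men) / 2.3 mV (women)."""
    sex = _require_sex(sex, "peguero_lo_presti")
    return _result("peguero_lo_presti", m.SD + m.SV4, "mV", "ge",
                   PEGUERO_THRESHOLDS[sex], sex)


def cornell_product(m: LeadMeasurements, sex: str) -> CriterionResult:
    """Cornell voltage-duration product, (RaVL + SV3 [+ 0.6 mV in women]) x
    QRS duration, positive above 244 mV.ms."""
    sex = _require_sex(sex, "cornell_product")
    voltage = m.RaVL + m.SV3 + (0.6 if sex == "F" else 0.0)
    return _result("cornell_product", voltage * m.qrs_duration_ms, "mV.ms",
                   "gt", 244.0, sex)


def romhilt_estes_score(m: LeadMeasurements) -> int:
    """Standard six-component Romhilt-Estes point score.

    Components: voltage (3), repolarization strain (3, proxied by T polarity
    opposite the dominant QRS deflection in V5/V6), left atrial abnormality
    (3, P terminal force in V1 > 0.04 mm.s), left axis deviation beyond -30
    degrees (2), QRS duration >= 90 ms (1), delayed intrinsicoid deflection
    in V5/V6 >= 50 ms (1).
    """
    score = 0
    limb = ["I", "II", "III", "aVR", "aVL", "aVF"]
    if (any(m.r[l] >= 2.0 or m.s[l] >= 2.0 for l in limb)
            or m.s["V1"] >= 3.0 or m.s["V2"] >= 3.0
            or m.r["V5"] >= 3.0 or m.r["V6"] >= 3.0):
        score += 3
    for lead in ("V5", "V6"):
        dominant = 1 if m.r[lead] >= m.s[lead] else -1
        if m.t_polarity[lead] != 0 and m.t_polarity[lead] == -dominant:
            score += 3
            break
    if m.ptf_v1_mm_s > 0.04:
        score += 3
    if m.frontal_axis_deg <= -30.0:
        score += 2
    if m.qrs_duration_ms >= 90.0:
        score += 1
    if any(m.intrinsicoid_ms.get(l, 0.0) >= 50.0 for l in ("V5", "V6")):
        score += 1
    return score


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _RegistryEntry:
    name: str
    formula: str
    comparator: str
    unit: str
    threshold: float | None = None
    threshold_men: float | None = None
    threshold_women: float | None = None
    product_variant: bool = True

    @property
    def sex_specific(self) -> bool:
        return self.threshold is None

    def threshold_for(self, sex: str | None) -> float:
        if not self.sex_specific:
            return float(self.threshold)
        sex = _require_sex(sex, self.name)
        return float(self.threshold_men if sex == "M" else self.threshold_women)


def load_registry(path: str | None = None) -> list[_RegistryEntry]:
    if path is not None:
        text = open(path).read()
    else:
        text = resources.files("vcglvh.data").joinpath("criteria.yaml").read_text()
    raw = yaml.safe_load(text)["criteria"]
    return [_RegistryEntry(**entry) for entry in raw]


_SAFE_FUNCS = {"max": max, "min": min, "abs": abs}


def _eval_formula(formula: str, symbols: dict[str, float]) -> float:
    return float(eval(formula, {"__builtins__": {}},
                      {**_SAFE_FUNCS, **symbols}))


def evaluate_all(m: LeadMeasurements, sex: str | None = None,
                 registry: list[_RegistryEntry] | None = None,
                 include_products: bool = True) -> list[CriterionResult]:
    """Evaluate the full criteria catalogue against one patient's measurements.

    Criteria whose inputs are missing, or sex-specific criteria evaluated
    without a declared sex, are skipped with a warning rather than raised.
    Voltage (mV) criteria also emit a ``*_vdp`` voltage-duration-product
    variant with the threshold scaled by a nominal 100 ms QRS duration.
    """
    registry = registry if registry is not None else load_registry()
    symbols = m.symbols()
    results: list[CriterionResult] = []
    for entry in registry:
        try:
            value = _eval_formula(entry.formula, symbols)
            thr = entry.threshold_for(sex)
        except (NameError, KeyError):
            warnings.warn(f"criterion {entry.name}: missing inputs, skipped")
            continue
        except ValueError as exc:
            warnings.warn(f"criterion {entry.name}: {exc}; skipped")
            continue
        results.append(_result(entry.name, value, entry.unit,
                               entry.comparator, thr,
                               sex if entry.sex_specific else None))
        if include_products and entry.unit == "mV" and entry.product_variant:
            results.append(_result(
                f"{entry.name}_vdp", value * m.qrs_duration_ms, "mV.ms",
                entry.comparator, thr * 100.0,
                sex if entry.sex_specific else None))

    if sex in ("M", "F"):
        results.append(cornell_product(m, sex))
    else:
        warnings.warn("cornell_product requires sex; skipped")
    score = romhilt_estes_score(m)
    results.append(_result("romhilt_estes_4", score, "points", "ge", 4.0))
    results.append(_result("romhilt_estes_5", score, "points", "ge", 5.0))
    return results


def continuous_features(m: LeadMeasurements) -> dict[str, float]:
    """Sex-independent continuous criterion values for the feature table.

    ``ECG_21`` is the Cornell voltage (RaVL + SV3, mV) and ``T_AREA_DI`` the
    T-wave area in lead I (Ashman units), the two ECG-group predictors of the
    combined tree models; the remaining registry formulas, the Romhilt-Estes
    score and the raw measurements round out the ECG feature group.
    """
    symbols = m.symbols()
    feats: dict[str, float] = {}
    feats["ECG_21"] = m.RaVL + m.SV3
    feats["T_AREA_DI"] = m.t_area_au["I"]
    for entry in load_registry():
        if entry.name == "cornell_voltage":
            continue
        try:
            feats[f"ECG_{entry.name}"] = _eval_formula(entry.formula, symbols)
        except (NameError, KeyError):
            continue
    feats["ECG_romhilt_estes"] = float(romhilt_estes_score(m))
    for sym, value in symbols.items():
        feats[f"ECG_{sym}"] = value
    return feats
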