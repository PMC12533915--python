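# Declarative registry of classical ECG-LVH voltage criteria.
#
# Each entry gives a formula over the measurement symbol table
# (RI, SIII, RaVL, SV1 ... SD, QRSd; amplitudes in mV, durations in ms),
# a comparator ("gt" strict, "ge" non-strict) and either a single threshold
# or sex-specific thresholds (men/women).  Unit "mV" entries also spawn a
# voltage-duration-product variant (value x QRS duration, threshold x 100 ms).
# The Cornell and Peguero-Lo Presti thresholds/comparators are additionally
# pinned in code.  Point-score criteria (Romhilt-Estes) and the sex-adjusted
# Cornell product are registered in code, not here.
criteria:
  - name: sokolow_lyon
    formula: "SV1 + max(RV5, RV6)"
    comparator: ge
    threshold: 3.5
    unit: mV
  - name: cornell_voltage
    formula: "RaVL + SV3"
    comparator: gt
    threshold_men: 2.8
    threshold_women: 2.0
    unit: mV
  - name: peguero_lo_presti
    formula: "SD + SV4"
    comparator: ge
    threshold_men: 2.8
    threshold_women: 2.3
    unit: mV
  - name: gubner_ungerleider
    formula: "RI + SIII"
    comparator: gt
    threshold: 2.5
    unit: mV
  - name: lewis_index
    formula: "(RI + SIII) - (RIII + SI)"
    comparator: gt
    threshold: 1.7
    unit: mV
  - name: ravl_voltage
    formula: "RaVL"
    comparator: gt
    threshold: 1.1
    unit: mV
  - name: r_i_voltage
    formula: "RI"
    comparator: gt
    threshold: 1.5
    unit: mV
  - name: r_avf_voltage
    formula: "RaVF"
    comparator: gt
    threshold: 2.0
    unit: mV
  - name: r_v5_voltage
    formula: "RV5"
    comparator: gt
    threshold: 2.6
    unit: mV
  - name: r_v6_voltage
    formula: "RV6"
    comparator: gt
    threshold: 2.6
    unit: mV
  - name: s_v1_voltage
    formula: "SV1"
    comparator: gt
    threshold: 2.4
    unit: mV
  - name: s_v2_voltage
    formula: "SV2"
    comparator: gt
    threshold: 3.0
    unit: mV
  - name: deepest_s_precordial
    formula: "max(SV1, SV2, SV3, SV4, SV5, SV6)"
    comparator: gt
    threshold: 3.0
    unit: mV
  - name: tallest_r_precordial
    formula: "max(RV1, RV2, RV3, RV4, RV5, RV6)"
    comparator: gt
    threshold: 3.0
    unit: mV
  - name: mcphie
    formula: "max(RV1, RV2, RV3, RV4, RV5, RV6) + max(SV1, SV2, SV3, SV4, SV5, SV6)"
    comparator: gt
    threshold: 4.5
    unit: mV
  - name: limb_lead_voltage
    formula: "max(RI, RII, RIII, RaVR, RaVL, RaVF, SI, SII, SIII, SaVR, SaVL, SaVF)"
    comparator: ge
    threshold: 2.0
    unit: mV
  - name: total_12_lead_voltage
    formula: "RI + SI + RII + SII + RIII + SIII + RaVR + SaVR + RaVL + SaVL + RaVF + SaVF + RV1 + SV1 + RV2 + SV2 + RV3 + SV3 + RV4 + SV4 + RV5 + SV5 + RV6 + SV6"
    comparator: gt
    threshold: 17.5
    unit: mV
  - name: holt_spodick
    formula: "RV6 - RV5"
    comparator: gt
    threshold: 0.0
    unit: mV
    product_variant: false
  - name: sokolow_lyon_product
    formula: "(SV1 + max(RV5, RV6)) * QRSd"
    comparator: gt
    threshold: 371.0
    unit: mV.ms
  - name: ravl_duration_product
    formula: "RaVL * QRSd"
    comparator: gt
    threshold: 104.0
    unit: mV.ms
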