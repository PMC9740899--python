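"""Bundled reference criterion tables from a laboratory lifting study.

Two tables accompany the package as worked-example inputs for the
from-table ranking mode:

* ``sequence_table`` -- 13 biomechanical stress criteria (7 muscle
  activity time integrals in %s, 6 peak joint forces in kN) for six
  recorded box-handling sequences (T1..T6: carry/lift/lower of two box
  types, 21 kg), as means and standard deviations over three subjects.

* ``concept_table`` -- 8 criteria (mean shoulder/back muscle activity
  in %, mean glenohumeral and L4/L5 joint force in N, and four
  parasitic arm-interface loads) for six simulated exoskeleton concept
  variants of a shoulder-support exoskeleton, plus the unsupported
  baseline column.  Dispersion values are available for the interface
  load rows and are used only for tie resolution.

These are printed, rounded values; the ranking arithmetic on them is
exactly reproducible, the simulated magnitudes behind them are not.
"""
from __future__ import annotations

import pandas as pd

SEQUENCES = ["T1", "T2", "T3", "T4", "T5", "T6"]

_SEQ_ROWS = {
    # criterion: (means, sds)
    "ma_integral:whole_body": ([78, 82, 54, 72, 90, 45], [6, 21, 16, 3, 13, 12]),
    "ma_integral:lower_extremities": ([28, 23, 15, 26, 22, 11], [5, 8, 6, 4, 3, 1]),
    "ma_integral:abdomen": ([27, 39, 30, 25, 36, 21], [4, 10, 7, 1, 3, 4]),
    "ma_integral:lower_back": ([24, 37, 29, 22, 35, 21], [3, 9, 9, 1, 3, 3]),
    "ma_integral:neck": ([13, 19, 12, 17, 24, 11], [3, 9, 2, 1, 12, 3]),
    "ma_integral:shoulders": ([47, 62, 41, 27, 56, 23], [16, 27, 17, 2, 15, 10]),
    "ma_integral:arms": ([78, 72, 50, 72, 87, 44], [7, 16, 14, 3, 7, 11]),
    "jf_max:knee": ([3.8, 3.7, 2.8, 3.4, 4.3, 2.8], [0.5, 0.5, 0.8, 0.4, 1.6, 0.6]),
    "jf_max:hip": ([4.0, 3.1, 3.0, 4.3, 4.2, 3.3], [1.2, 0.7, 0.5, 0.7, 0.2, 1.2]),
    "jf_max:glenohumeral": ([1.9, 2.7, 1.9, 1.4, 3.7, 1.8],
                            [0.5, 1.1, 0.2, 0.2, 1.8, 0.4]),
    "jf_max:elbow": ([1.2, 1.4, 1.0, 1.1, 1.2, 0.9], [0.1, 0.4, 0.2, 0.1, 0.4, 0.1]),
    "jf_max:wrist": ([1.3, 1.7, 1.0, 1.1, 1.7, 0.7], [0.0, 0.6, 0.3, 0.0, 1.2, 0.3]),
    "jf_max:l4l5": ([2.0, 2.6, 2.2, 2.1, 3.2, 2.4], [0.4, 0.1, 0.2, 0.3, 0.7, 0.4]),
}

SEQUENCE_OVERALL_SCORES = pd.Series(
    [50, 63, 32, 39, 70, 19], index=SEQUENCES, name="overall_score")

CONCEPTS = [
    "H: R.cc–A: R.lm",
    "H: R.cc–A: R.cc",
    "H: R.cc–A: U.lm-cc",
    "H: U.cc-ap–A: R.lm",
    "H: U.cc-ap–A: R.cc",
    "H: U.cc-lm–A: R.cc",
]
NO_EXO = "no_exo"

_CONCEPT_ROWS = {
    # criterion: (no-exo baseline, six concept values, optional sds)
    "ma_mean:shoulders": (37.1, [13.8, 15.1, 13.1, 13.4, 26.9, 13.2], None),
    "ma_mean:lower_back": (27.9, [8.9, 9.2, 9.0, 9.5, 10.3, 9.6], None),
    "jf_mean:glenohumeral": (1495.0,
                             [287.2, 329.9, 319.1, 298.4, 461.3, 334.2], None),
    "jf_mean:l4l5": (1665.3, [401.5, 429.8, 432.7, 448.5, 502.1, 460.5], None),
    "interface_force:distoproximal": (
        None, [4.2, 2.6, 10.8, 5.5, 5.0, 4.2],
        [2.7, 2.1, 8.3, 2.3, 3.7, 3.6]),
    "interface_force:lateromedial": (
        None, [38.1, 31.9, 37.5, 22.7, 15.4, 39.7],
        [27.3, 27.3, 34.7, 18.3, 9.7, 35.0]),
    "interface_torque:distoproximal": (
        None, [8.0, 11.4, 6.5, 6.3, 11.8, 7.8],
        [5.0, 4.2, 4.3, 4.3, 5.9, 4.7]),
    "interface_torque:craniocaudal": (
        None, [14.5, 4.6, 2.5, 3.7, 4.5, 3.0],
        [18.0, 3.1, 2.2, 3.3, 2.7, float("nan")]),
}

CONCEPT_OVERALL_RATINGS = pd.Series(
    [25.0, 28.0, 22.0, 24.0, 39.0, 30.0], index=CONCEPTS,
    name="overall_rating")

# supporting interface loads (not part of the rating): mean, sd
SUPPORTING_LOADS = {
    "force_craniocaudal": ([129.1, 61.9, 138.9, 137.4, 36.4, 107.6],
                           [30.0, 80.0, 23.0, 26.7, 87.2, 34.9]),
    "torque_lateromedial": ([1.4, 21.3, 0.0, 0.4, 25.9, 8.1],
                            [1.3, 17.2, 0.1, 0.3, 18.0, 4.4]),
}


def sequence_table() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(means, sds) of the 13 criteria for T1..T6."""
    means = pd.DataFrame({c: v[0] for c, v in _SEQ_ROWS.items()},
                         index=SEQUENCES).T
    sds = pd.DataFrame({c: v[1] for c, v in _SEQ_ROWS.items()},
                       index=SEQUENCES).T
    return means, sds


def concept_table(include_baseline: bool = False
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(values, sds) of the 8 rating criteria for the six concepts.

    With ``include_baseline`` the unsupported column is prepended for
    the four criteria that have one (NaN elsewhere).
    """
    cols = ([NO_EXO] + CONCEPTS) if include_baseline else CONCEPTS
    values = pd.DataFrame(index=list(_CONCEPT_ROWS), columns=cols,
                          dtype=float)
    sds = pd.DataFrame(index=list(_CONCEPT_ROWS), columns=cols, dtype=float)
    for crit, (base, vals, disp) in _CONCEPT_ROWS.items():
        for concept, v in zip(CONCEPTS, vals):
            values.loc[crit, concept] = v
        if include_baseline and base is not None:
            values.loc[crit, NO_EXO] = base
        if disp is not None:
            for concept, s in zip(CONCEPTS, disp):
                sds.loc[crit, concept] = s
    return values, sds


def baseline_values() -> pd.Series:
    """Unsupported-condition values for the four body-stress criteria."""
    return pd.Series({c: v[0] for c, v in _CONCEPT_ROWS.items()
                      if v[0] is not None})
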