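"""The seven nested deleteriousness masks.

Variants are first assigned to exactly one of seven mutually exclusive
*strata*, ordered from most to least stringent evidence of
deleteriousness; the burden mask ``m`` then aggregates strata ``1..m``
(nesting).  Stratum predicates are evaluated first-match-wins over
per-variant annotation flags:

1.  high-confidence loss of function (LOFTEE HC);
2.  "16 of 16": all sixteen deleteriousness predictor calls;
3.  "11 of 11": the five core predictors plus six further predictors;
4.  "5 of 5": the five core missense predictors;
5.  low-confidence LoF / high-impact at max MAF < 1%;
6.  "1 of 5" at moderate impact and max MAF < 1%;
7.  "0 of 5" at moderate impact and max MAF < 1%.

Each predictor call is a precomputed boolean input column (the
annotations themselves come from upstream tools and are not recomputed
here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MASK_NAMES: tuple[str, ...] = (
    "lof_hc",
    "16of16",
    "11of11",
    "5of5",
    "5of5_lof_lc_1pct",
    "1of5_1pct",
    "0of5_1pct",
)

#: the five core missense predictors ("5 of 5")
CORE5 = ("polyphen_hdiv", "polyphen_hvar", "sift", "lrt", "mutation_taster")
#: six further predictors completing "11 of 11"
MID6 = ("fathmm", "fathmm_mkl", "provean", "metasvm", "metalr", "mcap")
#: five rank-score predictors completing "16 of 16"
RANK5 = ("vest3", "cadd", "dann", "eigen_raw", "eigen_pc_raw")

PREDICTOR_COLUMNS = CORE5 + MID6 + RANK5

#: all annotation columns :func:`assign_strata` requires
REQUIRED_COLUMNS = PREDICTOR_COLUMNS + ("loftee", "vep_impact", "max_maf")


def assign_strata(annotations: pd.DataFrame) -> pd.Series:
    """Assign each variant to one of the seven strata (or none).

    Parameters
    ----------
    annotations : one row per variant; boolean columns for the sixteen
        predictor calls, ``loftee`` in {"HC", "LC", ""} , ``vep_impact``
        in {"HIGH", "MODERATE", "LOW", "MODIFIER"}, and numeric
        ``max_maf``.

    Returns
    -------
    Series of mask names (values from :data:`MASK_NAMES`) indexed like
    ``annotations``; variants matching no stratum get the empty string.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in annotations.columns]
    if missing:
        raise KeyError(f"annotation columns missing: {missing}")

    core5 = np.ones(len(annotations), dtype=bool)
    for c in CORE5:
        core5 &= annotations[c].to_numpy(dtype=bool)
    n_core = np.zeros(len(annotations), dtype=int)
    for c in CORE5:
        n_core += annotations[c].to_numpy(dtype=bool)
    mid6 = np.ones(len(annotations), dtype=bool)
    for c in MID6:
        mid6 &= annotations[c].to_numpy(dtype=bool)
    rank5 = np.ones(len(annotations), dtype=bool)
    for c in RANK5:
        rank5 &= annotations[c].to_numpy(dtype=bool)

    loftee = annotations["loftee"].fillna("").astype(str).to_numpy()
    impact = annotations["vep_impact"].astype(str).to_numpy()
    rare = annotations["max_maf"].to_numpy(dtype=float) < 0.01

    predicates = [
        loftee == "HC",
        core5 & mid6 & rank5,
        core5 & mid6,
        core5,
        (core5 | (impact == "HIGH")) & (loftee == "LC") & rare,
        (n_core >= 1) & (impact == "MODERATE") & rare,
        (n_core == 0) & (impact == "MODERATE") & rare,
    ]
    out = np.full(len(annotations), "", dtype=object)
    unassigned = np.ones(len(annotations), dtype=bool)
    for name, pred in zip(MASK_NAMES, predicates):
        take = unassigned & pred
        out[take] = name
        unassigned &= ~take
    return pd.Series(out, index=annotations.index, name="mask")


def stratum_annotations(mask_name: str, max_maf: float) -> dict:
    """Annotation flags that place a variant in exactly ``mask_name``.

    Inverse of :func:`assign_strata` for synthetic fixtures: the
    returned row evaluates to the requested stratum under the
    first-match rule.
    """
    if mask_name not in MASK_NAMES:
        raise ValueError(f"unknown mask {mask_name!r}")
    row = {c: False for c in PREDICTOR_COLUMNS}
    row["loftee"] = ""
    row["vep_impact"] = "MODERATE"
    row["max_maf"] = max_maf
    if mask_name == "lof_hc":
        row["loftee"] = "HC"
        row["vep_impact"] = "HIGH"
    elif mask_name == "16of16":
        for c in PREDICTOR_COLUMNS:
            row[c] = True
    elif mask_name == "11of11":
        for c in CORE5 + MID6:
            row[c] = True
    elif mask_name == "5of5":
        for c in CORE5:
            row[c] = True
    elif mask_name == "5of5_lof_lc_1pct":
        row["loftee"] = "LC"
        row["vep_impact"] = "HIGH"
    elif mask_name == "1of5_1pct":
        row["sift"] = True
    # 0of5_1pct: all-false moderate-impact defaults already apply
    return row
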