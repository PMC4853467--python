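"""Plasma-vs-blood-component exRNA comparison.

Small donor panels (typically six donors) measure the same assays in plasma,
exosomes, platelets, PBMCs, RBCs, T cells, B cells and neutrophils.  Each
(assay, component) pair is compared to plasma as the referent by OLS on a
component-vs-plasma indicator — algebraically the pooled-variance two-sample
t-test — and called up- or down-regulated in plasma at raw p < 0.05 (no
multiplicity correction here, unlike the cohort association screen).
Direction counts per assay class give the component summary grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS = ("not_significant", "up_in_plasma", "down_in_plasma")


def censor_panel(panel: pd.DataFrame, ceiling: float = 24.0) -> pd.DataFrame:
    """Censor non-detect (missing) Cq values in a long panel to the ceiling."""
    out = panel.copy()
    out["cq"] = out["cq"].fillna(ceiling)
    return out


@dataclass
class ComponentComparison:
    per_assay: pd.DataFrame  # assay_id, component, delta, p, direction


def compare_to_plasma(
    panel: pd.DataFrame,
    alpha: float = 0.05,
    referent: str = "plasma",
) -> ComponentComparison:
    """Per-(assay, component) comparison against the plasma referent.

    ``panel`` is long-format (donor_id, component, assay_id, cq).
    delta = mean plasma Cq - mean component Cq; since lower Cq means more
    template, a significant negative delta (plasma Cq lower) is called
    ``up_in_plasma`` and a significant positive delta ``down_in_plasma``.
    Zero pooled variance yields ``not_significant`` with a warning.
    """
    if referent not in set(panel["component"]):
        raise ValueError(f"panel lacks the {referent!r} referent")
    rows = []
    warned = False
    for assay, sub in panel.groupby("assay_id", sort=True):
        plasma = sub.loc[sub["component"] == referent, "cq"].to_numpy(float)
        if len(plasma) < 2:
            raise ValueError(f"{assay}: need >=2 referent donors")
        for comp, grp in sub[sub["component"] != referent].groupby(
            "component", sort=True
        ):
            vals = grp["cq"].to_numpy(float)
            if len(vals) < 2:
                raise ValueError(f"{assay}/{comp}: need >=2 donors")
            delta = float(plasma.mean() - vals.mean())
            # pooled-variance two-sample t == binary-indicator OLS slope test
            if np.var(plasma, ddof=1) == 0 and np.var(vals, ddof=1) == 0:
                p = float("nan")
                warned = True
            else:
                p = float(
                    stats.ttest_ind(plasma, vals, equal_var=True).pvalue
                )
            if np.isnan(p) or p >= alpha:
                direction = "not_significant"
            elif delta < 0:
                direction = "up_in_plasma"
            else:
                direction = "down_in_plasma"
            rows.append((assay, comp, delta, p, direction))
    if warned:
        warnings.warn("zero pooled variance for some comparisons; "
                      "reported not_significant")
    table = pd.DataFrame(
        rows, columns=["assay_id", "component", "delta", "p", "direction"]
    )
    return ComponentComparison(table)


def tabulate_directions(
    comparison: ComponentComparison,
    classes: pd.Series,
) -> pd.DataFrame:
    """Direction counts per (class, component).

    Rows are (class, component); columns are the three direction calls.
    Per row the counts sum to the class's assay total.
    """
    t = comparison.per_assay.copy()
    t["class"] = classes.reindex(t["assay_id"]).to_numpy()
    if t["class"].isna().any():
        missing = sorted(t.loc[t["class"].isna(), "assay_id"].unique())
        raise ValueError(f"assays without a class label: {missing[:5]}")
    grid = (
        t.groupby(["class", "component", "direction"], sort=True)
        .size()
        .unstack("direction", fill_value=0)
        .reindex(columns=DIRECTIONS, fill_value=0)
    )
    grid.columns.name = None
    return grid
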