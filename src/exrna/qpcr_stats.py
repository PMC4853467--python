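"""Cohort RT-qPCR Cq processing and association screening.

Covers the tabular half of the pipeline: sample exclusions, non-detect
censoring at the cycle ceiling, per-sample global-mean dCq normalisation,
haemolysis QC on the miR-23a/miR-451 pair, flagging of non-specific assays,
detection summaries, and per-assay ordinary least-squares association with
binary covariates (median-age split, sex) under Benjamini-Hochberg FDR.

Conventions: Cq matrices are pandas DataFrames (samples x assays) with NaN
as the non-detect marker ("ND" on disk); lower Cq means more template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXCLUSION_REASONS = (
    "inaccurate_volume",
    "poor_protein_precipitation",
    "potential_contamination",
)

HAEMOLYSIS_CATEGORIES = (
    "low",
    "moderate",
    "high",
    "missing_451",
    "missing_23a",
    "missing_both",
)


def apply_exclusions(
    samples: list[str],
    exclusion_log: dict[str, str],
) -> tuple[list[str], dict[str, int]]:
    """Drop excluded samples from a roster; tally exclusions by reason.

    Reasons come from the closed laboratory-error vocabulary
    (:data:`EXCLUSION_REASONS`).  A sample appearing twice in the log is
    excluded once, with a warning.
    """
    roster = set(samples)
    unknown = set(exclusion_log) - roster
    if unknown:
        raise ValueError(f"exclusion log names unknown samples: "
                         f"{sorted(unknown)[:5]}")
    tally = {r: 0 for r in EXCLUSION_REASONS}
    for sid, reason in exclusion_log.items():
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        tally[reason] += 1
    if len(exclusion_log) != len(set(exclusion_log)):  # dict: always equal
        warnings.warn("duplicate samples in exclusion log")
    remaining = [s for s in samples if s not in exclusion_log]
    return remaining, tally


@dataclass
class CensoredCq:
    """Censored Cq matrix with per-entry expressed flags."""

    cq: pd.DataFrame
    expressed: pd.DataFrame  # boolean, same shape
    ceiling: float
    detect_cutoff: float


def censor_cq(
    raw: pd.DataFrame,
    ceiling: float = 24.0,
    detect_cutoff: float = 23.0,
) -> CensoredCq:
    """Censor non-detects and near-ceiling values to the cycle ceiling.

    Non-detects (NaN) are assigned the maximum Cq (24 cycles by default) and
    flagged not-expressed.  An assay counts as expressed in a sample only
    when its Cq is below the detection cutoff (Cq < 23); observed values in
    [cutoff, ceiling) are likewise censored to the ceiling so that
    "expressed" and the ceiling assignment stay consistent.
    """
    if ceiling <= detect_cutoff:
        raise ValueError("ceiling must exceed detect_cutoff")
    vals = raw.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and finite.min() <= 0:
        raise ValueError("Cq values must be positive")
    expressed = raw.notna() & (raw < detect_cutoff)
    cq = raw.where(expressed, other=ceiling)
    return CensoredCq(cq, expressed, ceiling, detect_cutoff)


@dataclass
class DeltaCq:
    """Per-sample global-mean-normalised Cq values."""

    delta: pd.DataFrame
    expressed: pd.DataFrame
    flagged_samples: list[str]  # no expressed assays; dCq missing


def global_mean_normalize(censored: CensoredCq) -> DeltaCq:
    """dCq(s, a) = Cq(s, a) - mean over expressed assays of sample s.

    Centering is per sample ("global mean of expressed results"), which
    removes inter-individual offsets; samples with no expressed assay are
    flagged and left missing.
    """
    cq = censored.cq
    expressed = censored.expressed
    n_expr = expressed.sum(axis=1)
    means = cq.where(expressed).mean(axis=1)
    flagged = list(cq.index[n_expr == 0])
    delta = cq.sub(means, axis=0)
    delta.loc[flagged] = np.nan
    return DeltaCq(delta, expressed, flagged)


@dataclass
class HaemolysisReport:
    per_sample: pd.DataFrame  # delta_cq, category
    counts: dict[str, int]
    percent_high: float


def haemolysis_qc(
    raw: pd.DataFrame,
    assay_23a: str = "miR-23a",
    assay_451: str = "miR-451",
) -> HaemolysisReport:
    """Red-cell lysis check from the miR-23a/miR-451 Cq difference.

    delta = Cq(miR-23a) - Cq(miR-451) on raw, pre-censoring values:
    haemolysis releases RBC-derived miR-451, lowering its Cq and raising the
    delta.  delta < 5 suggests little or no haemolysis; delta >= 7 indicates
    significant haemolysis; [5.0, 7.0) is moderate.  Samples with a
    non-detect in either assay fall into the three missing categories.
    """
    for a in (assay_23a, assay_451):
        if a not in raw.columns:
            raise KeyError(f"assay column {a!r} not in matrix")
    cq23 = raw[assay_23a]
    cq451 = raw[assay_451]
    delta = cq23 - cq451
    category = pd.Series("low", index=raw.index, dtype=object)
    category[delta >= 5.0] = "moderate"
    category[delta >= 7.0] = "high"
    category[cq451.isna() & cq23.notna()] = "missing_451"
    category[cq23.isna() & cq451.notna()] = "missing_23a"
    category[cq23.isna() & cq451.isna()] = "missing_both"
    counts = {c: int((category == c).sum()) for c in HAEMOLYSIS_CATEGORIES}
    n = len(raw.index)
    report = pd.DataFrame({"delta_cq": delta, "category": category})
    return HaemolysisReport(report, counts, 100.0 * counts["high"] / n)


def flag_bad_assays(
    censored: CensoredCq,
    ntc: CensoredCq,
    variance_floor: float = 0.05,
    ntc_detect_rate: float = 0.5,
) -> list[str]:
    """Flag assays with flat sample signal that also amplify in NTC wells.

    Consistent, non-variable expression in samples combined with expression
    in no-template controls indicates non-specific amplification; such
    assays are removed before analysis.  An assay is flagged when the sample
    variance of its expressed Cq values is below ``variance_floor`` AND the
    fraction of NTC rows in which it is expressed is >= ``ntc_detect_rate``.
    """
    if ntc.cq.shape[0] < 1:
        raise ValueError("need at least one NTC row")
    flagged = []
    for assay in censored.cq.columns:
        expr = censored.expressed[assay]
        vals = censored.cq.loc[expr, assay]
        if len(vals) < 2:
            continue
        var = float(vals.var(ddof=1))
        if assay in ntc.cq.columns:
            rate = float(ntc.expressed[assay].mean())
        else:
            rate = 0.0
        if var < variance_floor and rate >= ntc_detect_rate:
            flagged.append(assay)
    return flagged


@dataclass
class DetectionTables:
    per_assay: pd.DataFrame  # n_expressed, percent_expressed, mean_cq, sd_cq
    per_sample: pd.DataFrame  # detected counts per class
    class_medians: pd.Series  # median detected count per class


def detection_summary(
    censored: CensoredCq,
    assay_classes: pd.Series,
) -> DetectionTables:
    """Per-assay expression prevalence and per-sample per-class counts."""
    expressed = censored.expressed
    n = expressed.shape[0]
    n_expr = expressed.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_cq = censored.cq.where(expressed).mean(axis=0)
        sd_cq = censored.cq.where(expressed).std(axis=0, ddof=1)
    per_assay = pd.DataFrame(
        {
            "class": assay_classes.reindex(expressed.columns),
            "n_expressed": n_expr,
            "percent_expressed": 100.0 * n_expr / n,
            "mean_cq": mean_cq,
            "sd_cq": sd_cq,
        }
    )
    per_sample = pd.DataFrame(index=expressed.index)
    for cls in sorted(assay_classes.dropna().unique()):
        cols = assay_classes.index[assay_classes == cls]
        cols = [c for c in cols if c in expressed.columns]
        per_sample[cls] = expressed[cols].sum(axis=1)
    return DetectionTables(per_assay, per_sample, per_sample.median(axis=0))


def median_split(ages: pd.Series) -> tuple[pd.Series, float]:
    """Binary age covariate: 1 = younger than the sample median.

    Ties at the median go to group 0, so group 1 is strictly younger.
    """
    vals = ages.to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 ages")
    if np.all(vals == vals[0]):
        raise ValueError("all ages equal; no split possible")
    med = float(np.median(vals))
    return (ages < med).astype(int), med


def associate(
    delta: DeltaCq | pd.DataFrame,
    covariate: pd.Series,
    assay_classes: pd.Series | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-assay OLS of dCq on a 0/1 covariate with BH-FDR across assays.

    For a binary covariate the OLS slope equals the group-1 minus group-0
    mean difference and its t-test is the pooled-variance two-sample t
    (df = n - 2), computed here in closed form.  Fold-change = 2^(-slope):
    values above 1 mean more expressed (lower dCq) in the covariate = 1
    group.  Assays with zero residual variance get an undefined p and are
    excluded from the BH step with a warning.
    """
    ddf = delta.delta if isinstance(delta, DeltaCq) else delta
    cov = covariate.reindex(ddf.index).to_numpy(dtype=float)
    if np.isnan(cov).any():
        raise ValueError("covariate missing for some samples")
    g1 = cov == 1
    g0 = cov == 0
    if not g1.any() or not g0.any():
        raise ValueError("both covariate groups must be non-empty")

    x = ddf.to_numpy(dtype=float)
    valid = ~np.isnan(x)
    n1 = (valid & g1[:, None]).sum(axis=0)
    n0 = (valid & g0[:, None]).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(g1[:, None], x, np.nan), axis=0)
        m0 = np.nanmean(np.where(g0[:, None], x, np.nan), axis=0)
        v1 = np.nanvar(np.where(g1[:, None], x, np.nan), axis=0, ddof=1)
        v0 = np.nanvar(np.where(g0[:, None], x, np.nan), axis=0, ddof=1)
    slope = m1 - m0
    df = n1 + n0 - 2
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / np.where(df > 0, df, np.nan)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), np.where(df > 0, df, 1))
    p = np.where((df > 0) & (se > 0), p, np.nan)

    table = pd.DataFrame(
        {
            "slope": slope,
            "fold_change": np.power(2.0, -slope),
            "p": p,
            "q": np.nan,
            "significant": False,
        },
        index=ddf.columns,
    )
    if assay_classes is not None:
        table.insert(0, "class", assay_classes.reindex(ddf.columns))
    ok = table["p"].notna()
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} assays with undefined p excluded from BH"
        )
    if ok.any():
        rej, q, _, _ = multipletests(
            table.loc[ok, "p"].to_numpy(), alpha=fdr, method="fdr_bh"
        )
        table.loc[ok, "q"] = q
        table.loc[ok, "significant"] = rej
    return table
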