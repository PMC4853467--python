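"""Ordinal-scored principal factor analysis of dCq matrices.

Censoring non-detects at the cycle ceiling would inflate correlations among
unexpressed assays, so each dCq value is first reduced to an ordered three-
level score (0 = not expressed, 1 = expressed below the sample's global
mean, 2 = expressed above it).  The Spearman rank-correlation matrix of the
scores is then factored by the principal-axis method (squared multiple
correlations on the diagonal), rotated by varimax, and assays are assigned
exclusively to the factor on which their absolute rotated loading is
largest, provided it clears the 0.4 membership cutoff.

Factor target sets can then be compared (Venn region counts) and screened
for pathway over-representation with the hypergeometric tail test under
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qpcr_stats import DeltaCq


def ordinal_score(delta: DeltaCq) -> pd.DataFrame:
    """Three-level ordinal scores from dCq and expressed flags.

    0 = not expressed; 1 = expressed with dCq >= 0 (below the sample's
    global mean); 2 = expressed with dCq < 0 (above it).
    """
    d = delta.delta
    scores = pd.DataFrame(0, index=d.index, columns=d.columns, dtype=np.int8)
    scores[delta.expressed & (d >= 0)] = 1
    scores[delta.expressed & (d < 0)] = 2
    return scores


def spearman_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix over assays.

    Ties get average ranks (Pearson correlation of the rank transform).
    Zero-variance assays are excluded with a warning: their rank
    correlation is undefined.
    """
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    variances = scores.var(axis=0)
    dropped = list(scores.columns[variances == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance assays: {dropped[:5]}"
        )
        scores = scores.drop(columns=dropped)
    ranks = np.apply_along_axis(stats.rankdata, 0, scores.to_numpy(float))
    corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=scores.columns, columns=scores.columns)


@dataclass
class FactorSolution:
    corr: pd.DataFrame
    eigenvalues: np.ndarray  # full spectrum of the reduced matrix, desc
    loadings: pd.DataFrame  # unrotated, assays x k
    communalities: pd.Series


def principal_factors(corr: pd.DataFrame, k: int = 4,
                      ridge: float = 1e-8) -> FactorSolution:
    """Principal-axis factoring with SMC communality estimates.

    The correlation matrix diagonal is replaced by squared multiple
    correlations (1 - 1/diag(R^-1)); the reduced matrix is
    eigendecomposed and factor j's loadings are eigvec_j * sqrt(eig_j)
    (negative eigenvalues clipped to zero).  The full eigenvalue spectrum
    is returned for scree inspection; the number of retained factors is a
    caller choice (four for this cohort, chosen by scree), not automated.
    """
    R = corr.to_numpy(dtype=float)
    p = R.shape[0]
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if k >= p:
        raise ValueError("k must be smaller than the matrix dimension")
    try:
        Rinv = np.linalg.inv(R)
        if (np.diag(Rinv) <= 0).any():
            raise np.linalg.LinAlgError("non-positive inverse diagonal")
    except np.linalg.LinAlgError:
        warnings.warn("singular correlation matrix; ridge-regularised SMC")
        Rinv = np.linalg.inv(R + ridge * np.eye(p))
    smc = 1.0 - 1.0 / np.diag(Rinv)
    reduced = R.copy()
    np.fill_diagonal(reduced, smc)
    eigvals, eigvecs = np.linalg.eigh(reduced)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    load = eigvecs[:, :k] * np.sqrt(np.clip(eigvals[:k], 0.0, None))
    cols = [f"F{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(load, index=corr.index, columns=cols)
    return FactorSolution(
        corr,
        eigvals,
        loadings,
        pd.Series((load ** 2).sum(axis=1), index=corr.index),
    )


@dataclass
class VarimaxResult:
    loadings: pd.DataFrame
    rotation: np.ndarray
    converged: bool
    criterion_path: list[float]


def _varimax_criterion(L: np.ndarray) -> float:
    # sum over factors of the variance of squared loadings
    sq = L ** 2
    return float((sq ** 2).sum() - (sq.sum(axis=0) ** 2).sum() / L.shape[0])


def varimax(loadings: pd.DataFrame, tol: float = 1e-6,
            max_iter: int = 1000) -> VarimaxResult:
    """Orthogonal varimax rotation with Kaiser row normalisation.

    Maximises the variance of squared loadings per factor; row
    communalities are invariant.  After rotation each factor column is
    sign-fixed so its largest-|loading| entry is positive.  k = 1 returns
    the input unchanged.
    """
    L0 = loadings.to_numpy(dtype=float)
    p, k = L0.shape
    if k < 2:
        return VarimaxResult(loadings.copy(), np.eye(k), True, [])
    h = np.sqrt((L0 ** 2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    A = L0 / h_safe[:, None]
    R = np.eye(k)
    d = 0.0
    path = [_varimax_criterion(A)]
    converged = False
    for _ in range(max_iter):
        Lr = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        path.append(_varimax_criterion(A @ R))
        if d_new <= d * (1 + tol):
            converged = True
            break
        d = d_new
    if not converged:
        warnings.warn("varimax did not converge; returning best iterate")
    out = (A @ R) * h_safe[:, None]
    # column sign convention: largest-|loading| entry positive
    signs = np.sign(out[np.abs(out).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    out = out * signs
    return VarimaxResult(
        pd.DataFrame(out, index=loadings.index, columns=loadings.columns),
        R * signs,
        converged,
        path,
    )


@dataclass
class FactorMembership:
    membership: pd.Series  # assay -> "F1".."Fk" or "None"
    qualifying: pd.DataFrame  # boolean, |loading| > cutoff
    counts: pd.Series  # per label
    summary: pd.DataFrame | None  # per-factor metadata summaries


def assign_membership(
    rotated: pd.DataFrame,
    cutoff: float = 0.4,
    assay_metadata: pd.DataFrame | None = None,
) -> FactorMembership:
    """Exclusive factor membership from rotated loadings.

    An assay belongs to a factor only if some |loading| exceeds the cutoff
    (0.4); among qualifying factors, the one with maximum |loading| wins,
    giving exclusive counts.  Assays clearing the cutoff nowhere are
    labelled "None".  Optional ``assay_metadata`` (e.g. detection rate and
    mean Cq per assay) yields per-factor mean +/- sd and range summaries.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    absL = rotated.abs()
    qualifying = absL > cutoff
    member = pd.Series("None", index=rotated.index, dtype=object)
    any_q = qualifying.any(axis=1)
    member[any_q] = absL[any_q].idxmax(axis=1)
    labels = list(rotated.columns) + ["None"]
    counts = pd.Series(
        [int((member == lab).sum()) for lab in labels], index=labels
    )
    summary = None
    if assay_metadata is not None:
        rows = []
        for lab in labels:
            sub = assay_metadata.reindex(member.index[member == lab])
            for col in assay_metadata.columns:
                v = sub[col].astype(float)
                rows.append(
                    (lab, col, len(sub), v.mean(), v.std(ddof=1),
                     v.min(), v.max())
                )
        summary = pd.DataFrame(
            rows,
            columns=["factor", "variable", "n", "mean", "sd", "min", "max"],
        )
    return FactorMembership(member, qualifying, counts, summary)


def set_overlaps(target_sets: dict[str, set]) -> dict[str, int]:
    """Counts for every region of the Venn partition of the given sets.

    Keys are '+'-joined sorted member names (e.g. ``"F1+F3"`` = elements in
    exactly F1 and F3); also includes ``"union"`` and per-set exclusive
    ``"only_<name>"`` counts.  Region counts sum to the union size.
    """
    if len(target_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(target_sets)
    union = set().union(*target_sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(target_sets[n] for n in combo))
            outside = set().union(
                *(target_sets[n] for n in names if n not in combo), set()
            )
            regions["+".join(combo)] = len(inside - outside)
    out = dict(regions)
    out["union"] = len(union)
    for n in names:
        out[f"only_{n}"] = regions[n]
    return out


def enrichment(
    query: set,
    annotation: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric pathway over-representation with BH correction.

    For each pathway, the upper-tail probability of drawing at least the
    observed overlap when |query| genes are sampled from the universe
    without replacement; enriched iff BH-adjusted p < alpha.  Target maps
    should be pre-filtered upstream (prediction score >= 80) before their
    unions become queries.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for pw in sorted(annotation):
        genes = annotation[pw]
        if not genes <= universe:
            raise ValueError(f"pathway {pw!r} not a subset of the universe")
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N)) if N else 1.0
        rows.append((pw, len(genes), k, p))
    table = pd.DataFrame(
        rows, columns=["pathway", "set_size", "overlap", "p"]
    ).set_index("pathway")
    if len(table):
        _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["q"] = q
        table["enriched"] = (table["q"] < alpha) & (table["overlap"] > 0)
    return table


def filter_targets(
    target_map: pd.DataFrame, score_floor: float = 80.0
) -> dict[str, set]:
    """mirna -> target-gene set, keeping predictions scoring >= the floor."""
    kept = target_map[target_map["score"] >= score_floor]
    return {
        m: set(g["gene_id"]) for m, g in kept.groupby("mirna_id")
    }
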