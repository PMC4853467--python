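"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-statements of the rules they
check (exhaustive enumeration, brute-force definitions); they never call
the implementation paths they verify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exrna import synthetic_data as sim


# ---------------------------------------------------------------------------
# Brute-force alignment oracle
# ---------------------------------------------------------------------------

def oracle_hits(seq, entries, max_mm=1, seed_len=19, max_overhang=3):
    """Enumerate every (reference, offset, overhang) placement.

    Returns {(mismatches, overhang): {species, ...}} over all placements
    within the mismatch budget; overhang trimming never shortens the query
    below the seed length.
    """
    hits: dict[tuple[int, int], set[str]] = {}
    max_h = min(max_overhang, max(0, len(seq) - seed_len))
    for h in range(max_h + 1):
        q = seq[: len(seq) - h]
        for sp, ref in entries:
            for s in range(len(ref) - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, ref[s:s + len(q)]))
                if mm <= max_mm:
                    hits.setdefault((mm, h), set()).add(sp)
    return hits


def oracle_assign(unique_sequences, refset, max_mm=1, seed_len=19,
                  max_overhang=3):
    """Brute-force hierarchical assignment: class order, min-cost ties,
    proportional splitting."""
    counts: dict[str, float] = {}
    unmapped = 0.0
    pending = list(unique_sequences)
    for cls in refset.class_order:
        entries = [(e.species_id, e.sequence) for e in refset.by_class(cls)]
        still = []
        for seq, mult in pending:
            hits = oracle_hits(seq, entries, max_mm, seed_len, max_overhang)
            if hits:
                winners = sorted(hits[min(hits)])
                for sp in winners:
                    counts[sp] = counts.get(sp, 0.0) + mult / len(winners)
            else:
                still.append((seq, mult))
        pending = still
    unmapped = float(sum(m for _, m in pending))
    return counts, unmapped


# ---------------------------------------------------------------------------
# Brute-force BH step-up
# ---------------------------------------------------------------------------

def oracle_bh(pvals: np.ndarray, alpha: float = 0.05):
    """Textbook BH: reject the k smallest p where k = max{i: p_(i) <= a i/m}.

    Also returns step-up adjusted p-values (monotone minimum from the top).
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= alpha * i / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    q_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return reject, q


# ---------------------------------------------------------------------------
# Factor label matching
# ---------------------------------------------------------------------------

def matched_recovery(truth_loadings: pd.DataFrame, membership: pd.Series):
    """(loaded-assay accuracy, noise->None rate) after optimal relabelling.

    Recovered factor labels are arbitrary up to permutation; match them to
    the planted labels by maximising the contingency-table trace.
    """
    from scipy.optimize import linear_sum_assignment

    loaded = truth_loadings.max(axis=1) > 0
    truth_f = truth_loadings[loaded].idxmax(axis=1)
    ct = pd.crosstab(truth_f, membership.reindex(truth_f.index))
    cols = [c for c in ct.columns if c != "None"]
    if not cols:
        acc = 0.0
    else:
        r, c = linear_sum_assignment(-ct[cols].to_numpy())
        acc = ct[cols].to_numpy()[r, c].sum() / int(loaded.sum())
    noise_idx = truth_loadings.index[~loaded]
    none_rate = (
        float((membership.reindex(noise_idx) == "None").mean())
        if len(noise_idx)
        else 1.0
    )
    return acc, none_rate


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_refset():
    return sim.make_reference_set(
        seed=11,
        class_sizes={"miRNA": 12, "piRNA": 8, "snoRNA": 5, "rRNA": 2,
                     "contaminant": 2},
        n_multimap_pairs=1,
    )


@pytest.fixture(scope="session")
def uniform_profile(small_refset):
    endog = [
        e.species_id
        for e in small_refset.entries
        if e.library_class not in sim.SCREEN_CLASSES
    ]
    return {s: 1.0 for s in endog}
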