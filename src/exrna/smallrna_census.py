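"""Hierarchical small-RNA read assignment and quantification.

Re-implements, at desk scale, the read-processing cascade used for plasma
extracellular small-RNA profiling: 3' adapter clipping, read collapsing with
N removal, contaminant and rRNA screening, hierarchical library assignment
with proportional multi-map splitting, reads-per-million normalisation,
mean-RPM detection calls and cross-cohort replication statistics.

The alignment engine is a bespoke exact/one-mismatch substring matcher
(hash-indexed by pigeonhole halves); the cascade itself, not a general-purpose
aligner, is the point, and every rule here has an exhaustive brute-force
oracle in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ReferenceSet, SCREEN_CLASSES

__all__ = [
    "ClippedReadSet",
    "AssignmentResult",
    "DetectionSummary",
    "ReplicationReport",
    "clip_adapter",
    "collapse_reads",
    "screen_library",
    "assign_hierarchical",
    "run_census",
    "counts_to_rpm",
    "detect_by_mean_rpm",
    "replication_overlap",
]


# ---------------------------------------------------------------------------
# Clipping and collapsing
# ---------------------------------------------------------------------------

@dataclass
class ClippedReadSet:
    """Unique clipped sequences with multiplicities and an audit trail."""

    unique_sequences: list[tuple[str, int]]
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def total_multiplicity(self) -> int:
        return sum(m for _, m in self.unique_sequences)


def clip_adapter(
    reads,
    adapter: str,
    min_overlap: int = 7,
    min_clipped_len: int = 16,
) -> tuple[list[str], dict[str, int]]:
    """Clip the 3' adapter off each read.

    A clip site is the leftmost position at which a prefix of the adapter,
    at least ``min_overlap`` bases long, exactly matches the read through to
    its 3' end.  Reads with no such site are dropped as ``no_adapter``;
    clipped inserts shorter than ``min_clipped_len`` (i.e. not longer than
    15 nt at the default) are dropped as ``too_short``.

    Returns the pre-collapse stream of clipped inserts plus audit counts.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    audit = {"input": 0, "no_adapter": 0, "too_short": 0}
    clipped: list[str] = []
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        audit["input"] += 1
        site = None
        # leftmost clip position whose adapter match reaches the read end
        for i in range(0, len(seq) - min_overlap + 1):
            tail = seq[i:]
            if len(tail) <= len(adapter) and adapter.startswith(tail):
                site = i
                break
        if site is None:
            audit["no_adapter"] += 1
            continue
        if site < min_clipped_len:
            audit["too_short"] += 1
            continue
        clipped.append(seq[:site])
    return clipped, audit


def collapse_reads(
    clipped: list[str], audit: dict[str, int] | None = None
) -> ClippedReadSet:
    """Collapse identical inserts and drop sequences containing N."""
    counts: dict[str, int] = {}
    contains_n = 0
    for seq in clipped:
        if "N" in seq:
            contains_n += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    out_audit = dict(audit) if audit else {"input": len(clipped),
                                           "no_adapter": 0, "too_short": 0}
    out_audit["contains_N"] = contains_n
    out_audit["retained"] = sum(counts.values())
    return ClippedReadSet(sorted(counts.items()), out_audit)


# ---------------------------------------------------------------------------
# Substring matcher
# ---------------------------------------------------------------------------

class SubstringIndex:
    """Exact/one-mismatch substring search over a set of reference sequences.

    Queries ask: which references contain this query as a substring with at
    most ``max_mismatches`` substitutions, and at what minimum mismatch
    count?  Exact hits use a per-length substring hash; one-mismatch hits use
    the pigeonhole split (one half of the query must match exactly).  Higher
    mismatch budgets fall back to a naive scan.
    """

    def __init__(self, entries: list[tuple[str, str]]):
        self.entries = entries  # (species_id, sequence)
        self._sub: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _table(self, length: int) -> dict[str, list[tuple[int, int]]]:
        tab = self._sub.get(length)
        if tab is None:
            tab = {}
            for ri, (_, seq) in enumerate(self.entries):
                for s in range(len(seq) - length + 1):
                    tab.setdefault(seq[s:s + length], []).append((ri, s))
            self._sub[length] = tab
        return tab

    @staticmethod
    def _hamming(a: str, b: str, cap: int) -> int:
        mm = 0
        for x, y in zip(a, b):
            if x != y:
                mm += 1
                if mm > cap:
                    return mm
        return mm

    def _verify(self, query, ri, start, cap, best):
        seq = self.entries[ri][1]
        if start < 0 or start + len(query) > len(seq):
            return
        mm = self._hamming(query, seq[start:start + len(query)], cap)
        if mm <= cap:
            sp = self.entries[ri][0]
            if mm < best.get(sp, cap + 1):
                best[sp] = mm

    def search(self, query: str, max_mismatches: int = 1) -> dict[str, int]:
        """species_id -> minimum mismatch count (<= max_mismatches)."""
        if not query:
            return {}
        best: dict[str, int] = {}
        m = len(query)
        for ri, s in self._table(m).get(query, ()):
            best[self.entries[ri][0]] = 0
        if max_mismatches == 0 or all(v == 0 for v in best.values()) and len(
            best
        ) == len(self.entries):
            return best
        if max_mismatches == 1:
            m1 = m // 2
            for ri, s in self._table(m1).get(query[:m1], ()):
                self._verify(query, ri, s, 1, best)
            for ri, s in self._table(m - m1).get(query[m1:], ()):
                self._verify(query, ri, s - m1, 1, best)
        elif max_mismatches > 1:
            for ri, (sp, seq) in enumerate(self.entries):
                for s in range(len(seq) - m + 1):
                    self._verify(query, ri, s, max_mismatches, best)
        return best


# ---------------------------------------------------------------------------
# Screening and hierarchical assignment
# ---------------------------------------------------------------------------

def screen_library(
    reads: ClippedReadSet,
    screen: ReferenceSet,
    max_mismatches: int = 1,
) -> tuple[ClippedReadSet, int]:
    """Archive reads contained in any screening sequence (<=1 mismatch).

    The screening set must be a single class (contaminant or rRNA); a read is
    archived if some screen sequence contains it as a substring with at most
    ``max_mismatches`` substitutions.  Survivors pass through unchanged.
    """
    classes = {e.library_class for e in screen.entries}
    if classes - set(SCREEN_CLASSES):
        raise ValueError(f"screen classes must be in {SCREEN_CLASSES}")
    index = SubstringIndex(
        [(e.species_id, e.sequence) for e in screen.entries]
    )
    survivors: list[tuple[str, int]] = []
    archived = 0
    for seq, mult in reads.unique_sequences:
        if index.search(seq, max_mismatches):
            archived += mult
        else:
            survivors.append((seq, mult))
    return ClippedReadSet(survivors, dict(reads.audit)), archived


@dataclass
class AssignmentResult:
    """Fractional per-species counts plus a stage-by-stage audit."""

    counts: dict[str, float]
    audit: dict[str, float]

    @property
    def total_assigned(self) -> float:
        return sum(self.counts.values())


def assign_hierarchical(
    reads: ClippedReadSet,
    refset: ReferenceSet,
    max_mismatches: int = 1,
    seed_len: int = 19,
    max_3p_overhang: int = 3,
) -> AssignmentResult:
    """Assign reads to library classes in order, splitting multi-maps.

    Libraries are tried in ``refset.class_order``; a read claimed by an
    earlier library never reaches a later one.  Within a library a read hits
    a reference when its 5'-anchored prefix (full length minus a 3' overhang
    h, 0 <= h <= ``max_3p_overhang``) occurs as a substring of the reference
    with at most ``max_mismatches`` substitutions; overhang trimming never
    shortens the query below the ``seed_len`` 5' seed.  Equally valid hits
    are those achieving the library's minimal (mismatches, overhang)
    lexicographic cost; a read hitting k species at that cost contributes
    multiplicity/k to each.
    """
    for cls in refset.class_order:
        if not refset.by_class(cls):
            raise ValueError(f"class_order names empty class {cls!r}")
    indexes = {
        cls: SubstringIndex(
            [(e.species_id, e.sequence) for e in refset.by_class(cls)]
        )
        for cls in refset.class_order
    }
    counts: dict[str, float] = {}
    audit: dict[str, float] = {f"mapped_{c}": 0.0 for c in refset.class_order}
    pending = list(reads.unique_sequences)
    for cls in refset.class_order:
        index = indexes[cls]
        still: list[tuple[str, int]] = []
        for seq, mult in pending:
            max_h = min(max_3p_overhang, max(0, len(seq) - seed_len))
            hits: dict[tuple[int, int], set[str]] = {}
            for h in range(max_h + 1):
                for sp, mm in index.search(seq[: len(seq) - h],
                                           max_mismatches).items():
                    hits.setdefault((mm, h), set()).add(sp)
            if hits:
                best = min(hits)
                winners = sorted(hits[best])
                share = mult / len(winners)
                for sp in winners:
                    counts[sp] = counts.get(sp, 0.0) + share
                audit[f"mapped_{cls}"] += mult
            else:
                still.append((seq, mult))
        pending = still
    audit["unmapped"] = float(sum(m for _, m in pending))
    return AssignmentResult(counts, audit)


def run_census(
    reads,
    refset: ReferenceSet,
    adapter: str,
    min_overlap: int = 7,
    min_clipped_len: int = 16,
    max_mismatches: int = 1,
    seed_len: int = 19,
    max_3p_overhang: int = 3,
) -> AssignmentResult:
    """Full single-sample cascade: clip, collapse, screen, assign.

    Returns an :class:`AssignmentResult` whose audit covers every stage;
    the screened contaminant and rRNA multiplicities are recorded under
    ``screened_contaminant`` and ``screened_rRNA``.
    """
    clipped, clip_audit = clip_adapter(
        reads, adapter, min_overlap=min_overlap,
        min_clipped_len=min_clipped_len
    )
    creads = collapse_reads(clipped, clip_audit)
    audit = dict(creads.audit)
    for cls in SCREEN_CLASSES:
        screen = refset.subset({cls})
        if screen.entries:
            creads, archived = screen_library(creads, screen, max_mismatches)
        else:
            archived = 0
        audit[f"screened_{cls}"] = archived
    result = assign_hierarchical(
        creads, refset, max_mismatches=max_mismatches,
        seed_len=seed_len, max_3p_overhang=max_3p_overhang
    )
    audit.update(result.audit)
    return AssignmentResult(result.counts, audit)


# ---------------------------------------------------------------------------
# RPM, detection, replication
# ---------------------------------------------------------------------------

def counts_to_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million of total mapped reads, per sample (row).

    Samples with zero mapped reads get an all-missing row.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    rpm = counts.div(totals.where(totals > 0), axis=0) * 1e6
    return rpm


@dataclass
class DetectionSummary:
    threshold: float
    mean_rpm: pd.Series
    detected: set[str]
    per_class: dict[str, int]


def detect_by_mean_rpm(
    rpm: pd.DataFrame,
    classes: dict[str, str],
    threshold: float = 1000.0,
) -> DetectionSummary:
    """Call a species detected when its mean RPM across samples >= threshold."""
    if rpm.shape[0] < 1:
        raise ValueError("need at least one sample")
    mean_rpm = rpm.mean(axis=0, skipna=True).fillna(0.0)
    detected = set(mean_rpm.index[mean_rpm >= threshold])
    per_class: dict[str, int] = {}
    for sp in detected:
        cls = classes.get(sp, "unknown")
        per_class[cls] = per_class.get(cls, 0) + 1
    return DetectionSummary(threshold, mean_rpm, detected, per_class)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (n <= 8)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    denom_x = rx - rx.mean()
    denom_y = ry - ry.mean()
    sx = math.sqrt((denom_x ** 2).sum())
    sy = math.sqrt((denom_y ** 2).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float((denom_x * denom_y[list(perm)]).sum() / (sx * sy))
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


@dataclass
class ReplicationReport:
    """Per-class cross-cohort overlap and rank-correlation summary."""

    per_class: pd.DataFrame  # n_a, n_overlap, overlap_percent, rho, p


def replication_overlap(
    rpm_a: pd.DataFrame,
    detected_a: set[str],
    rpm_b: pd.DataFrame,
    classes: dict[str, str],
    threshold: float = 1000.0,
) -> ReplicationReport:
    """Overlap of cohort A's detected species with cohort B, per class.

    B's detected set is computed with the same mean-RPM >= threshold rule;
    the overlap percentage is 100 * |A n B| / |A|.  Co-expression across
    cohorts is Spearman's rho of log mean RPM over the overlap, with an
    exact permutation two-sided p-value when |A n B| <= 8 and the
    t-approximation otherwise; rho is undefined below 3 overlapping species.
    """
    detected_b = detect_by_mean_rpm(rpm_b, classes, threshold).detected
    mean_a = rpm_a.mean(axis=0, skipna=True)
    mean_b = rpm_b.mean(axis=0, skipna=True)
    rows = []
    for cls in sorted({classes.get(s, "unknown") for s in detected_a}):
        a_cls = {s for s in detected_a if classes.get(s, "unknown") == cls}
        overlap = sorted(a_cls & detected_b)
        n_a, n_ov = len(a_cls), len(overlap)
        pct = 100.0 * n_ov / n_a if n_a else float("nan")
        rho = p = float("nan")
        if n_ov >= 3:
            la = np.log(mean_a[overlap].to_numpy(dtype=float))
            lb = np.log(mean_b[overlap].to_numpy(dtype=float))
            rho_res = stats.spearmanr(la, lb)
            rho = float(rho_res.statistic)
            if n_ov <= 8:
                p = _spearman_exact_p(la, lb, rho)
            else:
                p = float(rho_res.pvalue)
        rows.append((cls, n_a, n_ov, pct, rho, p))
    table = pd.DataFrame(
        rows,
        columns=["class", "n_a", "n_overlap", "overlap_percent", "rho", "p"],
    ).set_index("class")
    return ReplicationReport(table)
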