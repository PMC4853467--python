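"""Synthetic inputs with recorded ground truth for the exRNA pipeline.

Every downstream stage (read cascade, Cq statistics, factor analysis,
compartment comparison) consumes data that this module can fabricate with a
known generative truth, so the whole pipeline is testable without access to
restricted cohort data.  All generators take an explicit integer seed and use
a single :func:`numpy.random.default_rng` stream per call; identical calls
are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"

#: Screening classes are consumed before hierarchical assignment.
SCREEN_CLASSES = ("contaminant", "rRNA")

#: Canonical order in which libraries are tried during assignment.
DEFAULT_CLASS_ORDER = ("miRNA", "tRNA", "piRNA", "snoRNA", "exogenous")

#: Full 3' sequence ligated downstream of the insert (adapter + primer tail);
#: long enough that a 50 nt read never runs past it.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCACATCACGATCTCGTATGCCGTCTTCTGCTTG"

#: Reads are a fixed 50 nt before clipping; inserts of 15-45 nt leave the
#: adapter partially present, exercising both the >=7 adapter-base rule and
#: the >15 nt clipped-length rule.
READ_LENGTH = 50

#: Insert length ranges (nt) per library class.  miRNAs are 21-24 nt, piRNAs
#: 26-31 nt; tRNA/snoRNA entries model the fragments seen in plasma.
#: Screening references are long so that reads are substrings of them.
DEFAULT_LENGTH_RANGES = {
    "miRNA": (21, 24),
    "tRNA": (18, 36),
    "piRNA": (26, 31),
    "snoRNA": (20, 40),
    "rRNA": (100, 160),
    "contaminant": (100, 160),
    "exogenous": (20, 24),
}

_CANONICAL_CLASSES = (
    "miRNA",
    "tRNA",
    "piRNA",
    "snoRNA",
    "rRNA",
    "contaminant",
    "exogenous",
)

ND = float("nan")  # in-memory non-detect marker; serialised as "ND"

DEFAULT_COMPONENTS = (
    "plasma",
    "exosomes",
    "platelets",
    "PBMCs",
    "RBCs",
    "T cells",
    "B cells",
    "neutrophils",
)


# ---------------------------------------------------------------------------
# Reference sets and reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefEntry:
    species_id: str
    library_class: str
    sequence: str


@dataclass
class ReferenceSet:
    """Labelled small-RNA reference sequences in ordered library classes."""

    entries: list[RefEntry]
    class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER

    def __post_init__(self) -> None:
        ids = [e.species_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("species_id values must be unique")
        for e in self.entries:
            if not e.sequence or set(e.sequence) - set(BASES):
                raise ValueError(
                    f"{e.species_id}: sequence must be non-empty A/C/G/T"
                )
            if e.library_class not in self.class_order and (
                e.library_class not in SCREEN_CLASSES
            ):
                raise ValueError(
                    f"{e.species_id}: class {e.library_class!r} not in "
                    f"class_order or screening classes"
                )

    def by_class(self, library_class: str) -> list[RefEntry]:
        return [e for e in self.entries if e.library_class == library_class]

    @property
    def classes(self) -> dict[str, str]:
        """species_id -> library class."""
        return {e.species_id: e.library_class for e in self.entries}

    def subset(self, classes: set[str] | tuple[str, ...]) -> "ReferenceSet":
        return ReferenceSet(
            [e for e in self.entries if e.library_class in classes],
            class_order=self.class_order,
        )


@dataclass
class SimulatedReadSet:
    """Adapter-ligated reads plus their generative truth."""

    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: dict[str, str]  # read_id -> source species_id
    adapter: str
    params: dict = field(default_factory=dict)

    def truth_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for sp in self.truth.values():
            out[sp] = out.get(sp, 0) + 1
        return out


def _random_unique_seqs(rng, n: int, lo: int, hi: int, label: str) -> list[str]:
    space = sum(4 ** L for L in range(lo, hi + 1))
    if n > space:
        raise ValueError(
            f"cannot draw {n} unique sequences of {lo}-{hi} nt for class "
            f"{label!r}: only {space} exist"
        )
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(BASES), size=L))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def make_reference_set(
    seed: int,
    class_sizes: dict[str, int],
    length_ranges: dict[str, tuple[int, int]] | None = None,
    n_multimap_pairs: int = 0,
) -> ReferenceSet:
    """Build a deterministic toy reference library.

    ``n_multimap_pairs`` pairs of distinct piRNA species share an identical
    sequence, so proportional multi-map splitting can be exercised; every
    other sequence in the set is unique.
    """
    ranges = dict(DEFAULT_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    for cls, n in class_sizes.items():
        if n < 0:
            raise ValueError(f"negative count for class {cls!r}")
        lo, hi = ranges[cls]
        if lo > hi:
            raise ValueError(f"bad length range for class {cls!r}")
    n_pir = class_sizes.get("piRNA", 0)
    if n_multimap_pairs * 2 > n_pir:
        raise ValueError("n_multimap_pairs exceeds piRNA count / 2")

    rng = np.random.default_rng(seed)
    entries: list[RefEntry] = []
    # canonical class order keeps generation deterministic regardless of
    # dict insertion order
    for cls in _CANONICAL_CLASSES:
        n = class_sizes.get(cls, 0)
        if n == 0:
            continue
        lo, hi = ranges[cls]
        seqs = _random_unique_seqs(rng, n, lo, hi, cls)
        if cls == "piRNA":
            for i in range(n_multimap_pairs):
                seqs[2 * i + 1] = seqs[2 * i]
        for i, seq in enumerate(seqs):
            entries.append(RefEntry(f"{cls}-{i + 1:03d}", cls, seq))
    order = tuple(
        c for c in DEFAULT_CLASS_ORDER
        if class_sizes.get(c, 0) > 0
    ) or DEFAULT_CLASS_ORDER
    return ReferenceSet(entries, class_order=order)


def _mutate(rng, seq: str, sub_rate: float, n_rate: float) -> str:
    if sub_rate == 0 and n_rate == 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if sub_rate > 0 and rng.random() < sub_rate:
            chars[i] = BASES[(BASES.index(c) + int(rng.integers(1, 4))) % 4]
        if n_rate > 0 and rng.random() < n_rate:
            chars[i] = "N"
    return "".join(chars)


def simulate_reads(
    refset: ReferenceSet,
    n_reads: int,
    profile: dict[str, float],
    adapter: str = DEFAULT_ADAPTER,
    sub_rate: float = 0.0,
    n_rate: float = 0.0,
    contaminant_frac: float = 0.0,
    seed: int = 0,
    read_length: int = READ_LENGTH,
) -> SimulatedReadSet:
    """Draw adapter-ligated 50 nt reads from a reference set.

    Each read is an (optionally error-mutated) reference sequence followed by
    the 3' adapter, truncated at ``read_length``.  ``contaminant_frac`` of
    reads are drawn instead from contaminant/rRNA screening references, as
    random fragments of those longer sequences.  The per-read source species
    is recorded as truth.
    """
    if len(adapter) < 7:
        raise ValueError("adapter must be at least 7 nt")
    if not profile:
        raise ValueError("abundance profile is empty")
    by_id = {e.species_id: e for e in refset.entries}
    unknown = set(profile) - set(by_id)
    if unknown:
        raise ValueError(f"profile names unknown species: {sorted(unknown)}")
    species = sorted(profile)
    weights = np.array([profile[s] for s in species], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("profile weights must be non-negative, sum > 0")
    weights = weights / weights.sum()
    screens = [e for e in refset.entries if e.library_class in SCREEN_CLASSES]
    if contaminant_frac > 0 and not screens:
        raise ValueError("contaminant_frac > 0 but no screening references")

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    for i in range(n_reads):
        rid = f"read{i + 1:06d}"
        if contaminant_frac > 0 and rng.random() < contaminant_frac:
            e = screens[int(rng.integers(len(screens)))]
            frag_len = min(len(e.sequence), int(rng.integers(16, 41)))
            start = int(rng.integers(0, len(e.sequence) - frag_len + 1))
            insert = e.sequence[start:start + frag_len]
        else:
            e = by_id[species[int(rng.choice(len(species), p=weights))]]
            insert = e.sequence
        insert = _mutate(rng, insert, sub_rate, n_rate)
        reads.append((rid, (insert + adapter)[:read_length]))
        truth[rid] = e.species_id
    return SimulatedReadSet(
        reads=reads,
        truth=truth,
        adapter=adapter,
        params={
            "profile": dict(profile),
            "sub_rate": sub_rate,
            "n_rate": n_rate,
            "contaminant_frac": contaminant_frac,
            "seed": seed,
        },
    )


def dominant_pair_profile(
    refset: ReferenceSet,
    pair: tuple[str, str],
    pair_weight: float = 0.47,
    seed: int = 0,
) -> dict[str, float]:
    """Abundance profile with a dominant miRNA pair over a log-normal tail.

    Plasma small-RNA profiles are dominated by two miRNAs carrying ~47% of
    the reads; the remaining endogenous species receive log-normal weights
    (the tail shape is a modelling choice, not prescribed by the data).
    """
    rng = np.random.default_rng(seed)
    endog = [
        e.species_id
        for e in refset.entries
        if e.library_class not in SCREEN_CLASSES
    ]
    rest = [s for s in endog if s not in pair]
    if not set(pair) <= set(endog):
        raise ValueError("dominant pair must be endogenous species")
    tail = rng.lognormal(mean=0.0, sigma=1.0, size=len(rest))
    tail = tail / tail.sum() * (1.0 - pair_weight)
    profile = {pair[0]: pair_weight / 2, pair[1]: pair_weight / 2}
    profile.update(dict(zip(rest, tail)))
    return profile


# ---------------------------------------------------------------------------
# Cq cohorts
# ---------------------------------------------------------------------------

#: Haemolysis QC addresses these two assay columns by name.
HAEMOLYSIS_ASSAYS = ("miR-23a", "miR-451")

#: The cohort's haemolysis layout: per-category sample counts.
DEFAULT_HAEMOLYSIS_DESIGN = {
    "low": 2179,
    "moderate": 439,
    "high": 24,
    "missing_451": 9,
    "missing_23a": 24,
    "missing_both": 88,
}

_HAEMO_DELTA_RANGES = {
    "low": (1.0, 4.99),
    "moderate": (5.0, 6.99),
    "high": (7.0, 8.42),
}


@dataclass
class CohortSimSpec:
    """Generative description of an RT-qPCR cohort.

    Defaults mirror the profiled population: 2,763 samples over 471 assays
    (331 miRNA, 97 piRNA, 43 snoRNA), four latent factors, age and sex
    covariate effects in Cq units, per-assay Bernoulli detection, and a
    haemolysis layout realised in two reserved assay columns.
    """

    n_samples: int = 2763
    assay_counts: dict[str, int] = field(
        default_factory=lambda: {"miRNA": 331, "piRNA": 97, "snoRNA": 43}
    )
    n_latent_factors: int = 4
    loading: float = 0.8
    #: assays loaded per factor; None spreads all assays over the factors.
    assays_per_factor: int | None = None
    factor_scale: float = 1.0
    noise_sd: float = 0.6
    baseline_range: tuple[float, float] = (13.0, 21.0)
    detection_prob: float = 1.0  # per-assay probability an entry amplifies
    censor_value: float = 24.0
    age_effect_assays: tuple[str, ...] = ()
    age_effect: float = 0.0  # Cq units added for the older half of samples
    sex_effect_assays: tuple[str, ...] = ()
    sex_effect: float = 0.0  # Cq units added for female samples
    haemolysis_design: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.assay_counts.values()):
            raise ValueError("assay counts must be positive")
        if not (0 < self.loading <= 1):
            raise ValueError("loading magnitude must be in (0, 1]")
        if not (0 <= self.detection_prob <= 1):
            raise ValueError("detection probability must be in [0, 1]")

    @classmethod
    def planted_factors(cls, seed: int = 0) -> "CohortSimSpec":
        """Canonical planted-factor recovery condition.

        Four orthogonal factors, loading 0.8, 20 assays each, 40 pure-noise
        assays, 2,000 samples.  Assay baselines sit just below the Cq < 23
        detection cutoff so factor swings drive detection itself — the
        regime in which the cohort's factors were detection-rate-defined —
        keeping the three-level ordinal score informative after per-sample
        centering.
        """
        return cls(
            n_samples=2000,
            assay_counts={"miRNA": 120},
            n_latent_factors=4,
            assays_per_factor=20,
            loading=0.8,
            factor_scale=1.5,
            noise_sd=0.6,
            baseline_range=(21.0, 23.0),
            seed=seed,
        )

    @property
    def assay_ids(self) -> list[str]:
        out = []
        for cls in ("miRNA", "piRNA", "snoRNA"):
            out += [
                f"{cls}-a{i + 1:03d}"
                for i in range(self.assay_counts.get(cls, 0))
            ]
        return out

    @property
    def assay_classes(self) -> pd.Series:
        ids = self.assay_ids
        return pd.Series(
            [a.split("-a")[0] for a in ids], index=ids, name="class"
        )


@dataclass
class SimulatedCohort:
    cq: pd.DataFrame  # samples x assays, NaN = non-detect
    phenotypes: pd.DataFrame  # age (years), sex (1 = female)
    assay_classes: pd.Series
    truth: dict


def simulate_cq_cohort(spec: CohortSimSpec) -> SimulatedCohort:
    """Generate a Cq cohort with planted factor/covariate/haemolysis truth.

    Cq(s, a) = baseline_a + scale * loading_{a,f} * z_{s,f}
               + age/sex effects + Gaussian noise; entries failing the
    per-assay detection draw are emitted as the non-detect marker (NaN).
    """
    assays = spec.assay_ids
    n_assays = len(assays)
    if spec.n_latent_factors > n_assays:
        raise ValueError("more latent factors than assays")
    bad = (set(spec.age_effect_assays) | set(spec.sex_effect_assays)) - set(
        assays
    )
    if bad:
        raise ValueError(f"effect sets name unknown assays: {sorted(bad)}")

    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_latent_factors

    age = rng.normal(67.0, 9.0, size=n)
    sex = (rng.random(n) < 0.54).astype(int)  # 1 = female
    samples = [f"S{i + 1:04d}" for i in range(n)]
    pheno = pd.DataFrame({"age": age, "sex": sex}, index=samples)

    baseline = rng.uniform(*spec.baseline_range, size=n_assays)
    loadings = np.zeros((n_assays, max(k, 1)))
    if k > 0:
        # contiguous blocks of assays load on one factor each; any assays
        # beyond k * block are pure noise
        block = spec.assays_per_factor or n_assays // k
        if k * block > n_assays:
            raise ValueError("assays_per_factor * k exceeds assay count")
        for f in range(k):
            loadings[f * block:(f + 1) * block, f] = spec.loading
    scores = rng.standard_normal((n, max(k, 1)))

    cq = baseline[None, :] + spec.factor_scale * scores @ loadings.T
    if spec.noise_sd > 0:
        cq = cq + rng.normal(0.0, spec.noise_sd, size=(n, n_assays))
    age_idx = [assays.index(a) for a in spec.age_effect_assays]
    if age_idx:
        # shift for the older half, mirroring the median-split analysis
        older = (age >= np.median(age)).astype(float)
        cq[np.ix_(older == 1, age_idx)] += spec.age_effect
    sex_idx = [assays.index(a) for a in spec.sex_effect_assays]
    if sex_idx:
        cq[:, sex_idx] += spec.sex_effect * sex[:, None]

    if spec.detection_prob < 1.0:
        nd = rng.random((n, n_assays)) >= spec.detection_prob
        cq = np.where(nd, np.nan, cq)

    cq_df = pd.DataFrame(cq, index=samples, columns=assays)

    # haemolysis pair: two reserved columns constructed to the target bins
    design = spec.haemolysis_design
    haem_bins = None
    if design is not None:
        if sum(design.values()) != n:
            raise ValueError("haemolysis design counts must sum to n_samples")
        labels: list[str] = []
        for cat, cnt in design.items():
            if cat not in set(_HAEMO_DELTA_RANGES) | {
                "missing_451", "missing_23a", "missing_both"
            }:
                raise ValueError(f"unknown haemolysis category {cat!r}")
            labels += [cat] * cnt
        labels = list(rng.permutation(labels))
        cq23 = np.full(n, np.nan)
        cq451 = np.full(n, np.nan)
        for i, cat in enumerate(labels):
            if cat == "missing_both":
                continue
            base23 = rng.normal(19.0, 0.5)
            if cat == "missing_451":
                cq23[i] = base23
            elif cat == "missing_23a":
                cq451[i] = base23 - rng.uniform(1.0, 5.0)
            else:
                lo, hi = _HAEMO_DELTA_RANGES[cat]
                cq23[i] = base23
                cq451[i] = base23 - rng.uniform(lo, hi)
        cq_df[HAEMOLYSIS_ASSAYS[0]] = cq23
        cq_df[HAEMOLYSIS_ASSAYS[1]] = cq451
        haem_bins = pd.Series(labels, index=samples, name="haemolysis_bin")

    truth = {
        "loadings": pd.DataFrame(
            loadings,
            index=assays,
            columns=[f"F{j + 1}" for j in range(max(k, 1))],
        ),
        "age_effect_assays": tuple(spec.age_effect_assays),
        "sex_effect_assays": tuple(spec.sex_effect_assays),
        "haemolysis_bins": haem_bins,
    }
    return SimulatedCohort(
        cq=cq_df,
        phenotypes=pheno,
        assay_classes=spec.assay_classes,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Blood-component panels
# ---------------------------------------------------------------------------

def simulate_component_panel(
    n_donors: int = 6,
    components: tuple[str, ...] = DEFAULT_COMPONENTS,
    planted_direction: dict[tuple[str, str], str] | None = None,
    effect: float = 2.0,
    noise_sd: float = 0.2,
    assays: tuple[str, ...] = ("miR-x1", "miR-x2", "piR-x1"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor, per-component Cq panel with planted plasma-relative shifts.

    ``planted_direction`` maps (assay, component) to ``up_in_plasma`` /
    ``down_in_plasma`` / ``null``; plasma-enriched assays get a *higher*
    component Cq by ``effect`` cycles (lower Cq = more abundant).  Returns a
    long-format panel (donor_id, component, assay_id, cq) and the planted
    truth table.
    """
    if n_donors < 2:
        raise ValueError("need at least 2 donors")
    if "plasma" not in components:
        raise ValueError("components must include the plasma referent")
    planted = planted_direction or {}
    for (assay, comp), d in planted.items():
        if comp not in components:
            raise ValueError(f"unknown component label {comp!r}")
        if assay not in assays:
            raise ValueError(f"unknown assay {assay!r}")
        if d not in ("up_in_plasma", "down_in_plasma", "null"):
            raise ValueError(f"unknown direction {d!r}")

    rng = np.random.default_rng(seed)
    baseline = {a: rng.uniform(14.0, 21.0) for a in assays}
    rows = []
    for d in range(n_donors):
        donor = f"D{d + 1}"
        for comp in components:
            for a in assays:
                mu = baseline[a]
                direction = planted.get((a, comp), "null")
                if comp != "plasma":
                    if direction == "up_in_plasma":
                        mu += effect
                    elif direction == "down_in_plasma":
                        mu -= effect
                cq = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((donor, comp, a, cq))
    panel = pd.DataFrame(
        rows, columns=["donor_id", "component", "assay_id", "cq"]
    )
    truth_rows = [
        (a, c, planted.get((a, c), "null"))
        for a in assays
        for c in components
        if c != "plasma"
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["assay_id", "component", "direction"]
    )
    return panel, truth
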