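"""Read-cascade rules against brute-force oracles and worked arithmetic."""

import numpy as np
import pandas as pd
import pytest

from exrna import smallrna_census as census
from exrna import synthetic_data as sim
from exrna.synthetic_data import ReferenceSet, RefEntry

from conftest import oracle_assign, oracle_hits

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _clip_site_oracle(seq, adapter, min_overlap):
    """Naive scan of every suffix position."""
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if len(tail) <= len(adapter) and adapter[: len(tail)] == tail:
            return i
    return None


class TestClipAdapter:
    def test_eight_adapter_bases_clip_and_retain(self):
        read = "A" * 20 + ADAPTER[:8]
        clipped, audit = census.clip_adapter([read], ADAPTER)
        assert clipped == ["A" * 20]
        assert audit == {"input": 1, "no_adapter": 0, "too_short": 0}

    def test_six_adapter_bases_is_no_adapter(self):
        read = "A" * 20 + ADAPTER[:6]
        clipped, audit = census.clip_adapter([read], ADAPTER)
        assert clipped == [] and audit["no_adapter"] == 1

    def test_fifteen_nt_insert_is_too_short(self):
        read = "A" * 15 + ADAPTER[:10]
        clipped, audit = census.clip_adapter([read], ADAPTER)
        assert clipped == [] and audit["too_short"] == 1

    def test_sixteen_nt_insert_retained(self):
        read = "A" * 16 + ADAPTER[:10]
        clipped, _ = census.clip_adapter([read], ADAPTER)
        assert clipped == ["A" * 16]

    def test_matches_suffix_scan_oracle_on_random_reads(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(20, 51))
            read = "".join(rng.choice(list("ACGT"), n))
            if rng.random() < 0.7:
                cut = int(rng.integers(10, n))
                read = read[:cut] + ADAPTER[: n - cut]
            site = _clip_site_oracle(read, ADAPTER, 7)
            clipped, audit = census.clip_adapter([read], ADAPTER)
            if site is None:
                assert audit["no_adapter"] == 1
            elif site < 16:
                assert audit["too_short"] == 1
            else:
                assert clipped == [read[:site]]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            census.clip_adapter(["ACGT"], "")


class TestCollapseReads:
    def test_collapse_counts(self):
        out = census.collapse_reads(["ACGT" * 5, "ACGT" * 5, "TTTT" * 5])
        assert dict(out.unique_sequences) == {"ACGT" * 5: 2, "TTTT" * 5: 1}

    def test_n_reads_removed(self):
        out = census.collapse_reads(["ACNT" + "A" * 16])
        assert out.audit["retained"] == 0 and out.audit["contains_N"] == 1

    def test_empty_input(self):
        out = census.collapse_reads([])
        assert out.unique_sequences == [] and out.audit["retained"] == 0


class TestScreenLibrary:
    @pytest.fixture()
    def screen(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 120))
        return ReferenceSet(
            [RefEntry("rRNA-1", "rRNA", seq)], class_order=("miRNA",)
        ), seq

    def test_rrna_fragment_archived(self, screen):
        refs, seq = screen
        reads = census.collapse_reads([seq[30:55]])
        survivors, archived = census.screen_library(reads, refs)
        assert archived == 1 and survivors.unique_sequences == []

    def test_two_mismatches_survive(self, screen):
        refs, seq = screen
        frag = list(seq[30:55])
        frag[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[3]]
        frag[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[10]]
        frag = "".join(frag)
        # exhaustive mismatch-count oracle over every placement
        best = min(
            sum(a != b for a, b in zip(frag, seq[s:s + len(frag)]))
            for s in range(len(seq) - len(frag) + 1)
        )
        assert best == 2
        reads = census.collapse_reads([frag])
        survivors, archived = census.screen_library(reads, refs)
        assert archived == 0 and len(survivors.unique_sequences) == 1

    def test_empty_screen_passes_everything(self):
        refs = ReferenceSet([], class_order=("miRNA",))
        reads = census.collapse_reads(["ACGT" * 6])
        survivors, archived = census.screen_library(reads, refs)
        assert archived == 0 and len(survivors.unique_sequences) == 1


def _mutate_base(s, i):
    return s[:i] + {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]] + s[i + 1:]


class TestAssignHierarchical:
    def test_identical_references_split_proportionally(self):
        seq = "ACGTACGTACGTACGTACGTACGTAC"
        refs = ReferenceSet(
            [RefEntry("piR-a", "piRNA", seq), RefEntry("piR-b", "piRNA", seq)],
            class_order=("piRNA",),
        )
        reads = census.ClippedReadSet([(seq, 10)], {})
        out = census.assign_hierarchical(reads, refs)
        assert out.counts == {"piR-a": 5.0, "piR-b": 5.0}

    def test_exact_hit_beats_one_mismatch(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), 24))
        b = _mutate_base(a, 5)
        refs = ReferenceSet(
            [RefEntry("A", "miRNA", a), RefEntry("B", "miRNA", b)],
            class_order=("miRNA",),
        )
        out = census.assign_hierarchical(
            census.ClippedReadSet([(a, 3)], {}), refs
        )
        assert out.counts == {"A": 3.0}

    def test_earlier_class_wins(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        refs = ReferenceSet(
            [RefEntry("m1", "miRNA", seq), RefEntry("p1", "piRNA", seq)],
            class_order=("miRNA", "piRNA"),
        )
        out = census.assign_hierarchical(
            census.ClippedReadSet([(seq, 4)], {}), refs
        )
        assert out.counts == {"m1": 4.0}
        assert out.audit["mapped_piRNA"] == 0

    def test_missing_class_in_order_rejected(self):
        refs = ReferenceSet(
            [RefEntry("m1", "miRNA", "ACGT" * 6)],
            class_order=("miRNA", "piRNA"),
        )
        with pytest.raises(ValueError, match="piRNA"):
            census.assign_hierarchical(
                census.ClippedReadSet([("ACGT" * 6, 1)], {}), refs
            )

    def test_overhang_allows_3p_nontemplate_additions(self):
        rng = np.random.default_rng(9)
        ref = "".join(rng.choice(list("ACGT"), 26))
        refs = ReferenceSet(
            [RefEntry("p1", "piRNA", ref)], class_order=("piRNA",)
        )
        read = ref + "C" if ref[-1] != "C" else ref + "G"
        out = census.assign_hierarchical(
            census.ClippedReadSet([(read, 1)], {}), refs
        )
        assert out.counts == {"p1": 1.0}

    @pytest.mark.parametrize("inst_seed", range(12))
    def test_agrees_with_exhaustive_oracle(self, inst_seed):
        rng = np.random.default_rng(100 + inst_seed)
        refs = sim.make_reference_set(
            seed=int(rng.integers(1 << 30)),
            class_sizes={"miRNA": 6, "piRNA": 4, "snoRNA": 3},
            n_multimap_pairs=1,
        )
        seqs = [e.sequence for e in refs.entries]
        reads = []
        for _ in range(40):
            s = seqs[int(rng.integers(len(seqs)))]
            if rng.random() < 0.4:
                s = _mutate_base(s, int(rng.integers(len(s))))
            if rng.random() < 0.3:
                s = s + "".join(rng.choice(list("ACGT"),
                                           int(rng.integers(1, 4))))
            reads.append(s)
        creads = census.collapse_reads(reads)
        out = census.assign_hierarchical(creads, refs)
        oc_counts, oc_unmapped = oracle_assign(creads.unique_sequences, refs)
        assert out.audit["unmapped"] == oc_unmapped
        assert set(out.counts) == set(oc_counts)
        for sp in oc_counts:
            assert out.counts[sp] == pytest.approx(oc_counts[sp], abs=1e-12)


class TestQuantification:
    def test_rpm_arithmetic(self):
        counts = pd.DataFrame({"A": [4.0], "B": [6.0]}, index=["s1"])
        rpm = census.counts_to_rpm(counts)
        assert rpm.loc["s1", "A"] == pytest.approx(400_000)
        assert rpm.loc["s1", "B"] == pytest.approx(600_000)

    def test_single_species_rpm(self):
        rpm = census.counts_to_rpm(pd.DataFrame({"A": [3.0]}, index=["s"]))
        assert rpm.loc["s", "A"] == pytest.approx(1_000_000)

    def test_rpm_rows_sum_to_a_million(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.uniform(0, 50, size=(6, 9)))
        rpm = census.counts_to_rpm(counts)
        assert np.allclose(rpm.sum(axis=1), 1e6, rtol=1e-6)

    def test_zero_sample_flagged_missing(self):
        counts = pd.DataFrame({"A": [0.0, 2.0]}, index=["s1", "s2"])
        rpm = census.counts_to_rpm(counts)
        assert rpm.loc["s1"].isna().all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            census.counts_to_rpm(pd.DataFrame({"A": [-1.0]}))


class TestDetection:
    def test_mean_rpm_threshold(self):
        rpm = pd.DataFrame({"A": [1500.0, 600.0], "B": [0.0, 0.0]})
        out = census.detect_by_mean_rpm(rpm, {"A": "miRNA", "B": "miRNA"})
        assert out.detected == {"A"}
        assert out.per_class == {"miRNA": 1}

    def test_detected_set_shrinks_with_threshold(self):
        rng = np.random.default_rng(3)
        rpm = pd.DataFrame(rng.uniform(0, 3000, size=(5, 30)))
        sizes = [
            len(census.detect_by_mean_rpm(rpm, {}, t).detected)
            for t in np.linspace(500, 2000, 7)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestReplication:
    @staticmethod
    def _fixture(n_a, n_overlap, cls, seed=0):
        """Two cohorts whose detected sets realise |A| and |A n B|."""
        rng = np.random.default_rng(seed)
        species = [f"{cls}-{i}" for i in range(n_a)]
        classes = {s: cls for s in species}
        a_vals = rng.uniform(2000, 50000, n_a)
        b_vals = np.where(
            np.arange(n_a) < n_overlap,
            a_vals * rng.uniform(0.5, 2.0, n_a),
            rng.uniform(1, 500, n_a),
        )
        rpm_a = pd.DataFrame([a_vals], columns=species)
        rpm_b = pd.DataFrame([b_vals], columns=species)
        return rpm_a, set(species), rpm_b, classes

    @pytest.mark.parametrize(
        "n_a,n_ov,pct",
        [(144, 22, 15), (74, 56, 76)],
        ids=["piRNA-overlap", "snoRNA-overlap"],
    )
    def test_printed_overlap_percentages(self, n_a, n_ov, pct):
        rpm_a, det_a, rpm_b, classes = self._fixture(n_a, n_ov, "x")
        report = census.replication_overlap(rpm_a, det_a, rpm_b, classes)
        row = report.per_class.loc["x"]
        assert row["n_a"] == n_a and row["n_overlap"] == n_ov
        assert round(row["overlap_percent"]) == pct

    def test_identical_cohorts(self):
        rng = np.random.default_rng(1)
        rpm = pd.DataFrame(
            rng.uniform(1500, 9000, size=(3, 12)),
            columns=[f"s{i}" for i in range(12)],
        )
        classes = {c: "miRNA" for c in rpm.columns}
        det = census.detect_by_mean_rpm(rpm, classes).detected
        report = census.replication_overlap(rpm, det, rpm.copy(), classes)
        row = report.per_class.loc["miRNA"]
        assert row["overlap_percent"] == 100.0
        assert row["rho"] == pytest.approx(1.0)

    def test_small_overlap_rho_undefined(self):
        rpm_a, det_a, rpm_b, classes = self._fixture(10, 2, "x")
        report = census.replication_overlap(rpm_a, det_a, rpm_b, classes)
        assert np.isnan(report.per_class.loc["x", "rho"])

    def test_rho_invariant_under_monotone_transform(self):
        rpm_a, det_a, rpm_b, classes = self._fixture(20, 12, "x", seed=5)
        r1 = census.replication_overlap(rpm_a, det_a, rpm_b, classes)
        # cubing RPM is strictly monotone (single-sample cohorts, so the
        # mean commutes); ranks, the detected sets and rho are unchanged
        r2 = census.replication_overlap(
            rpm_a ** 3, det_a, rpm_b ** 3, classes, threshold=1000.0 ** 3
        )
        assert r1.per_class.loc["x", "rho"] == pytest.approx(
            r2.per_class.loc["x", "rho"]
        )

    def test_exact_permutation_p_for_perfect_rank(self):
        rpm_a, det_a, rpm_b, classes = self._fixture(5, 5, "x", seed=2)
        rpm_b = rpm_a * 2.0  # perfect rank agreement, n = 5
        report = census.replication_overlap(rpm_a, det_a, rpm_b, classes)
        row = report.per_class.loc["x"]
        assert row["rho"] == pytest.approx(1.0)
        # only the two perfect permutations of 5! reach |rho| = 1
        assert row["p"] == pytest.approx(2 / 120)


class TestCascadeProperties:
    def test_zero_noise_truth_recovery(self, small_refset, uniform_profile):
        reads = sim.simulate_reads(
            small_refset, 1500, uniform_profile, sub_rate=0.0, n_rate=0.0,
            seed=13
        )
        result = census.run_census(reads.reads, small_refset, reads.adapter)
        truth = reads.truth_counts()
        # the seeded multimap pair shares one sequence: counts split evenly,
        # so compare the pair by their sum and everything else exactly
        pair = [
            e.species_id
            for e in small_refset.entries
            if sum(
                x.sequence == e.sequence for x in small_refset.entries
            ) > 1
        ]
        for sp, n in truth.items():
            if sp in pair:
                continue
            assert result.counts.get(sp, 0.0) == pytest.approx(float(n))
        if pair:
            assert sum(result.counts.get(s, 0.0) for s in pair) == (
                pytest.approx(sum(truth.get(s, 0) for s in pair))
            )

    def test_mass_conservation_with_errors(self, small_refset,
                                           uniform_profile):
        reads = sim.simulate_reads(
            small_refset, 3000, uniform_profile, sub_rate=0.01, n_rate=0.003,
            contaminant_frac=0.15, seed=21
        )
        result = census.run_census(reads.reads, small_refset, reads.adapter)
        a = result.audit
        recovered = (
            a["no_adapter"] + a["too_short"] + a["contains_N"]
            + a["screened_contaminant"] + a["screened_rRNA"]
            + result.total_assigned + a["unmapped"]
        )
        assert recovered == pytest.approx(a["input"], abs=1e-9)
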