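import numpy as np
import pandas as pd
import pytest

from conftest import map_dataset, small_config
from pirnakit.align import Alignment, MappedReadSet
from pirnakit.clusters import (
    ClusterCandidate,
    ClusterExpressionMatrix,
    PiRNACluster,
    classify_expression,
    merge_clusters,
    predict_clusters,
    quantify_clusters,
)
from pirnakit.reads import CollapsedRead
from pirnakit.synthetic import simulate_dataset


def _cand(chrom, start, end, dataset="d1"):
    return ClusterCandidate(chrom, start, end, 10.0, 10, 0.9, 0.9, False, dataset)


class TestMerge:
    def test_gap_below_threshold_merges(self):
        merged = merge_clusters([[_cand("c", 1000, 2000), _cand("c", 11499, 12000)]])
        assert [(c.start, c.end) for c in merged] == [(1000, 12000)]

    def test_gap_exactly_10kb_not_merged(self):
        merged = merge_clusters([[_cand("c", 1000, 2000), _cand("c", 12000, 13000)]])
        assert len(merged) == 2

    def test_transitive_merge_across_datasets(self):
        merged = merge_clusters(
            [
                [_cand("c", 0, 1000, "a"), _cand("c", 20_000, 21_000, "a")],
                [_cand("c", 9000, 12_000, "b")],
            ]
        )
        assert [(c.start, c.end) for c in merged] == [(0, 21_000)]
        assert merged[0].source_datasets == {"a", "b"}

    def test_idempotent_and_order_independent(self):
        sets = [
            [_cand("c", 0, 500, "a"), _cand("c", 30_000, 31_000, "a")],
            [_cand("c", 5000, 6000, "b")],
            [_cand("d", 100, 900, "c")],
        ]
        once = merge_clusters(sets)
        again = merge_clusters(
            [[_cand(c.chrom, c.start, c.end) for c in once]]
        )
        assert [(c.chrom, c.start, c.end) for c in once] == [
            (c.chrom, c.start, c.end) for c in again
        ]
        rev = merge_clusters(list(reversed(sets)))
        assert [(c.chrom, c.start, c.end) for c in once] == [
            (c.chrom, c.start, c.end) for c in rev
        ]


class TestPredict:
    def test_planted_cluster_recovered(self):
        ds = simulate_dataset(small_config(seed=41, n_reads=20_000))
        mapped = map_dataset(ds)
        inter = mapped.subset(
            {
                s
                for s, l in ds.truth.read_labels.items()
                if l in ("primary", "secondary")
            }
        )
        cands = predict_clusters(inter, total_mapped_count=mapped.total_count)
        truth = [(c, s, e) for c, s, e, _ in ds.truth.clusters]
        # every truth cluster hit by exactly one candidate within 200 bp
        recovered = 0
        for chrom, s, e in truth:
            hits = [
                c
                for c in cands
                if c.chrom == chrom and c.start < e and s < c.end
            ]
            if hits and abs(hits[0].start - s) <= 200 and abs(hits[0].end - e) <= 200:
                recovered += 1
        assert recovered >= 0.9 * len(truth)
        # no candidate outside any truth cluster
        for c in cands:
            assert any(
                c.chrom == chrom and c.start < e + 200 and s - 200 < c.end
                for chrom, s, e in truth
            )

    def test_composition_gate_blocks_unbiased_locus(self):
        # same density but no 1U/10A bias
        rng = np.random.default_rng(7)
        alns = []
        for i in range(300):
            seq = "G" + "".join(rng.choice(list("ACGT"), size=8)) + "C" + "".join(
                rng.choice(list("ACGT"), size=16)
            )
            alns.append(
                Alignment(CollapsedRead(seq, 1), "c", int(rng.integers(0, 4000)),
                          "+", (), 0, 0)
            )
        seen = {}
        uniq = [a for a in alns if seen.setdefault(a.read.sequence, a) is a]
        mapped = MappedReadSet(uniq, [])
        assert predict_clusters(mapped, total_mapped_count=len(uniq)) == []

    def test_overlapping_windows_merge_to_one_candidate(self):
        rng = np.random.default_rng(8)
        alns = []
        for i in range(400):
            seq = "T" + "".join(rng.choice(list("ACGT"), size=25))
            alns.append(
                Alignment(CollapsedRead(seq, 1), "c", int(rng.integers(0, 6000)),
                          "+", (), 0, 0)
            )
        seen = {}
        uniq = [a for a in alns if seen.setdefault(a.read.sequence, a) is a]
        cands = predict_clusters(
            MappedReadSet(uniq, []), total_mapped_count=len(uniq)
        )
        assert len(cands) == 1

    def test_empty_input(self):
        assert predict_clusters(MappedReadSet([], [])) == []


class TestQuantify:
    def _mapped(self, entries, n_filler=0):
        alns = []
        for i, (chrom, start, strand, count) in enumerate(entries):
            seq = "T" + format(i, "024b").replace("0", "A").replace("1", "C")
            alns.append(
                Alignment(CollapsedRead(seq, count), chrom, start, strand, (), 0, 0)
            )
        for i in range(n_filler):
            seq = "G" + format(i, "024b").replace("0", "G").replace("1", "T")
            alns.append(
                Alignment(CollapsedRead(seq, 1), "far", 10_000 + i, "+", (), 0, 0)
            )
        return MappedReadSet(alns, [])

    def test_rpm_arithmetic(self):
        clusters = [PiRNACluster("c", 0, 1000)]
        mapped = self._mapped([("c", 10, "+", 50)], n_filler=950)
        mat = quantify_clusters(clusters, {"d": mapped})
        assert mat.rpm.loc["c:0-1000", "d"] == pytest.approx(50 * 1e6 / 1000)

    def test_multimapper_apportioned(self):
        clusters = [PiRNACluster("c", 0, 1000)]
        alns = [
            Alignment(CollapsedRead("T" * 25, 4), "c", 10, "+", (), 0, 0),
            Alignment(CollapsedRead("T" * 25, 4), "far", 5000, "+", (), 0, 0),
        ]
        mapped = MappedReadSet(alns, [])
        mat = quantify_clusters(clusters, {"d": mapped})
        # half the count lands in the cluster
        assert mat.rpm.loc["c:0-1000", "d"] == pytest.approx(2 * 1e6 / 4)

    def test_cluster_counts_bounded_by_total(self):
        clusters = [PiRNACluster("c", 0, 500), PiRNACluster("c", 2000, 2500)]
        mapped = self._mapped(
            [("c", 10, "+", 5), ("c", 2100, "-", 3), ("c", 9000, "+", 7)]
        )
        mat = quantify_clusters(clusters, {"d": mapped})
        assert sum(mat.clustered_fraction.values()) <= 1.0

    def test_zero_read_dataset_rejected(self):
        with pytest.raises(ValueError):
            quantify_clusters([PiRNACluster("c", 0, 10)], {"d": MappedReadSet([], [])})


class TestClassify:
    def _matrix(self, rows, datasets):
        clusters = [PiRNACluster("c", i * 30_000, i * 30_000 + 1000)
                    for i in range(len(rows))]
        df = pd.DataFrame(rows, index=[c.name for c in clusters], columns=datasets)
        for c, (_, row) in zip(clusters, df.iterrows()):
            c.rpm = row.to_dict()
        return ClusterExpressionMatrix(df, clusters)

    def test_identical_profiles_same_class(self):
        rows = [[100, 1, 1], [200, 2, 2], [1, 100, 1], [1, 1, 100]]
        mat = classify_expression(self._matrix(rows, list("abc")), k=3, top_n=4)
        assert mat.classes.iloc[0] == mat.classes.iloc[1]

    def test_four_class_design_recovery(self):
        rng = np.random.default_rng(17)
        rows, want = [], []
        for cls in range(4):
            for _ in range(25):
                base = rng.uniform(0.0, 0.1, size=8)
                base[cls * 2 : cls * 2 + 2] += rng.uniform(5, 10)
                rows.append(base * rng.uniform(1, 100))
                want.append(cls)
        m = self._matrix(rows, [f"d{i}" for i in range(8)])
        names = list(m.rpm.index)
        mat = classify_expression(m, k=4, top_n=100)
        got = mat.classes.loc[names].to_numpy()
        # label-permutation-tolerant agreement
        agree = 0
        for cls in range(4):
            members = got[np.array(want) == cls]
            agree += np.max(np.bincount(members)[1:])
        assert agree >= 95

    def test_k_equals_one(self):
        rows = [[1, 2], [2, 1], [5, 5], [1, 9]]
        mat = classify_expression(self._matrix(rows, ["a", "b"]), k=1, top_n=4)
        assert set(mat.classes) == {1}

    def test_constant_row_flagged(self):
        rows = [[5, 5, 5], [1, 10, 1], [10, 1, 1], [1, 1, 10]]
        mat = classify_expression(self._matrix(rows, list("abc")), k=2, top_n=4)
        assert mat.flagged_rows == ["c:0-1000"]
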