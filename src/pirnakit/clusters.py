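"""piRNA cluster prediction, merging, quantification and classification.

Primary piRNAs are processed from long single-stranded precursor
transcripts, so they map in dense, strand-biased, 1U/10A-enriched
genomic intervals ("piRNA clusters").  Prediction here is a
deterministic sliding-window gate over the unannotated (intergenic)
read fraction: a window qualifies on normalized 5'-end read density,
distinct-sequence support, 1U-or-10A composition and strand coherence
(mono-directional, or bi-directional with a single switch point);
qualifying windows are merged and trimmed to the outermost read
termini.

Clusters predicted independently from several libraries are condensed by
transitively merging intervals closer than 10 kb, quantified as rpm
(reads per million mapped) per library, and classified by hierarchical
clustering (Pearson distance, average linkage) of their expression
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from pirnakit.align import MappedReadSet

DEFAULT_LENGTH_RANGE = (24, 32)


@dataclass
class ClusterCandidate:
    """A qualifying piRNA-producing interval from one library."""

    chrom: str
    start: int
    end: int
    n_reads: float
    n_distinct: int
    frac_1U_or_10A: float
    frac_main_strand: float
    bidirectional: bool
    dataset: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PiRNACluster:
    """A merged piRNA cluster with per-library expression."""

    chrom: str
    start: int
    end: int
    source_datasets: set = field(default_factory=set)
    rpm: dict = field(default_factory=dict)
    expression_class: int | None = None
    repeat_content: float | None = None
    gene_content: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def max_rpm(self) -> float:
        return max(self.rpm.values()) if self.rpm else 0.0

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ClusterExpressionMatrix:
    """Cluster x library rpm matrix with optional linkage and classes."""

    rpm: pd.DataFrame  # rows: cluster names, columns: dataset labels
    clusters: list[PiRNACluster]
    clustered_fraction: dict[str, float] = field(default_factory=dict)
    linkage: np.ndarray | None = None
    classes: pd.Series | None = None
    flagged_rows: list[str] = field(default_factory=list)


def _read_features(seq: str) -> tuple[bool, bool]:
    return seq[0] == "T", len(seq) >= 10 and seq[9] == "A"


class _ChromEnds:
    """Sorted 5'-end arrays for one chromosome."""

    def __init__(self, alns, weights, seq_ids):
        order = np.argsort([a.five_prime for a in alns], kind="stable")
        self.alns = [alns[i] for i in order]
        self.pos = np.array([a.five_prime for a in self.alns], dtype=np.int64)
        self.w = weights[order]
        self.is_plus = np.array([a.strand == "+" for a in self.alns])
        self.seq_id = seq_ids[order]
        feats = [_read_features(a.read.sequence) for a in self.alns]
        self.good = np.array([u or a for u, a in feats])
        self.is_1u = np.array([u for u, _ in feats])
        # prefix sums for O(1) window statistics
        self.cw = np.concatenate(([0.0], np.cumsum(self.w)))
        self.cw_plus = np.concatenate(([0.0], np.cumsum(self.w * self.is_plus)))
        self.cw_good = np.concatenate(([0.0], np.cumsum(self.w * self.good)))
        # strand coherence is judged on 5'U reads (putative primaries):
        # ping-pong responders map antisense within a cluster and would
        # otherwise vote against the precursor orientation
        w1u = self.w * self.is_1u
        self.cw_1u = np.concatenate(([0.0], np.cumsum(w1u)))
        self.cw_plus_1u = np.concatenate(([0.0], np.cumsum(w1u * self.is_plus)))

    def strand_fraction(self, i: int, j: int) -> float:
        """Main-strand weight fraction over 5'U reads in ends i..j."""
        denom = self.cw_1u[j] - self.cw_1u[i]
        if denom > 0:
            pfrac = (self.cw_plus_1u[j] - self.cw_plus_1u[i]) / denom
        else:
            pfrac = (self.cw_plus[j] - self.cw_plus[i]) / (self.cw[j] - self.cw[i])
        return max(pfrac, 1.0 - pfrac)

    def window(self, lo: int, hi: int) -> tuple[int, int]:
        return (
            int(np.searchsorted(self.pos, lo, side="left")),
            int(np.searchsorted(self.pos, hi, side="left")),
        )


def _bidirectional_split(ce: _ChromEnds, i: int, j: int, min_frac: float) -> bool:
    """True iff ends i..j split at one point into strand-homogeneous halves.

    Judged on 5'U reads like the mono-directional gate (all reads if no
    5'U read is present).
    """
    sel = ce.is_1u[i:j]
    if not sel.any():
        sel = np.ones(j - i, dtype=bool)
    w = ce.w[i:j][sel]
    plus = ce.is_plus[i:j][sel]
    if len(w) < 2:
        return False
    cp = np.concatenate(([0.0], np.cumsum(w * plus)))
    ct = np.concatenate(([0.0], np.cumsum(w)))
    total_p, total = cp[-1], ct[-1]
    for s in range(1, len(w)):
        lt, lp = ct[s], cp[s]
        rt, rp = total - lt, total_p - lp
        if lt == 0 or rt == 0:
            continue
        lf, rf = lp / lt, rp / rt
        if (lf >= min_frac and (1 - rf) >= min_frac) or (
            (1 - lf) >= min_frac and rf >= min_frac
        ):
            return True
    return False


def predict_clusters(
    mapped: MappedReadSet,
    total_mapped_count: float | None = None,
    window: int = 5000,
    step: int = 1000,
    min_density_rpm_kb: float = 5.0,
    min_distinct: int = 10,
    min_1U_10A_frac: float = 0.75,
    min_strand_frac: float = 0.75,
    min_span: int = 1000,
    max_internal_gap: int = 1000,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    dataset: str = "",
) -> list[ClusterCandidate]:
    """Sliding-window prediction of piRNA-producing intervals.

    ``mapped`` should hold the unannotated (intergenic) read fraction;
    reads outside ``length_range`` are ignored.  ``total_mapped_count``
    is the library size used for rpm normalization (defaults to the
    total copies in ``mapped``).  A window of ``window`` bp advanced by
    ``step`` qualifies when

    * apportioned 5'-end density >= ``min_density_rpm_kb`` rpm per kb,
    * distinct sequences >= ``min_distinct``,
    * count-weighted fraction of reads with 5'U or 10A >= ``min_1U_10A_frac``,
    * main-strand fraction >= ``min_strand_frac`` computed over 5'U
      reads (putative primaries; antisense ping-pong responders do not
      vote against the precursor orientation), or the window splits at
      one point into two strand-homogeneous halves (bidirectional).

    Overlapping qualifying windows are merged and each merged interval
    is trimmed to the outermost termini of the reads whose 5' ends fall
    inside it.  Two structural gates then apply.  Candidates are split
    at internal stretches of more than ``max_internal_gap`` bp without
    read coverage (read-distribution gate: cluster transcripts produce
    reads tiling the whole locus, whereas transposon copies attract
    isolated piles of multimapping piRNAs separated by empty sequence),
    and resulting blocks shorter than ``min_span`` bp — such as those
    isolated transposon-copy piles — are dropped (minimum cluster
    extent).
    """
    lo_len, hi_len = length_range
    alns = [a for a in mapped.alignments if lo_len <= a.length <= hi_len]
    if not alns:
        return []
    if total_mapped_count is None:
        total_mapped_count = mapped.total_count
    seq_index: dict[str, int] = {}
    weights = np.array([mapped.weight(a) for a in alns])
    seq_ids = np.array(
        [seq_index.setdefault(a.read.sequence, len(seq_index)) for a in alns]
    )
    per_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(alns):
        per_chrom.setdefault(a.chrom, []).append(i)

    out: list[ClusterCandidate] = []
    for chrom, idxs in per_chrom.items():
        ce = _ChromEnds([alns[i] for i in idxs], weights[idxs], seq_ids[idxs])
        max_pos = int(ce.pos[-1])
        qual: list[tuple[int, int]] = []
        for w0 in range(0, max_pos + 1, step):
            i, j = ce.window(w0, w0 + window)
            if j - i == 0:
                continue
            wsum = ce.cw[j] - ce.cw[i]
            density = wsum * 1e6 / total_mapped_count / (window / 1000.0)
            if density < min_density_rpm_kb:
                continue
            if len(set(ce.seq_id[i:j].tolist())) < min_distinct:
                continue
            if (ce.cw_good[j] - ce.cw_good[i]) / wsum < min_1U_10A_frac:
                continue
            if ce.strand_fraction(i, j) < min_strand_frac and not _bidirectional_split(
                ce, i, j, min_strand_frac
            ):
                continue
            qual.append((w0, w0 + window))
        # merge overlapping qualifying windows, split each merged
        # interval at uncovered internal gaps, then trim blocks to read
        # termini
        for ws, we in _union(qual):
            i0, j0 = ce.window(ws, we)
            footprints = _union(
                (a.start, a.end + max_internal_gap) for a in ce.alns[i0:j0]
            )
            for bs, be_pad in footprints:
                be = be_pad - max_internal_gap
                i, j = ce.window(bs, be)
                sub = [a for a in ce.alns[i:j] if bs <= a.start and a.end <= be]
                if not sub:
                    continue
                start = min(a.start for a in sub)
                end = max(a.end for a in sub)
                if end - start < min_span:
                    continue
                wsum = ce.cw[j] - ce.cw[i]
                main = ce.strand_fraction(i, j)
                out.append(
                    ClusterCandidate(
                        chrom=chrom,
                        start=start,
                        end=end,
                        n_reads=float(wsum),
                        n_distinct=len(set(ce.seq_id[i:j].tolist())),
                        frac_1U_or_10A=float(
                            (ce.cw_good[j] - ce.cw_good[i]) / wsum
                        ),
                        frac_main_strand=float(main),
                        bidirectional=main < min_strand_frac,
                        dataset=dataset,
                    )
                )
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def _union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly-overlapping intervals (touching intervals merge)."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merge_clusters(
    candidate_sets: Iterable[Sequence[ClusterCandidate]],
    max_gap: int = 10_000,
) -> list[PiRNACluster]:
    """Condense per-library candidates into distinct piRNA clusters.

    Any two intervals on the same chromosome that overlap or whose gap
    is strictly less than ``max_gap`` are transitively merged; the
    merged interval spans the extrema and records the union of source
    library labels.  Merging is idempotent and independent of the order
    of the candidate sets.
    """
    by_chrom: dict[str, list[ClusterCandidate]] = {}
    for cands in candidate_sets:
        for c in cands:
            by_chrom.setdefault(c.chrom, []).append(c)
    out: list[PiRNACluster] = []
    for chrom in sorted(by_chrom):
        cands = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur: PiRNACluster | None = None
        for c in cands:
            if cur is not None and c.start - cur.end < max_gap:
                cur.end = max(cur.end, c.end)
                cur.source_datasets.add(c.dataset)
            else:
                if cur is not None:
                    out.append(cur)
                cur = PiRNACluster(chrom, c.start, c.end, {c.dataset})
        if cur is not None:
            out.append(cur)
    return out


def quantify_clusters(
    clusters: list[PiRNACluster],
    mapped_per_dataset: Mapping[str, MappedReadSet],
) -> ClusterExpressionMatrix:
    """Per-library rpm coverage of merged clusters.

    rpm(cluster, library) = apportioned count of alignments whose 5' end
    lies in the cluster, times 1e6, divided by the library's total
    mapped apportioned count.  Also reports the clustered-read fraction
    per library (sum over clusters / total).
    """
    if not mapped_per_dataset:
        raise ValueError("no datasets")
    bounds: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for ci, c in enumerate(clusters):
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end, ci))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("cluster intervals must be disjoint; merge first")
        bounds[chrom] = (starts, ends, [i for _, _, i in ivs])

    data = {}
    clustered_fraction = {}
    for label, mapped in mapped_per_dataset.items():
        total = mapped.total_count
        if total == 0:
            raise ValueError(f"dataset {label!r} has zero mapped reads")
        counts = np.zeros(len(clusters))
        for a in mapped.alignments:
            if a.chrom not in bounds:
                continue
            starts, ends, order = bounds[a.chrom]
            k = int(np.searchsorted(starts, a.five_prime, side="right")) - 1
            if k >= 0 and a.five_prime < ends[k]:
                counts[order[k]] += mapped.weight(a)
        data[label] = counts * 1e6 / total
        clustered_fraction[label] = float(counts.sum() / total)
    for ci, c in enumerate(clusters):
        c.rpm = {label: float(data[label][ci]) for label in data}
    df = pd.DataFrame(data, index=[c.name for c in clusters])
    return ClusterExpressionMatrix(df, clusters, clustered_fraction)


def classify_expression(
    matrix: ClusterExpressionMatrix, k: int = 4, top_n: int = 100
) -> ClusterExpressionMatrix:
    """Classify the top clusters by their expression profile shape.

    Rows are the ``top_n`` clusters by maximum rpm, each scaled to
    [0, 1] relative to its own extremes; the distance is 1 - Pearson
    correlation of scaled profiles, clustered by agglomerative average
    linkage and cut into ``k`` classes.  Class labels are renumbered by
    the mean position of peak expression across member clusters.
    Constant rows (Pearson undefined) fall back to Euclidean distance
    and are flagged.
    """
    df = matrix.rpm
    top = df.loc[df.max(axis=1).sort_values(ascending=False).index[:top_n]]
    if len(top) < k:
        raise ValueError(f"need >= k={k} clusters after top-{top_n} selection")
    vals = top.to_numpy(dtype=float)
    rng_row = vals.max(axis=1) - vals.min(axis=1)
    flagged = rng_row == 0
    scaled = np.where(
        flagged[:, None], 0.5, (vals - vals.min(axis=1, keepdims=True)) / np.where(rng_row == 0, 1, rng_row)[:, None]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d_corr = pdist(scaled, metric="correlation")
    if np.any(flagged) or np.any(~np.isfinite(d_corr)):
        d_eucl = pdist(scaled, metric="euclidean")
        span = d_eucl.max() or 1.0
        d_corr = np.where(np.isfinite(d_corr), d_corr, 2.0 * d_eucl / span)
    Z = linkage(d_corr, method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    peaks = scaled.argmax(axis=1)
    order = (
        pd.Series(peaks).groupby(labels).mean().sort_values().index.tolist()
    )
    relabel = {old: new for new, old in enumerate(order, start=1)}
    classes = pd.Series([relabel[l] for l in labels], index=top.index)
    name_to_cluster = {c.name: c for c in matrix.clusters}
    for name, cls in classes.items():
        name_to_cluster[name].expression_class = int(cls)
    matrix.linkage = Z
    matrix.classes = classes
    matrix.flagged_rows = top.index[flagged].tolist()
    return matrix


def validate_clusters(
    clusters: list[PiRNACluster],
    mapped: MappedReadSet,
    annotation_by_sequence: Mapping[str, str],
    reject_classes: tuple[str, ...] = ("rRNA", "tRNA"),
    max_reject_frac: float = 0.5,
) -> tuple[list[PiRNACluster], pd.DataFrame]:
    """Reject clusters dominated by rRNA/tRNA signal.

    For each cluster the count-weighted annotation-class composition of
    the reads mapping into it is computed; clusters where the rejected
    classes exceed ``max_reject_frac`` of the signal are dropped.
    Returns the retained clusters and the full composition table.
    """
    rows = []
    kept = []
    for c in clusters:
        w_total = w_reject = 0.0
        for a in mapped.alignments:
            if a.chrom == c.chrom and c.start <= a.five_prime < c.end:
                w = mapped.weight(a)
                w_total += w
                if annotation_by_sequence.get(a.read.sequence) in reject_classes:
                    w_reject += w
        frac = w_reject / w_total if w_total else 0.0
        rows.append({"cluster": c.name, "reject_frac": frac, "signal": w_total})
        if frac <= max_reject_frac:
            kept.append(c)
    return kept, pd.DataFrame(rows)


def write_bed(clusters: Iterable[PiRNACluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            cls = c.expression_class if c.expression_class is not None else "."
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tpiC_{c.name}\t{cls}\t.\n")


def write_gff3(clusters: Iterable[PiRNACluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(clusters, start=1):
            attrs = f"ID=piC{i};max_rpm={c.max_rpm:.3f}"
            fh.write(
                f"{c.chrom}\tpirnakit\tpiRNA_cluster\t{c.start + 1}\t{c.end}\t"
                f".\t.\t.\t{attrs}\n"
            )
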