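"""Ping-pong signature detection and bootstrap quantification.

Secondary piRNA biogenesis (the ping-pong cycle) leaves a diagnostic
footprint: sense/antisense piRNA pairs whose 5' ends overlap by exactly
10 bp.  This module computes the 5'-overlap score histogram S(o), a
Z-score for the 10 bp bias, bootstrap-normalized ping-pong measures
(pps-mbr, ppr-mbr) that are comparable across libraries of different
depth, the length-combination matrix of ping-pong pairs, and positional
base biases (1U/10A) in information-content bits.

Score definition: with c_+(p) and c_-(p) the apportioned read counts of
5' ends at genomic position p on the plus and minus strand,

    S(o) = sum over chromosomes and positions p of c_+(p) * c_-(p + o - 1)

so o = 10 counts pairs with the canonical 10 bp 5' overlap.  Multimapper
counts are apportioned 1/n across their retained alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from pirnakit.align import MappedReadSet
from pirnakit.reads import CollapsedRead

LENGTH_RANGE = (15, 36)


@dataclass
class OverlapHistogram:
    """5'-overlap score histogram S(o) for overlaps o = 1..max_overlap."""

    S: dict[int, float]

    @property
    def max_overlap(self) -> int:
        return max(self.S)

    def background(self, signal_offset: int = 10) -> list[float]:
        return [v for o, v in sorted(self.S.items()) if o != signal_offset]


@dataclass
class PingPongStats:
    """Bootstrap ping-pong measures aggregated over pseudo-replicates."""

    pps_mbr: float
    pps_sd: float
    ppr_mbr: float
    ppr_sd: float
    z10: float
    p_value: float
    n_replicates: int
    reads_per_replicate: int


@dataclass
class PingPongMatrix:
    """Symmetric length-pair weight matrix of ping-pong pairs."""

    lengths: tuple[int, ...]
    M: np.ndarray

    @property
    def total_weight(self) -> float:
        d = float(np.trace(self.M))
        return (float(self.M.sum()) + d) / 2.0

    @property
    def mode_cell(self) -> tuple[int, int] | None:
        if not np.any(self.M > 0):
            return None
        i, j = np.unravel_index(int(np.argmax(self.M)), self.M.shape)
        l1, l2 = self.lengths[i], self.lengths[j]
        return (min(l1, l2), max(l1, l2))


@dataclass
class PositionBias:
    """Per-position base composition and 1U/10A information heights."""

    frequencies: np.ndarray  # shape (max_len, 4) over A,C,G,T
    bits_1U: float
    bits_10A: float


class _PairIndex:
    """Static 5'-end pairing structure reused across bootstrap replicates.

    Positions are packed into int64 keys (chrom_id * 2^32 + position);
    for every overlap o the matched (plus-end, minus-end) index pairs
    are precomputed once, so each replicate only recomputes weights.
    """

    SHIFT = np.int64(1) << np.int64(32)

    def __init__(self, mapped: MappedReadSet, max_overlap: int = 20):
        self.max_overlap = max_overlap
        reads = mapped.reads
        self.reads = reads
        self.read_counts = np.array([r.count for r in reads], dtype=np.float64)
        seq_to_id = {r.sequence: i for i, r in enumerate(reads)}
        chrom_to_id: dict[str, int] = {}
        aln_key, aln_strand, aln_read, aln_len = [], [], [], []
        for a in mapped.alignments:
            cid = chrom_to_id.setdefault(a.chrom, len(chrom_to_id))
            aln_key.append(cid * int(self.SHIFT) + a.five_prime)
            aln_strand.append(0 if a.strand == "+" else 1)
            aln_read.append(seq_to_id[a.read.sequence])
            aln_len.append(a.length)
        self.aln_key = np.array(aln_key, dtype=np.int64)
        self.aln_strand = np.array(aln_strand, dtype=np.int8)
        self.aln_read = np.array(aln_read, dtype=np.int64)
        self.aln_len = np.array(aln_len, dtype=np.int64)
        self.n_align = np.zeros(len(reads), dtype=np.float64)
        np.add.at(self.n_align, self.aln_read, 1.0)

        self._ends = {}
        for s in (0, 1):
            mask = self.aln_strand == s
            keys = self.aln_key[mask]
            uk, inv = np.unique(keys, return_inverse=True)
            self._ends[s] = {
                "mask": mask,
                "uk": uk,
                "inv": inv,
                "aln_read": self.aln_read[mask],
                "aln_len": self.aln_len[mask],
            }
        # matched unique-end index pairs per overlap
        self.pairs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        up, um = self._ends[0]["uk"], self._ends[1]["uk"]
        for o in range(1, max_overlap + 1):
            _, ip, im = np.intersect1d(
                up, um - np.int64(o - 1), return_indices=True
            )
            self.pairs[o] = (ip, im)

    def end_weights(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Summed apportioned 5'-end weights per unique end, both strands."""
        w_aln = counts[self.aln_read] / self.n_align[self.aln_read]
        out = []
        for s in (0, 1):
            e = self._ends[s]
            out.append(
                np.bincount(e["inv"], weights=w_aln[e["mask"]], minlength=len(e["uk"]))
            )
        return out[0], out[1]

    def histogram(self, counts: np.ndarray) -> OverlapHistogram:
        wp, wm = self.end_weights(counts)
        S = {}
        for o, (ip, im) in self.pairs.items():
            S[o] = float(np.dot(wp[ip], wm[im]))
        return OverlapHistogram(S)

    def participating_reads(self, counts: np.ndarray) -> np.ndarray:
        """Boolean mask over reads with >=1 alignment in a 10 bp-overlap pair."""
        wp, wm = self.end_weights(counts)
        ip, im = self.pairs[10]
        live = (wp[ip] > 0) & (wm[im] > 0)
        mask = np.zeros(len(self.reads), dtype=bool)
        for s, idx in ((0, ip[live]), (1, im[live])):
            e = self._ends[s]
            hit = np.isin(e["inv"], idx)
            mask[e["aln_read"][hit]] = True
        return mask & (counts > 0)


def overlap_histogram(
    mapped: MappedReadSet, max_overlap: int = 20
) -> OverlapHistogram:
    """Compute S(o) for o = 1..max_overlap over all chromosomes."""
    if not mapped.alignments:
        return OverlapHistogram({o: 0.0 for o in range(1, max_overlap + 1)})
    idx = _PairIndex(mapped, max_overlap)
    return idx.histogram(idx.read_counts)


def zscore_pvalue(
    hist: OverlapHistogram, signal_offset: int = 10
) -> tuple[float, float]:
    """Z-score of S(10) against the background offsets, and its normal tail.

    Background is every other offset in the histogram (1..9 and 11..20 by
    default); the sample standard deviation (n-1) is used.  A degenerate
    background (zero variance) yields ``(nan, nan)``.
    """
    bg = np.array(hist.background(signal_offset), dtype=float)
    sd = float(bg.std(ddof=1))
    if sd == 0.0 or len(bg) < 3:
        return (math.nan, math.nan)
    z = (hist.S[signal_offset] - float(bg.mean())) / sd
    return (z, float(norm.sf(z)))


def bootstrap_pingpong(
    mapped: MappedReadSet,
    n_replicates: int = 100,
    reads_per_replicate: int = 1_000_000,
    seed: int | None = None,
    aggregate: str = "mean",
) -> PingPongStats:
    """Bootstrap ping-pong quantification over pseudo-replicates.

    Each pseudo-replicate draws ``reads_per_replicate`` reads with
    replacement from the count-weighted read distribution (whole reads
    with all their retained alignments, preserving multimapping
    structure).  Per replicate:

    * pps = S(10) of the replicate, scaled by (1e6 / R)^2 so that the
      expected pair-count scale matches replicates of one million reads;
    * ppr = total drawn count of reads participating in at least one
      10 bp-overlap pair (each read counted once), scaled by 1e6 / R.

    With the default R = 1e6 both scalings are the identity.  Mean and
    standard deviation over the replicates are reported (median if
    ``aggregate="median"``); the Z-score/p-value reported alongside are
    computed on the original (un-bootstrapped) data.
    """
    if reads_per_replicate < 1:
        raise ValueError("reads_per_replicate must be >= 1")
    if mapped.total_count < 1:
        raise ValueError("no mapped reads to bootstrap from")
    idx = _PairIndex(mapped)
    probs = idx.read_counts / idx.read_counts.sum()
    rng = np.random.default_rng(seed)
    lin = 1e6 / reads_per_replicate
    pps_list, ppr_list = [], []
    for _ in range(n_replicates):
        cnt = rng.multinomial(reads_per_replicate, probs).astype(np.float64)
        hist = idx.histogram(cnt)
        pps_list.append(hist.S[10] * lin * lin)
        mask = idx.participating_reads(cnt)
        ppr_list.append(float(cnt[mask].sum()) * lin)
    pps = np.array(pps_list)
    ppr = np.array(ppr_list)
    agg = np.median if aggregate == "median" else np.mean
    z10, p = zscore_pvalue(idx.histogram(idx.read_counts))
    return PingPongStats(
        pps_mbr=float(agg(pps)),
        pps_sd=float(pps.std(ddof=1)) if n_replicates > 1 else 0.0,
        ppr_mbr=float(agg(ppr)),
        ppr_sd=float(ppr.std(ddof=1)) if n_replicates > 1 else 0.0,
        z10=z10,
        p_value=p,
        n_replicates=n_replicates,
        reads_per_replicate=reads_per_replicate,
    )


def pingpong_matrix(
    mapped: MappedReadSet, length_range: tuple[int, int] = LENGTH_RANGE
) -> PingPongMatrix:
    """Length-combination matrix of 10 bp 5'-overlap pairs.

    For every opposite-strand end pair in ping-pong register and every
    read pair spanning it, the product of apportioned weights is added
    to the unordered cell {len_plus, len_minus}.
    """
    lo, hi = length_range
    lengths = tuple(range(lo, hi + 1))
    M = np.zeros((len(lengths), len(lengths)))
    if not mapped.alignments:
        return PingPongMatrix(lengths, M)
    idx = _PairIndex(mapped)
    counts = idx.read_counts
    w_aln = counts[idx.aln_read] / idx.n_align[idx.aln_read]
    # per unique end: weight summed by read length
    per_end: dict[int, list[dict[int, float]]] = {}
    for s in (0, 1):
        e = idx._ends[s]
        comp: list[dict[int, float]] = [dict() for _ in range(len(e["uk"]))]
        ww = w_aln[e["mask"]]
        for i, (end_i, ln) in enumerate(zip(e["inv"], e["aln_len"])):
            comp[end_i][int(ln)] = comp[end_i].get(int(ln), 0.0) + float(ww[i])
        per_end[s] = comp
    ip, im = idx.pairs[10]
    off = lo
    for i, j in zip(ip, im):
        for l1, w1 in per_end[0][i].items():
            for l2, w2 in per_end[1][j].items():
                if lo <= l1 <= hi and lo <= l2 <= hi:
                    M[l1 - off, l2 - off] += w1 * w2
                    if l1 != l2:
                        M[l2 - off, l1 - off] += w1 * w2
    return PingPongMatrix(lengths, M)


def pingpong_pair_reads(mapped: MappedReadSet) -> list[tuple[CollapsedRead, float]]:
    """Reads participating in 10 bp-overlap pairs, with apportioned weights."""
    if not mapped.alignments:
        return []
    idx = _PairIndex(mapped)
    mask = idx.participating_reads(idx.read_counts)
    return [(idx.reads[i], float(idx.read_counts[i])) for i in np.nonzero(mask)[0]]


_BASE_TO_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def base_bias_bits(
    reads: Iterable[CollapsedRead] | Iterable[tuple[CollapsedRead, float]],
    max_len: int | None = None,
) -> PositionBias:
    """Positional base composition in sequence-logo information bits.

    Frequencies are count-weighted (or weighted by supplied weights).
    Position i information content is IC_i = 2 + sum_b p_b log2 p_b and
    the reported height of base b is p_b * IC_i.  Positions beyond a
    read's length do not receive contributions from that read.
    """
    items: list[tuple[CollapsedRead, float]] = []
    for r in reads:
        if isinstance(r, tuple):
            items.append(r)
        else:
            items.append((r, float(r.count)))
    if not items:
        raise ValueError("empty read set")
    L = max_len or max(len(r.sequence) for r, _ in items)
    counts = np.zeros((L, 4))
    for r, w in items:
        for i, b in enumerate(r.sequence[:L]):
            if b in _BASE_TO_COL:
                counts[i, _BASE_TO_COL[b]] += w
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic[totals[:, 0] == 0] = 0.0
    heights = freqs * ic[:, None]
    bits_1u = float(heights[0, _BASE_TO_COL["T"]]) if L >= 1 else 0.0
    bits_10a = float(heights[9, _BASE_TO_COL["A"]]) if L >= 10 else 0.0
    return PositionBias(frequencies=freqs, bits_1U=bits_1u, bits_10A=bits_10a)


def write_histogram_tsv(hist: OverlapHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("overlap\tscore\n")
        for o in sorted(hist.S):
            fh.write(f"{o}\t{hist.S[o]:.6g}\n")


def write_stats_tsv(stats: PingPongStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k in ("pps_mbr", "pps_sd", "ppr_mbr", "ppr_sd", "z10", "p_value"):
            fh.write(f"{k}\t{getattr(stats, k):.6g}\n")


def write_matrix_tsv(mat: PingPongMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("length1\tlength2\tweight\n")
        for i, l1 in enumerate(mat.lengths):
            for j, l2 in enumerate(mat.lengths):
                if mat.M[i, j] > 0:
                    fh.write(f"{l1}\t{l2}\t{mat.M[i, j]:.6g}\n")
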