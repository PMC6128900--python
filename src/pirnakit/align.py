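"""Exhaustive mismatch-tolerant genomic mapping of small RNAs.

Small-RNA mapping here must report *every* genomic placement of a read
up to a mismatch budget (piRNAs are transposon-derived multimappers and
counts are apportioned across placements), and mismatches must be
classified into internal edits versus non-template 3' additions, because
tailed miRNAs/piRNAs carry untemplated 3' nucleotides that a naive
mismatch cap would discard.

The mapper uses disjoint exact seeds (pigeonhole over the mismatch
budget) with full verification of every candidate window, so it is
guaranteed to find exactly the set of placements a brute-force
window-by-window scan would find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from pirnakit.reads import CollapsedRead

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


# byte -> small integer code lookup; unknown bytes -> 9 (never matches)
_LUT = np.full(256, 9, dtype=np.uint8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c
_LUT[ord("N")] = 4


def encode_seq(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N to 0..4 (uint8); other bytes to 9."""
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


class Genome:
    """A reference genome held in memory with lazy k-mer indexes.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> nucleotide string (A/C/G/T/N).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty genome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper().replace("U", "T")
            if set(seq) - set("ACGTN"):
                raise ValueError(f"chromosome {name!r} has non-ACGTN characters")
            self.sequences[name] = seq
        self._codes = {n: encode_seq(s) for n, s in self.sequences.items()}
        # (chrom, q) -> (sorted window hashes, window starts in hash order)
        self._indexes: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def codes(self, chrom: str) -> np.ndarray:
        return self._codes[chrom]

    def window_index(self, chrom: str, q: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted rolling hashes of all length-q windows plus their starts.

        Hashes are base-5 polynomial hashes in wrapping uint64
        arithmetic; collisions are harmless because every candidate is
        verified base-by-base.
        """
        key = (chrom, q)
        if key not in self._indexes:
            codes = self._codes[chrom]
            n = len(codes) - q + 1
            if n <= 0:
                self._indexes[key] = (np.empty(0, np.uint64), np.empty(0, np.int64))
                return self._indexes[key]
            h = np.zeros(n, dtype=np.uint64)
            five = np.uint64(5)
            for j in range(q):
                h = h * five + codes[j : j + n].astype(np.uint64)
            order = np.argsort(h, kind="stable")
            self._indexes[key] = (h[order], order.astype(np.int64))
        return self._indexes[key]


def _hash_rows(mat: np.ndarray) -> np.ndarray:
    """Base-5 hash of each row of a uint8 code matrix (wrapping uint64)."""
    h = np.zeros(mat.shape[0], dtype=np.uint64)
    five = np.uint64(5)
    for j in range(mat.shape[1]):
        h = h * five + mat[:, j].astype(np.uint64)
    return h


@dataclass(frozen=True)
class Alignment:
    """One genomic placement of a collapsed read.

    ``start`` is the 0-based leftmost genomic position of the half-open
    interval ``[start, start + len(read))`` on the plus strand of the
    reference, regardless of read strand.  ``mismatch_positions`` are
    1-based read coordinates counted from the read 5' end.
    ``n_3p_nontemplate`` is the length of the maximal contiguous
    mismatch run ending at the read 3' terminus; remaining mismatches
    are internal.
    """

    read: CollapsedRead
    chrom: str
    start: int
    strand: str
    mismatch_positions: tuple[int, ...]
    n_internal: int
    n_3p_nontemplate: int

    @property
    def length(self) -> int:
        return len(self.read.sequence)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatch_positions)

    @property
    def five_prime(self) -> int:
        """0-based genomic position of the read 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def classify_mismatches(positions: Sequence[int], read_len: int) -> tuple[int, int]:
    """Split mismatch positions into (n_internal, n_3p_nontemplate).

    The 3'-non-template count is the maximal contiguous run of mismatch
    positions ending exactly at the read 3' terminus.
    """
    pos = set(positions)
    n3p = 0
    p = read_len
    while p in pos:
        n3p += 1
        p -= 1
    return len(pos) - n3p, n3p


def _sort_key(a: Alignment):
    return (a.read.sequence, a.chrom, a.start, a.strand)


def map_reads(
    reads: Iterable[CollapsedRead],
    genome: Genome,
    max_mismatch: int = 3,
) -> list[Alignment]:
    """Report ALL genomic placements of each read with <= max_mismatch mismatches.

    Both strands are searched; a minus-strand alignment compares the
    read with the reverse complement of the genomic window.  Output is
    (read sequence, chrom, start, strand)-sorted and deterministic.
    """
    reads = list(reads)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    alignments: list[Alignment] = []
    # group reads by length; search plus strand with the read itself and
    # minus strand with its reverse complement
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        by_len.setdefault(len(r.sequence), []).append(i)

    for L, idxs in by_len.items():
        n_seeds = max_mismatch + 1
        # seed length capped at 16 so different read lengths share one
        # genome index; pigeonhole only needs m+1 disjoint seeds
        q = min(max(1, L // n_seeds), 16)
        offsets = [i * q for i in range(min(n_seeds, L // q))][:n_seeds]
        fwd = np.stack([encode_seq(reads[i].sequence) for i in idxs])
        rev = np.stack([encode_seq(revcomp(reads[i].sequence)) for i in idxs])
        for chrom in genome.sequences:
            codes = genome.codes(chrom)
            if len(codes) < L:
                continue
            hashes, starts_by_hash = genome.window_index(chrom, q)
            for strand, mat in (("+", fwd), ("-", rev)):
                if L <= max_mismatch:
                    # too short for m+1 disjoint seeds: every window is a
                    # candidate (a window may mismatch at all L positions)
                    n_win = len(codes) - L + 1
                    cand_read = np.repeat(np.arange(mat.shape[0]), n_win)
                    cand_start = np.tile(np.arange(n_win), mat.shape[0])
                else:
                    cand_read, cand_start = _seed_candidates(
                        mat, offsets, q, hashes, starts_by_hash, len(codes), L
                    )
                if cand_read.size == 0:
                    continue
                _verify(
                    reads,
                    idxs,
                    mat,
                    codes,
                    cand_read,
                    cand_start,
                    chrom,
                    strand,
                    max_mismatch,
                    alignments,
                )
    alignments.sort(key=_sort_key)
    return alignments


def _seed_candidates(mat, offsets, q, hashes, starts_by_hash, chrom_len, L):
    """Candidate (read row, window start) pairs from exact seed hits."""
    all_read = []
    all_start = []
    for off in offsets:
        if off + q > L:
            continue
        seed_h = _hash_rows(mat[:, off : off + q])
        left = np.searchsorted(hashes, seed_h, side="left")
        right = np.searchsorted(hashes, seed_h, side="right")
        counts = right - left
        total = int(counts.sum())
        if total == 0:
            continue
        rows = np.repeat(np.arange(mat.shape[0]), counts)
        # flat indices into starts_by_hash covering [left_i, right_i) per row
        base = np.repeat(left, counts)
        within = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        win_starts = starts_by_hash[base + within] - off
        keep = (win_starts >= 0) & (win_starts + L <= chrom_len)
        all_read.append(rows[keep])
        all_start.append(win_starts[keep])
    if not all_read:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rows = np.concatenate(all_read)
    starts = np.concatenate(all_start)
    key = rows.astype(np.int64) * (chrom_len + 1) + starts
    _, uniq_idx = np.unique(key, return_index=True)
    return rows[uniq_idx], starts[uniq_idx]


def _verify(
    reads, idxs, mat, codes, cand_read, cand_start, chrom, strand, max_mm, out
):
    L = mat.shape[1]
    # batch verification to bound memory on candidate-heavy inputs
    batch = 200_000
    for b in range(0, cand_read.size, batch):
        rr = cand_read[b : b + batch]
        ss = cand_start[b : b + batch]
        windows = codes[ss[:, None] + np.arange(L)[None, :]]
        mism = windows != mat[rr]
        nm = mism.sum(axis=1)
        ok = np.nonzero(nm <= max_mm)[0]
        for j in ok:
            row = int(rr[j])
            start = int(ss[j])
            read = reads[idxs[row]]
            if nm[j] == 0:
                positions: tuple[int, ...] = ()
            else:
                offs = np.nonzero(mism[j])[0]
                if strand == "+":
                    positions = tuple(int(o) + 1 for o in offs)
                else:
                    # window offset j on the revcomp corresponds to read
                    # position L - j (1-based from the 5' end)
                    positions = tuple(sorted(L - int(o) for o in offs))
            n_int, n3p = classify_mismatches(positions, L)
            out.append(
                Alignment(read, chrom, start, strand, positions, n_int, n3p)
            )


@dataclass
class MappedReadSet:
    """Retained alignments plus the reads that failed to map.

    Every retained read has at least one alignment and, after best-hit
    filtering, all its retained alignments share the same total mismatch
    count.
    """

    alignments: list[Alignment] = field(default_factory=list)
    unmapped: list[CollapsedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._n_align: dict[str, int] = {}
        for a in self.alignments:
            self._n_align[a.read.sequence] = self._n_align.get(a.read.sequence, 0) + 1

    def n_alignments(self, read: CollapsedRead) -> int:
        return self._n_align.get(read.sequence, 0)

    def weight(self, a: Alignment) -> float:
        """Apportioned weight of one alignment: count / n placements."""
        return a.read.count / self._n_align[a.read.sequence]

    @property
    def reads(self) -> list[CollapsedRead]:
        seen: dict[str, CollapsedRead] = {}
        for a in self.alignments:
            seen.setdefault(a.read.sequence, a.read)
        return list(seen.values())

    @property
    def total_count(self) -> int:
        """Total read copies of all mapped reads."""
        return sum(r.count for r in self.reads)

    def subset(self, keep: set[str]) -> "MappedReadSet":
        """Restrict to alignments of reads whose sequence is in ``keep``."""
        return MappedReadSet(
            [a for a in self.alignments if a.read.sequence in keep], []
        )


def filter_alignments(
    alignments: Iterable[Alignment],
    max_3p_nt: int = 2,
    max_internal: int = 1,
    all_reads: Iterable[CollapsedRead] | None = None,
) -> MappedReadSet:
    """Apply the mismatch-classification filter and best-hit rule.

    1. Discard alignments with more than ``max_3p_nt`` non-template 3'
       nucleotides or more than ``max_internal`` internal mismatches.
    2. Per read, keep only alignments with the minimal total mismatch
       count among the survivors.
    3. Multimapping reads keep all tied-best alignments.

    Reads whose alignments are all discarded are reported as unmapped;
    pass ``all_reads`` to also report reads that produced no raw
    placement at all.
    """
    per_read: dict[str, list[Alignment]] = {}
    failed: dict[str, CollapsedRead] = {}
    if all_reads is not None:
        for r in all_reads:
            failed.setdefault(r.sequence, r)
    for a in alignments:
        failed.setdefault(a.read.sequence, a.read)
        if a.n_3p_nontemplate > max_3p_nt or a.n_internal > max_internal:
            continue
        per_read.setdefault(a.read.sequence, []).append(a)
    kept: list[Alignment] = []
    for seq, alns in per_read.items():
        best = min(a.n_mismatch for a in alns)
        kept.extend(a for a in alns if a.n_mismatch == best)
        failed.pop(seq, None)
    kept.sort(key=_sort_key)
    return MappedReadSet(kept, sorted(failed.values()))


def write_alignment_table(mapped: MappedReadSet, path: str | Path) -> None:
    """Tab-separated alignment export."""
    with open(path, "w") as fh:
        fh.write(
            "read\tcount\tchrom\tstart\tend\tstrand\tn_internal\tn_3p_nontemplate\n"
        )
        for a in mapped.alignments:
            fh.write(
                f"{a.read.sequence}\t{a.read.count}\t{a.chrom}\t{a.start}\t"
                f"{a.end}\t{a.strand}\t{a.n_internal}\t{a.n_3p_nontemplate}\n"
            )


def write_sam(mapped: MappedReadSet, genome: Genome, path: str | Path) -> None:
    """Minimal SAM export (M-only CIGAR; mismatches are not split)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for a in mapped.alignments:
            flag = 0 if a.strand == "+" else 16
            seq = a.read.sequence if a.strand == "+" else revcomp(a.read.sequence)
            fh.write(
                f"{a.read.sequence}_x{a.read.count}\t{flag}\t{a.chrom}\t"
                f"{a.start + 1}\t255\t{a.length}M\t*\t0\t0\t{seq}\t*\t"
                f"NM:i:{a.n_mismatch}\n"
            )
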