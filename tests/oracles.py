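"""Independent brute-force oracles used to validate the fast paths."""

from __future__ import annotations

import numpy as np

from pirnakit.align import Genome, MappedReadSet, revcomp
from pirnakit.reads import CollapsedRead


def brute_force_map(reads, genome: Genome, max_mismatch: int):
    """Window-by-window exhaustive mapping on both strands.

    Every length-L genomic window is compared base-by-base against the
    read (plus strand) and its reverse complement (minus strand); no
    seeding or indexing is involved.  Returns a set of
    (sequence, chrom, start, strand, mismatch_positions) tuples,
    mismatch positions 1-based from the read 5' end.
    """
    out = set()
    arrays = {
        c: np.frombuffer(s.encode(), dtype=np.uint8)
        for c, s in genome.sequences.items()
    }
    for read in reads:
        seq = read.sequence
        L = len(seq)
        probes = {
            "+": np.frombuffer(seq.encode(), dtype=np.uint8),
            "-": np.frombuffer(revcomp(seq).encode(), dtype=np.uint8),
        }
        for chrom, arr in arrays.items():
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            for strand, probe in probes.items():
                mism = windows != probe
                hits = np.nonzero(mism.sum(axis=1) <= max_mismatch)[0]
                for start in hits:
                    offs = np.nonzero(mism[start])[0]
                    if strand == "+":
                        positions = tuple(int(o) + 1 for o in offs)
                    else:
                        positions = tuple(sorted(L - int(o) for o in offs))
                    out.add((seq, chrom, int(start), strand, positions))
    return out


def brute_force_best_filter(placements, max_3p_nt=2, max_internal=1):
    """Reference implementation of the mismatch-class + best-hit filter."""
    from pirnakit.align import classify_mismatches

    surviving = {}
    for seq, chrom, start, strand, mism in placements:
        n_int, n3p = classify_mismatches(mism, len(seq))
        if n3p > max_3p_nt or n_int > max_internal:
            continue
        surviving.setdefault(seq, []).append(
            (len(mism), chrom, start, strand, mism)
        )
    out = set()
    for seq, cands in surviving.items():
        best = min(c[0] for c in cands)
        for nm, chrom, start, strand, mism in cands:
            if nm == best:
                out.add((seq, chrom, start, strand, mism))
    return out


def allpairs_overlap_histogram(mapped: MappedReadSet, max_overlap: int = 20):
    """O(n^2) all-pairs 5'-overlap score oracle."""
    S = {o: 0.0 for o in range(1, max_overlap + 1)}
    plus = [(a, mapped.weight(a)) for a in mapped.alignments if a.strand == "+"]
    minus = [(a, mapped.weight(a)) for a in mapped.alignments if a.strand == "-"]
    for ap, wp in plus:
        for am, wm in minus:
            if am.chrom != ap.chrom:
                continue
            o = am.five_prime - ap.five_prime + 1
            if 1 <= o <= max_overlap:
                S[o] += wp * wm
    return S


def allpairs_participating(mapped: MappedReadSet):
    """Reads with >=1 alignment in a 10 bp 5'-overlap pair (oracle)."""
    plus_ends = {}
    minus_ends = {}
    for a in mapped.alignments:
        d = plus_ends if a.strand == "+" else minus_ends
        d.setdefault((a.chrom, a.five_prime), set()).add(a.read.sequence)
    participating = set()
    for (chrom, p), seqs in plus_ends.items():
        partner = minus_ends.get((chrom, p + 9))
        if partner:
            participating |= seqs | partner
    return participating
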