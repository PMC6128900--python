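"""Read ingestion, collapsing and complexity filtering.

Small-RNA libraries contain many identical molecules; collapsing to
unique sequences with copy counts is the first processing step.  Reads
longer than 36 nt cannot be piRNAs and are rejected; low-complexity
sequences (homopolymers, short tandem repeats) are removed because they
map promiscuously and carry no positional information.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

_VALID = set("ACGTN")


def _normalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass
class RawReadSet:
    """An ordered collection of raw reads from one library.

    Parameters
    ----------
    source_id
        Free-text label of the library (e.g. a tissue or SRA run).
    records
        Ordered ``(read_id, sequence)`` tuples.  Sequences are
        normalized to the DNA alphabet A/C/G/T/N on construction.
    """

    source_id: str
    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        normd = []
        for read_id, seq in self.records:
            seq = _normalize(seq)
            if not seq:
                raise ValueError(f"empty sequence in record {read_id!r}")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"record {read_id!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            normd.append((read_id, seq))
        self.records = normd

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, order=True)
class CollapsedRead:
    """A unique small-RNA sequence with its aggregated copy count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, source_id: str | None = None) -> RawReadSet:
    """Read a (optionally gzipped) FASTA file into a :class:`RawReadSet`."""
    records = []
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            records.append((name, "".join(chunks)))
    return RawReadSet(source_id or str(path), records)


def read_fastq(path: str | Path, source_id: str | None = None) -> RawReadSet:
    """Read a (optionally gzipped) FASTQ file into a :class:`RawReadSet`."""
    records = []
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            fh.readline()  # quality line, ignored
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header.strip()!r}")
            records.append((header[1:].split()[0], seq))
    return RawReadSet(source_id or str(path), records)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def collapse_and_filter(
    reads: RawReadSet, max_len: int = 36
) -> list[CollapsedRead]:
    """Collapse raw reads to unique sequences with counts.

    Reads longer than ``max_len`` and reads containing N are discarded;
    the counts of the survivors sum to the number of retained raw
    records.

    Returns the collapsed reads sorted by descending count, then
    sequence, for deterministic downstream behaviour.
    """
    counts: dict[str, int] = {}
    for _read_id, seq in reads.records:
        if len(seq) > max_len or "N" in seq:
            continue
        counts[seq] = counts.get(seq, 0) + 1
    return sorted(
        (CollapsedRead(s, c) for s, c in counts.items()),
        key=lambda r: (-r.count, r.sequence),
    )


def is_low_complexity(
    seq: str, max_repeat_fraction: float = 0.75, max_motif: int = 5
) -> bool:
    """Tandem-repeat coverage test.

    A sequence is low-complexity iff for some motif length k in
    ``1..max_motif`` the longest contiguous run of perfect tandem
    repeats of a single k-mer covers at least ``max_repeat_fraction``
    of the sequence.
    """
    n = len(seq)
    if n == 0:
        return False
    for k in range(1, max_motif + 1):
        if k > n:
            break
        # longest stretch where seq[i] == seq[i-k], extended by the
        # leading k-mer itself
        best = run = k
        for i in range(k, n):
            if seq[i] == seq[i - k]:
                run += 1
            else:
                run = k
            if run > best:
                best = run
        if best / n >= max_repeat_fraction:
            return True
    return False


def filter_low_complexity(
    reads: Iterable[CollapsedRead],
    max_repeat_fraction: float = 0.75,
    max_motif: int = 5,
) -> list[CollapsedRead]:
    """Remove low-complexity reads (see :func:`is_low_complexity`)."""
    if not 0 < max_repeat_fraction <= 1:
        raise ValueError("max_repeat_fraction must be in (0, 1]")
    if max_motif < 1:
        raise ValueError("max_motif must be >= 1")
    return [
        r
        for r in reads
        if not is_low_complexity(r.sequence, max_repeat_fraction, max_motif)
    ]


def write_collapsed_fasta(reads: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``>seq<i>_x<count>`` headers.

    Ordering is deterministic: descending count, then lexicographic
    sequence, so write -> read -> write is byte-identical.
    """
    ordered = sorted(reads, key=lambda r: (-r.count, r.sequence))
    with open(path, "w") as fh:
        for i, r in enumerate(ordered, start=1):
            fh.write(f">seq{i}_x{r.count}\n{r.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[CollapsedRead]:
    """Read the collapsed-FASTA dialect written by :func:`write_collapsed_fasta`."""
    reads: list[CollapsedRead] = []
    count = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                try:
                    count = int(line.rsplit("_x", 1)[1])
                except (IndexError, ValueError):
                    raise ValueError(
                        f"{path}:{lineno}: malformed collapsed-FASTA header {line!r}"
                    ) from None
            else:
                if count is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                reads.append(CollapsedRead(_normalize(line), count))
                count = None
    return sorted(reads, key=lambda r: (-r.count, r.sequence))
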