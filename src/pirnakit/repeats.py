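"""Transposon landscapes and piRNA-cluster repeat/gene content.

Consumes RepeatMasker ``.out`` annotation (we parse the format; running
RepeatMasker itself is out of scope) and computes: divergence-binned
transposon landscapes (bp per family per 1% divergence bin, a proxy for
insertion-age structure), genome-wide and restricted to piRNA clusters;
per-family cluster-vs-genome enrichment folds; and the protein-coding
(CDS) content of clusters from a GFF3 annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pirnakit.clusters import PiRNACluster


@dataclass
class RepeatRecord:
    """One RepeatMasker hit, coordinates converted to 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_family: str
    percent_divergence: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatAnnotation:
    records: list[RepeatRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def families(self) -> list[str]:
        return sorted({r.repeat_family for r in self.records})

    @property
    def total_bp(self) -> int:
        """Per-record bp (nested hits counted per record)."""
        return sum(r.length for r in self.records)


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "  repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)   repeat"
    "         class/family      begin  end    (left)  ID\n"
    "\n"
)


def parse_repeatmasker_out(path: str | Path) -> RepeatAnnotation:
    """Parse a standard RepeatMasker ``.out`` file.

    The three header lines are skipped; fields are whitespace-separated
    with column 2 the percent divergence, columns 5-7 the 1-based
    inclusive query coordinates and column 9 the strand ('C' meaning
    minus).  Malformed lines raise with their line number.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            try:
                div = float(fields[1])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = "-" if fields[8] in ("C", "-") else "+"
                name = fields[9]
                family = fields[10]
            except (IndexError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: malformed RepeatMasker line: {line.rstrip()!r}"
                ) from None
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            if not 0 <= div <= 100:
                raise ValueError(f"{path}:{lineno}: divergence {div} out of range")
            if family in ("", "Unknown", "unknown", "Unspecified"):
                family = "Unknown"
            records.append(
                RepeatRecord(chrom, start, end, strand, name, family, div)
            )
    return RepeatAnnotation(records)


def write_repeatmasker_out(annot: RepeatAnnotation, path: str | Path) -> None:
    """Write records back in RepeatMasker ``.out`` layout (fixture writer)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, r in enumerate(annot.records, start=1):
            strand = "C" if r.strand == "-" else "+"
            fh.write(
                f"{1000:>5} {r.percent_divergence:4.1f}  0.0  0.0  {r.chrom} "
                f"{r.start + 1} {r.end} (0) {strand} {r.repeat_name} "
                f"{r.repeat_family} 1 {r.length} (0) {i}\n"
            )


class _IntervalSet:
    """Merged disjoint intervals per chromosome with O(log n) overlap bp."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            by_chrom.setdefault(chrom, []).append((s, e))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0
        for chrom, ivs in by_chrom.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            cum = np.concatenate(([0], np.cumsum(ends - starts)))
            self._data[chrom] = (starts, ends, cum)
            total += int(cum[-1])
        self.total_bp = total

    def overlap_bp(self, chrom: str, s: int, e: int) -> int:
        if chrom not in self._data:
            return 0
        starts, ends, cum = self._data[chrom]
        i = int(np.searchsorted(ends, s, side="right"))
        j = int(np.searchsorted(starts, e, side="left"))
        if i >= j:
            return 0
        full = int(cum[j] - cum[i])
        # clip the flanking intervals to [s, e)
        full -= max(0, s - int(starts[i]))
        full -= max(0, int(ends[j - 1]) - e)
        return full


@dataclass
class TELandscape:
    """bp per (family, integer divergence bin); scope genome or clusters."""

    table: pd.DataFrame  # index: family, columns: bin 0..max_bin
    scope: str

    @property
    def family_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def total_bp(self) -> float:
        return float(self.table.to_numpy().sum())


def te_landscape(
    annot: RepeatAnnotation,
    scope_intervals: Sequence[tuple[str, int, int]] | None = None,
    max_divergence: int = 50,
    bin_width: float = 1.0,
) -> TELandscape:
    """Divergence-binned transposon landscape.

    Each record contributes its bp overlap with the scope (whole genome
    if no intervals are given) to bin ``floor(divergence / bin_width)``;
    divergences above ``max_divergence`` fall into the last bin so that
    per-family bp totals are conserved.  Records are counted
    individually (nested hits may double-count; use
    :func:`enrichment_fold` for unioned fractions).
    """
    n_bins = int(max_divergence / bin_width) + 1
    scope = _IntervalSet(scope_intervals) if scope_intervals is not None else None
    fams = annot.families
    table = pd.DataFrame(
        0.0, index=fams, columns=list(range(n_bins))
    )
    for r in annot.records:
        bp = (
            r.length
            if scope is None
            else scope.overlap_bp(r.chrom, r.start, r.end)
        )
        if bp == 0:
            continue
        b = min(int(r.percent_divergence / bin_width), n_bins - 1)
        table.at[r.repeat_family, b] += bp
    return TELandscape(table, "genome" if scope is None else "clusters")


@dataclass
class EnrichmentTable:
    """Per-family genome/cluster fractions and enrichment folds."""

    table: pd.DataFrame  # columns: genome_fraction, cluster_fraction, fold
    genome_repeat_content: float
    cluster_repeat_content: float


def enrichment_fold(
    annot: RepeatAnnotation,
    clusters: Sequence[PiRNACluster],
    genome_size: int,
) -> EnrichmentTable:
    """Cluster-vs-genome enrichment of each repeat family.

    Fractions use per-family unioned bp (nested RepeatMasker hits do not
    double-count), so genome_fraction = family bp / genome bp and
    cluster_fraction = family bp inside clusters / total cluster bp;
    fold is their ratio (NaN where the family is absent genome-wide).
    The overall repeat content of the genome and of the clusters is
    reported alongside.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    cluster_set = _IntervalSet((c.chrom, c.start, c.end) for c in clusters)
    if cluster_set.total_bp == 0:
        raise ValueError("zero total cluster bp")
    per_family: dict[str, list[tuple[str, int, int]]] = {}
    for r in annot.records:
        per_family.setdefault(r.repeat_family, []).append((r.chrom, r.start, r.end))
    rows = {}
    for fam, ivs in per_family.items():
        fam_set = _IntervalSet(ivs)
        g_frac = fam_set.total_bp / genome_size
        in_cluster = sum(
            cluster_set.overlap_bp(ch, s, e)
            for ch, (s, e) in _merged_items(fam_set)
        )
        c_frac = in_cluster / cluster_set.total_bp
        rows[fam] = {
            "genome_fraction": g_frac,
            "cluster_fraction": c_frac,
            "fold": c_frac / g_frac if g_frac > 0 else float("nan"),
        }
    all_set = _IntervalSet((r.chrom, r.start, r.end) for r in annot.records)
    in_cluster_all = sum(
        cluster_set.overlap_bp(ch, s, e) for ch, (s, e) in _merged_items(all_set)
    )
    columns = ["genome_fraction", "cluster_fraction", "fold"]
    table = (
        pd.DataFrame(rows).T.sort_values("fold", ascending=False)
        if rows
        else pd.DataFrame(columns=columns)
    )
    return EnrichmentTable(
        table,
        genome_repeat_content=all_set.total_bp / genome_size,
        cluster_repeat_content=in_cluster_all / cluster_set.total_bp,
    )


def _merged_items(iset: _IntervalSet):
    for chrom, (starts, ends, _cum) in iset._data.items():
        for s, e in zip(starts, ends):
            yield chrom, (int(s), int(e))


def gene_content(
    clusters: Sequence[PiRNACluster],
    gff3_path: str | Path,
    feature_types: tuple[str, ...] = ("CDS",),
) -> tuple[pd.DataFrame, float]:
    """Protein-coding fraction of piRNA clusters.

    The fraction is bp of cluster intersected with the union of CDS
    features divided by cluster bp; per-cluster values and the
    cluster-bp-weighted aggregate are returned.  Cluster
    ``gene_content`` attributes are filled in.
    """
    cds: list[tuple[str, int, int]] = []
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(f"malformed GFF3 line: {line.rstrip()!r}")
            if f[2] in feature_types:
                cds.append((f[0], int(f[3]) - 1, int(f[4])))
    if not cds:
        warnings.warn(f"no {feature_types} features in {gff3_path}; fractions are 0")
    cds_set = _IntervalSet(cds)
    rows = []
    tot_bp = tot_overlap = 0
    for c in clusters:
        ov = cds_set.overlap_bp(c.chrom, c.start, c.end)
        frac = ov / c.length if c.length else 0.0
        c.gene_content = frac
        rows.append({"cluster": c.name, "coding_fraction": frac})
        tot_bp += c.length
        tot_overlap += ov
    aggregate = tot_overlap / tot_bp if tot_bp else 0.0
    return pd.DataFrame(rows), aggregate


def cluster_repeat_content(
    annot: RepeatAnnotation, clusters: Sequence[PiRNACluster]
) -> None:
    """Fill per-cluster ``repeat_content`` (unioned repeat bp / cluster bp)."""
    rep_set = _IntervalSet((r.chrom, r.start, r.end) for r in annot.records)
    for c in clusters:
        c.repeat_content = (
            rep_set.overlap_bp(c.chrom, c.start, c.end) / c.length
            if c.length
            else 0.0
        )


def write_landscape_tsv(ls: TELandscape, path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tdivergence_bin\tbp\n")
        for fam in ls.table.index:
            for b in ls.table.columns:
                bp = ls.table.at[fam, b]
                if bp > 0:
                    fh.write(f"{fam}\t{b}\t{bp:.0f}\n")


def write_enrichment_tsv(et: EnrichmentTable, path) -> None:
    et.table.to_csv(path, sep="\t", index_label="family")
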