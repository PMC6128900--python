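"""Synthetic small-RNA study generator with a ground-truth manifest.

Generates a random genome with planted piRNA clusters, transposon
copies at controlled per-family genomic fractions and cluster
enrichment folds, tRNA/miRNA/protein-coding loci, and a small-RNA read
set with known structure:

* primary piRNAs drawn from cluster intervals, 5'U-biased, with a
  strand-coherent cluster orientation plus a minor antisense fraction;
* a controllable fraction (the ping-pong rate) of primaries spawning a
  secondary piRNA on the opposite strand with exactly 10 bp 5' overlap
  and the complementary 10A bias;
* background classes: miRNAs (from planted precursor loci), 3' tRFs
  (ending at the mature tRNA 3' end, CCA included), mRNA degradation
  fragments (18-30 nt, sampled sense from the planted gene loci — the
  annotated class that spans the piRNA length window), and
  low-complexity reads;
* per-read copy counts from a geometric distribution (exercises
  collapsing).

Biased bases are written back into the genome before read extraction,
so every non-low-complexity read maps with zero mismatches; untemplated
3' tails can be appended to a configurable read fraction to exercise
the alignment filter.  Everything realized (cluster coordinates, read
labels, the participating-read fraction from an all-pairs oracle on the
true coordinates, per-family bp) is recorded in a serializable
GroundTruth manifest for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pirnakit.align import Genome, revcomp
from pirnakit.reads import RawReadSet
from pirnakit.repeats import RepeatAnnotation, RepeatRecord, write_repeatmasker_out

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TEFamily:
    """A planted transposon family."""

    name: str
    genome_fraction: float
    cluster_enrichment_fold: float
    divergence_mean: float
    divergence_sd: float = 3.0
    consensus_length: int = 500


def default_te_families() -> list[TEFamily]:
    return [
        TEFamily("Gypsy", 0.04, 4.0, 12.0),
        TEFamily("RTE", 0.03, 1.0, 18.0),
        TEFamily("Kolobok", 0.01, 8.0, 6.0),
        TEFamily("hAT5", 0.008, 12.0, 5.0),
        TEFamily("Unknown", 0.05, 1.0, 25.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a mollusk-scale desk study: a 2 Mb genome over 5
    chromosomes with 20 planted piRNA clusters, 50k raw reads with a
    piRNA fraction showing a 0.3 ping-pong rate, 0.8/0.7 1U/10A biases,
    distinct primary (≈29 nt) and secondary (≈25 nt) length
    populations, and miRNA / 3'-tRF / low-complexity background at
    proportions echoing real mollusk libraries.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    n_chroms: int = 5
    n_clusters: int = 20
    cluster_length_range: tuple[int, int] = (3000, 8000)
    cluster_min_separation: int = 25_000
    te_families: list[TEFamily] = field(default_factory=default_te_families)
    n_reads: int = 50_000
    pingpong_rate: float = 0.3
    primary_length_dist: dict[int, float] = field(
        default_factory=lambda: {28: 0.2, 29: 0.6, 30: 0.2}
    )
    secondary_length_dist: dict[int, float] = field(
        default_factory=lambda: {24: 0.2, 25: 0.6, 26: 0.2}
    )
    p_1U: float = 0.8
    p_10A: float = 0.7
    frac_antisense: float = 0.1
    background: dict[str, float] = field(
        default_factory=lambda: {
            "miRNA": 0.40,
            "tRF": 0.12,
            "mRNA_frag": 0.06,
            "low_complexity": 0.03,
        }
    )
    n_mirna_genes: int = 25
    n_trna_genes: int = 12
    n_genes: int = 30
    gene_length: int = 1500
    frac_3p_tailed: float = 0.0
    duplication_p: float = 0.5

    def validate(self) -> None:
        if not 0 <= self.pingpong_rate <= 1:
            raise ValueError("pingpong_rate must be in [0, 1]")
        if sum(self.background.values()) > 1:
            raise ValueError("background proportions must sum to <= 1")
        te_total = sum(f.genome_fraction for f in self.te_families)
        if te_total > 0.9:
            raise ValueError(f"TE genome fractions sum to {te_total} > 0.9")
        chrom_len = self.genome_length // self.n_chroms
        if self.cluster_length_range[1] + 2 * self.cluster_min_separation > chrom_len:
            raise ValueError("chromosomes too short for the requested clusters")


@dataclass
class GroundTruth:
    """Realized design of one simulation, for recovery tests."""

    clusters: list[tuple[str, int, int, str]] = field(default_factory=list)
    te_realized: dict = field(default_factory=dict)
    mirna_refs: list[tuple[str, str]] = field(default_factory=list)
    trna_refs: list[tuple[str, str]] = field(default_factory=list)
    mrna_refs: list[tuple[str, str]] = field(default_factory=list)
    gene_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    read_labels: dict[str, str] = field(default_factory=dict)
    participating_sequences: list[str] = field(default_factory=list)
    participating_fraction: float = 0.0
    counts_by_label: dict[str, int] = field(default_factory=dict)
    total_mappable_count: int = 0

    def te_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.te_realized).T

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        gt = cls(**d)
        gt.clusters = [tuple(c) for c in gt.clusters]
        gt.mirna_refs = [tuple(r) for r in gt.mirna_refs]
        gt.trna_refs = [tuple(r) for r in gt.trna_refs]
        gt.mrna_refs = [tuple(r) for r in gt.mrna_refs]
        gt.gene_intervals = [tuple(g) for g in gt.gene_intervals]
        return gt


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _overlaps(occ: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(s < oe and os_ < e for os_, oe in occ)


def _place(
    rng: np.random.Generator,
    chrom_len: int,
    length: int,
    occupied: list[tuple[int, int]],
    lo: int = 0,
    hi: int | None = None,
    tries: int = 200,
) -> int | None:
    hi = chrom_len if hi is None else hi
    if hi - lo < length:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi - length + 1))
        if not _overlaps(occupied, s, s + length):
            return s
    return None


def simulate_genome(
    config: SimulationConfig,
) -> tuple[Genome, RepeatAnnotation, GroundTruth]:
    """Random genome with planted clusters, TE copies and gene/ncRNA loci.

    TE copy numbers are deterministic given the target fractions (copies
    = target bp / consensus length, placed without intra-family
    overlap), so realized fractions match the plan up to rounding and
    placement rejection; realized bp are recorded in the manifest.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom_len = config.genome_length // config.n_chroms
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    arrays = {c: _random_seq(rng, chrom_len) for c in chrom_names}
    truth = GroundTruth()

    # --- piRNA clusters: strand-coherent intervals, well separated ---
    sep = config.cluster_min_separation
    occ_cluster: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for i in range(config.n_clusters):
        chrom = chrom_names[i % config.n_chroms]
        length = int(rng.integers(*config.cluster_length_range))
        padded = [(max(0, s - sep), e + sep) for s, e in occ_cluster[chrom]]
        s = _place(rng, chrom_len, length, padded, lo=sep, hi=chrom_len - sep)
        if s is None:
            raise ValueError("could not place clusters; reduce n_clusters/separation")
        strand = "+" if rng.random() < 0.5 else "-"
        occ_cluster[chrom].append((s, s + length))
        truth.clusters.append((chrom, s, s + length, strand))
    cluster_bp = sum(e - s for _, s, e, _ in truth.clusters)

    # --- transposon copies at planted fractions / enrichment folds ---
    records: list[RepeatRecord] = []
    te_occ: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    clusters_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for chrom, s, e, _ in truth.clusters:
        clusters_by_chrom[chrom].append((s, e))
    cluster_list = [(c, s, e) for c, s, e, _ in truth.clusters]
    cluster_weights = np.array([e - s for _, s, e in cluster_list], dtype=float)
    cluster_weights /= cluster_weights.sum()

    for fam in config.te_families:
        target_total = fam.genome_fraction * config.genome_length
        target_in = fam.genome_fraction * fam.cluster_enrichment_fold * cluster_bp
        if target_in > target_total + fam.consensus_length:
            raise ValueError(
                f"family {fam.name}: enrichment fold {fam.cluster_enrichment_fold} "
                "infeasible for the cluster/genome size ratio"
            )
        n_in = int(round(target_in / fam.consensus_length))
        n_out = int(round((target_total - target_in) / fam.consensus_length))
        consensus = _random_seq(rng, fam.consensus_length)
        realized_in = realized_out = 0
        for k in range(n_in + n_out):
            inside = k < n_in
            if inside:
                ci = int(rng.choice(len(cluster_list), p=cluster_weights))
                chrom, lo, hi = cluster_list[ci]
                s = _place(rng, chrom_len, fam.consensus_length, te_occ[chrom], lo, hi)
            else:
                chrom = chrom_names[int(rng.integers(config.n_chroms))]
                avoid = te_occ[chrom] + clusters_by_chrom[chrom]
                s = _place(rng, chrom_len, fam.consensus_length, avoid)
            if s is None:
                continue
            div = float(np.clip(rng.normal(fam.divergence_mean, fam.divergence_sd), 0.5, 49.5))
            copy = consensus.copy()
            n_mut = int(round(div / 100 * fam.consensus_length))
            if n_mut:
                pos = rng.choice(fam.consensus_length, size=n_mut, replace=False)
                copy[pos] = _BASES[
                    (np.searchsorted(_BASES, copy[pos]) + rng.integers(1, 4, n_mut)) % 4
                ]
            arrays[chrom][s : s + fam.consensus_length] = copy
            te_occ[chrom].append((s, s + fam.consensus_length))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                RepeatRecord(
                    chrom, s, s + fam.consensus_length, strand, f"{fam.name}-1",
                    fam.name, round(div, 1),
                )
            )
            if inside:
                realized_in += fam.consensus_length
            else:
                realized_out += fam.consensus_length
        truth.te_realized[fam.name] = {
            "planted_genome_fraction": fam.genome_fraction,
            "planted_fold": fam.cluster_enrichment_fold,
            "genome_bp": realized_in + realized_out,
            "cluster_bp": realized_in,
            "genome_fraction": (realized_in + realized_out) / config.genome_length,
            "cluster_fraction": realized_in / cluster_bp if cluster_bp else 0.0,
        }

    # --- ncRNA and protein-coding loci (outside clusters and TE copies) ---
    def _plant_locus(seq: np.ndarray) -> tuple[str, int] | None:
        chrom = chrom_names[int(rng.integers(config.n_chroms))]
        avoid = te_occ[chrom] + clusters_by_chrom[chrom]
        s = _place(rng, chrom_len, len(seq), avoid)
        if s is None:
            return None
        arrays[chrom][s : s + len(seq)] = seq
        te_occ[chrom].append((s, s + len(seq)))
        return chrom, s

    for i in range(config.n_mirna_genes):
        mature = _random_seq(rng, int(rng.integers(21, 23)))
        placed = _plant_locus(mature)
        if placed:
            truth.mirna_refs.append((f"mir-{i + 1}", mature.tobytes().decode()))
    isoacceptors = [
        "tRNA-Gly-TCC", "tRNA-Ala-AGC", "tRNA-Glu-CTC", "tRNA-Lys-TTT",
        "tRNA-Val-CAC", "tRNA-Asp-GTC",
    ]
    for i in range(config.n_trna_genes):
        trna = _random_seq(rng, 72)
        # plant mature tRNA followed by CCA so the 3' tRF is templated
        locus = np.concatenate([trna, np.frombuffer(b"CCA", dtype=np.uint8)])
        placed = _plant_locus(locus)
        if placed:
            name = f"{isoacceptors[i % len(isoacceptors)]}-{i // len(isoacceptors) + 1}"
            truth.trna_refs.append((name, trna.tobytes().decode()))
    for i in range(config.n_genes):
        chrom = chrom_names[int(rng.integers(config.n_chroms))]
        s = _place(rng, chrom_len, config.gene_length, [])
        if s is not None:
            truth.gene_intervals.append((chrom, s, s + config.gene_length))

    genome = Genome(
        {c: arrays[c].tobytes().decode() for c in chrom_names}
    )
    return genome, RepeatAnnotation(records), truth


def _sample_len(rng, dist: dict[int, float]) -> int:
    ls = sorted(dist)
    ps = np.array([dist[l] for l in ls], dtype=float)
    return int(rng.choice(ls, p=ps / ps.sum()))


def simulate_reads(
    config: SimulationConfig, genome: Genome, truth: GroundTruth
) -> tuple[RawReadSet, Genome, GroundTruth]:
    """Simulate the small-RNA library over a simulated genome.

    Returns the raw read set, the genome updated with the forced 1U/10A
    bases (reads are extracted from the updated genome so they map with
    zero mismatches), and the manifest updated with read labels and the
    participating-read fraction computed by an all-pairs 10 bp-overlap
    oracle on the true coordinates.
    """
    rng = np.random.default_rng([config.seed, 2])
    arrays = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy() for c, s in genome.sequences.items()}
    chrom_len = {c: len(a) for c, a in arrays.items()}
    mean_dup = 1.0 / config.duplication_p

    bg_total = sum(config.background.values())
    n_events = max(1, int(round(config.n_reads / mean_dup)))
    n_bg = {
        cls: int(round(frac * n_events)) for cls, frac in config.background.items()
    }
    n_pi = max(0, n_events - sum(n_bg.values()))
    rho = config.pingpong_rate
    n_primary = int(round(n_pi / (1.0 + rho))) if n_pi else 0

    clusters = truth.clusters
    cw = np.array([e - s for _, s, e, _ in clusters], dtype=float)
    cw = cw / cw.sum() if len(clusters) else cw

    # events: (label, chrom, strand, five_prime, length, tail)
    events: list[tuple[str, str, str, int, int, str]] = []

    for _ in range(n_primary):
        if not clusters:
            break
        ci = int(rng.choice(len(clusters), p=cw))
        chrom, cs, ce, cstrand = clusters[ci]
        L = _sample_len(rng, config.primary_length_dist)
        antisense = rng.random() < config.frac_antisense
        strand = cstrand if not antisense else ("-" if cstrand == "+" else "+")
        paired = (not antisense) and rng.random() < rho
        for _try in range(100):
            start = int(rng.integers(cs, ce - L))
            fp = start if strand == "+" else start + L - 1
            if paired:
                Ls = _sample_len(rng, config.secondary_length_dist)
                fp2 = fp + 9 if strand == "+" else fp - 9
                s2 = fp2 - Ls + 1 if strand == "+" else fp2
                if s2 < 0 or s2 + Ls > chrom_len[chrom]:
                    continue
            break
        else:
            continue
        # forced biases are written to the plus strand of the genome: the
        # initiator 5'U and the responder 10A are the same genomic base
        force = rng.random() < config.p_1U
        if paired:
            force = force or rng.random() < config.p_10A
        if force:
            arrays[chrom][fp] = ord("T") if strand == "+" else ord("A")
        events.append(("primary", chrom, strand, fp, L, ""))
        if paired:
            strand2 = "-" if strand == "+" else "+"
            events.append(("secondary", chrom, strand2, fp2, Ls, ""))

    for _ in range(n_bg.get("miRNA", 0)):
        if not truth.mirna_refs:
            break
        name, seq = truth.mirna_refs[int(rng.integers(len(truth.mirna_refs)))]
        events.append(("miRNA", "", "+", -1, len(seq), seq))
    for _ in range(n_bg.get("tRF", 0)):
        if not truth.trna_refs:
            break
        name, seq = truth.trna_refs[int(rng.integers(len(truth.trna_refs)))]
        trf = (seq + "CCA")[-21:]
        events.append(("tRF", "", "+", -1, len(trf), trf))
    genes = truth.gene_intervals
    for _ in range(n_bg.get("mRNA_frag", 0)):
        if not genes:
            break
        chrom, gs, ge = genes[int(rng.integers(len(genes)))]
        L = int(rng.integers(18, 31))
        s = int(rng.integers(gs, ge - L))
        events.append(("mRNA_frag", chrom, "+", s, L, ""))
    motifs = ["A", "T", "AC", "AG", "AT", "CT"]
    for _ in range(n_bg.get("low_complexity", 0)):
        m = motifs[int(rng.integers(len(motifs)))]
        events.append(("low_complexity", "", "+", -1, 21, (m * 21)[:21]))

    # extract genomic sequences after all forced writes
    recs: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    counts_by_label: dict[str, int] = {}
    seq_counts: dict[str, int] = {}
    plus_ends: dict[tuple[str, int], set[str]] = {}
    minus_ends: dict[tuple[str, int], set[str]] = {}
    rid = 0
    for label, chrom, strand, fp, L, literal in events:
        if literal:
            seq = literal
        else:
            if strand == "+":
                seq = arrays[chrom][fp : fp + L].tobytes().decode()
            else:
                seq = revcomp(arrays[chrom][fp - L + 1 : fp + 1].tobytes().decode())
            if label in ("primary", "secondary") and rng.random() < config.frac_3p_tailed:
                tail_n = int(rng.integers(1, 3))
                seq = seq + "".join(
                    "ACGT"[int(rng.integers(4))] for _ in range(tail_n)
                )
        copies = int(rng.geometric(config.duplication_p))
        for _ in range(copies):
            rid += 1
            recs.append((f"r{rid:06d}", seq))
        labels.setdefault(seq, label)
        counts_by_label[label] = counts_by_label.get(label, 0) + copies
        seq_counts[seq] = seq_counts.get(seq, 0) + copies
        if label != "low_complexity" and not literal:
            (plus_ends if strand == "+" else minus_ends).setdefault(
                (chrom, fp), set()
            ).add(seq)
        elif label in ("miRNA", "tRF"):
            # background loci are genomic but isolated; they cannot pair
            pass

    # all-pairs oracle on true coordinates: 10 bp 5' overlap pairs
    participating: set[str] = set()
    for (chrom, p), seqs in plus_ends.items():
        partner = minus_ends.get((chrom, p + 9))
        if partner:
            participating |= seqs
            participating |= partner
    mappable = {s: c for s, c in seq_counts.items() if labels[s] != "low_complexity"}
    total_mappable = sum(mappable.values())
    part_count = sum(c for s, c in mappable.items() if s in participating)

    # mRNA references: gene transcripts extracted after forced writes so
    # degradation fragments match their reference exactly
    truth.mrna_refs = [
        (f"gene{i + 1}", arrays[chrom][s:e].tobytes().decode())
        for i, (chrom, s, e) in enumerate(truth.gene_intervals)
    ]
    truth.read_labels = labels
    truth.participating_sequences = sorted(participating)
    truth.participating_fraction = (
        part_count / total_mappable if total_mappable else 0.0
    )
    truth.counts_by_label = counts_by_label
    truth.total_mappable_count = total_mappable

    updated = Genome({c: a.tobytes().decode() for c, a in arrays.items()})
    reads = RawReadSet(f"sim_seed{config.seed}", recs)
    return reads, updated, truth


@dataclass
class SyntheticDataset:
    """Convenience bundle: one fully simulated study."""

    config: SimulationConfig
    genome: Genome
    repeats: RepeatAnnotation
    reads: RawReadSet
    truth: GroundTruth

    def write_fixture(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome FASTA, reads FASTQ, RepeatMasker .out, GFF3,
        reference FASTAs and the truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "reads": outdir / "reads.fastq",
            "repeats": outdir / "repeats.out",
            "gff3": outdir / "genes.gff3",
            "mirna": outdir / "mirna.fa",
            "trna": outdir / "trna.fa",
            "mrna": outdir / "mrna.fa",
            "truth": outdir / "truth.json",
        }
        self.genome.to_fasta(paths["genome"])
        with open(paths["reads"], "w") as fh:
            for rid, seq in self.reads.records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        write_repeatmasker_out(self.repeats, paths["repeats"])
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for i, (chrom, s, e) in enumerate(self.truth.gene_intervals, 1):
                fh.write(
                    f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t+\t.\tID=gene{i}\n"
                    f"{chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t+\t0\tID=cds{i};Parent=gene{i}\n"
                )
        for key, refs in (
            ("mirna", self.truth.mirna_refs),
            ("trna", self.truth.trna_refs),
            ("mrna", self.truth.mrna_refs),
        ):
            with open(paths[key], "w") as fh:
                for name, seq in refs:
                    fh.write(f">{name}\n{seq}\n")
        self.truth.save(paths["truth"])
        return paths


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run both simulation stages and bundle the results."""
    genome, repeat_annot, truth = simulate_genome(config)
    reads, genome, truth = simulate_reads(config, genome, truth)
    return SyntheticDataset(config, genome, repeat_annot, reads, truth)
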