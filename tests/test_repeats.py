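import numpy as np
import pytest

from pirnakit.clusters import PiRNACluster
from pirnakit.repeats import (
    RepeatAnnotation,
    RepeatRecord,
    enrichment_fold,
    gene_content,
    parse_repeatmasker_out,
    te_landscape,
    write_repeatmasker_out,
)
from pirnakit.synthetic import SimulationConfig, simulate_genome


def _rec(chrom, start, end, family="Gypsy", div=3.2, strand="+"):
    return RepeatRecord(chrom, start, end, strand, family + "-1", family, div)


class TestParser:
    def test_round_trip_and_coordinate_conversion(self, tmp_path):
        annot = RepeatAnnotation(
            [_rec("chr1", 1000, 1500), _rec("chr2", 0, 200, "hAT5", 11.8, "-")]
        )
        p = tmp_path / "x.out"
        write_repeatmasker_out(annot, p)
        got = parse_repeatmasker_out(p)
        assert [(r.chrom, r.start, r.end, r.strand, r.repeat_family,
                 r.percent_divergence) for r in got.records] == [
            ("chr1", 1000, 1500, "+", "Gypsy", 3.2),
            ("chr2", 0, 200, "-", "hAT5", 11.8),
        ]

    def test_one_based_inclusive_input(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text(
            "h1\nh2\n\n"
            "  225 3.2 0.0 0.0 scaf1 1001 1500 (0) + Gypsy-1 Gypsy 1 500 (0) 1\n"
        )
        r = parse_repeatmasker_out(p).records[0]
        assert (r.start, r.end) == (1000, 1500)

    def test_c_strand_maps_to_minus(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text(
            "h1\nh2\n\n"
            "  225 3.2 0.0 0.0 scaf1 1 100 (0) C Gypsy-1 Gypsy 1 100 (0) 1\n"
        )
        assert parse_repeatmasker_out(p).records[0].strand == "-"

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text("h1\nh2\n\nnot a valid line\n")
        with pytest.raises(ValueError, match=":4"):
            parse_repeatmasker_out(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text("h1\nh2\n\n")
        assert len(parse_repeatmasker_out(p)) == 0


class TestLandscape:
    def test_divergence_binning(self):
        ls = te_landscape(RepeatAnnotation([_rec("c", 0, 500, div=3.2)]))
        assert ls.table.at["Gypsy", 3] == 500
        assert ls.total_bp == 500

    def test_partial_cluster_overlap(self):
        annot = RepeatAnnotation([_rec("c", 0, 500, div=3.2)])
        ls = te_landscape(annot, scope_intervals=[("c", 250, 1000)])
        assert ls.table.at["Gypsy", 3] == 250

    def test_empty_annotation(self):
        ls = te_landscape(RepeatAnnotation([]))
        assert ls.total_bp == 0

    def test_bp_conservation_and_scope_monotonicity(self):
        rng = np.random.default_rng(6)
        records = [
            _rec("c", s, s + 100, fam, float(rng.uniform(0, 60)))
            for fam in ("Gypsy", "RTE")
            for s in rng.integers(0, 9900, size=20)
        ]
        annot = RepeatAnnotation(records)
        genome_ls = te_landscape(annot)
        cluster_ls = te_landscape(annot, scope_intervals=[("c", 2000, 5000)])
        for fam in ("Gypsy", "RTE"):
            fam_bp = sum(r.length for r in records if r.repeat_family == fam)
            assert genome_ls.family_totals[fam] == fam_bp
            assert cluster_ls.family_totals[fam] <= fam_bp

    def test_overlap_matches_per_base_oracle(self):
        rng = np.random.default_rng(9)
        scope = [("c", 100, 400), ("c", 600, 900)]
        covered = np.zeros(2000, dtype=bool)
        for _, s, e in scope:
            covered[s:e] = True
        annot = RepeatAnnotation(
            [
                _rec("c", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 1800, 50), rng.integers(10, 200, 50)
                )
            ]
        )
        ls = te_landscape(annot, scope_intervals=scope)
        oracle = sum(int(covered[r.start : r.end].sum()) for r in annot.records)
        assert ls.total_bp == oracle


class TestEnrichment:
    def test_fold_arithmetic(self):
        # family at 2% of genome and 16% of cluster bp -> fold 8
        clusters = [PiRNACluster("c", 0, 10_000)]
        records = [_rec("c", 0, 1600)]  # 1600/10000 of cluster
        records += [_rec("c", 20_000 + i * 1000, 20_000 + i * 1000 + 50)
                    for i in range(8)]  # 400 bp outside
        et = enrichment_fold(RepeatAnnotation(records), clusters, 100_000)
        row = et.table.loc["Gypsy"]
        assert row["genome_fraction"] == pytest.approx(0.02)
        assert row["cluster_fraction"] == pytest.approx(0.16)
        assert row["fold"] == pytest.approx(8.0)

    def test_family_absent_from_clusters(self):
        clusters = [PiRNACluster("c", 0, 1000)]
        et = enrichment_fold(
            RepeatAnnotation([_rec("c", 5000, 5400)]), clusters, 10_000
        )
        assert et.table.loc["Gypsy", "fold"] == 0.0

    def test_nested_hits_do_not_double_count_fractions(self):
        clusters = [PiRNACluster("c", 0, 1000)]
        records = [_rec("c", 100, 500), _rec("c", 200, 400)]
        et = enrichment_fold(RepeatAnnotation(records), clusters, 10_000)
        assert et.table.loc["Gypsy", "cluster_fraction"] == pytest.approx(0.4)

    def test_planted_enrichment_recovered(self):
        cfg = SimulationConfig(
            seed=51,
            te_families=[
                __import__("pirnakit.synthetic", fromlist=["TEFamily"]).TEFamily(
                    "hATw", 0.01, 20.0, 5.0
                )
            ],
            cluster_length_range=(3000, 5000),
        )
        genome, annot, truth = simulate_genome(cfg)
        clusters = [PiRNACluster(c, s, e) for c, s, e, _ in truth.clusters]
        et = enrichment_fold(annot, clusters, genome.total_length)
        assert et.table.loc["hATw", "fold"] == pytest.approx(20.0, rel=0.1)


class TestGeneContent:
    def _gff(self, tmp_path, features):
        p = tmp_path / "g.gff3"
        with open(p, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, s, e, ftype in features:
                fh.write(
                    f"{chrom}\tsrc\t{ftype}\t{s + 1}\t{e}\t.\t+\t0\tID=x\n"
                )
        return p

    def test_fraction_arithmetic(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 500, 670, "CDS")])
        df, agg = gene_content([PiRNACluster("c", 0, 10_000)], gff)
        assert agg == pytest.approx(0.017)

    def test_no_overlap(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 50_000, 51_000, "CDS")])
        _, agg = gene_content([PiRNACluster("c", 0, 10_000)], gff)
        assert agg == 0.0

    def test_cds_containing_cluster(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 0, 5000, "CDS")])
        df, agg = gene_content([PiRNACluster("c", 1000, 2000)], gff)
        assert agg == pytest.approx(1.0)

    def test_gff_without_cds_warns(self, tmp_path):
        gff = self._gff(tmp_path, [("c", 0, 500, "exon")])
        with pytest.warns(UserWarning):
            _, agg = gene_content([PiRNACluster("c", 0, 1000)], gff)
        assert agg == 0.0
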