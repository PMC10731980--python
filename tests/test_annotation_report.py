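"""Region classification, intolerance calls and pipeline assembly."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

import mamutspec as m
from mamutspec import io_formats as iof
from mamutspec.annotation_report import (
    REGIONS, RegionCall, annotate_singletons, classify_region, intolerance,
    region_summary, run_pipeline,
)
from mamutspec.ma_simulator import emit_cohort, simulate_cohort
from mamutspec.singleton_filter import SingletonSet

from test_indel_spectrum import Row


GFF = (
    "##gff-version 3\n"
    "c1\t.\tgene\t100\t1000\t.\t+\t.\tID=g1\n"
    "c1\t.\tfive_prime_UTR\t100\t149\t.\t+\t.\tParent=g1\n"
    "c1\t.\texon\t100\t400\t.\t+\t.\tParent=g1\n"
    "c1\t.\tCDS\t150\t400\t.\t+\t0\tParent=g1\n"
    "c1\t.\texon\t600\t800\t.\t+\t.\tParent=g1\n"
    "c1\t.\tCDS\t600\t700\t.\t+\t0\tParent=g1\n"
    "c1\t.\tthree_prime_UTR\t701\t800\t.\t+\t.\tParent=g1\n"
)


@pytest.fixture
def gff_index(tmp_path):
    p = tmp_path / "ann.gff3"
    p.write_text(GFF)
    return iof.read_gff(p, known_contigs=["c1"])


class TestClassifyRegion:
    @pytest.mark.parametrize("pos,region,coding", [
        (200, "exon", True),     # inside CDS
        (120, "UTR", False),     # 5' UTR
        (500, "intron", False),  # in gene, outside exons
        (50, "intergenic", False),
        (750, "UTR", False),     # 3' UTR
    ])
    def test_snv_calls(self, gff_index, pos, region, coding):
        call = classify_region(gff_index, Row("c1", pos, "A", "G"))
        assert (call.region, call.coding) == (region, coding)
        if region != "intergenic":
            assert call.gene_id == "g1"

    def test_indel_classified_by_interval_overlap(self, gff_index):
        # deletion anchored just before the CDS, spanning into it
        call = classify_region(gff_index, Row("c1", 148, "AAAA", "A"))
        assert call.region == "exon" and call.coding

    def test_matches_naive_scan_on_random_positions(self, tmp_path):
        rng = np.random.default_rng(13)
        feats = []
        lines = ["##gff-version 3"]
        for i in range(60):
            s = int(rng.integers(1, 8000))
            e = s + int(rng.integers(10, 600))
            feats.append(("gene", s, e))
            lines.append(f"c1\t.\tgene\t{s}\t{e}\t.\t+\t.\tID=g{i}")
            cs = s + int(rng.integers(0, min(100, e - s)))
            ce = min(e, cs + int(rng.integers(10, 200)))
            feats.append(("CDS", cs, ce))
            lines.append(f"c1\t.\tCDS\t{cs}\t{ce}\t.\t+\t.\tParent=g{i}")
            if rng.random() < 0.5:
                us, ue = s, min(e, s + 30)
                feats.append(("five_prime_UTR", us, ue))
                lines.append(f"c1\t.\tfive_prime_UTR\t{us}\t{ue}\t.\t+\t.\tParent=g{i}")
        p = tmp_path / "r.gff3"
        p.write_text("\n".join(lines) + "\n")
        idx = iof.read_gff(p, known_contigs=["c1"])
        for _ in range(1000):
            q = int(rng.integers(1, 9000))
            overlapping = {t for (t, s, e) in feats if s <= q <= e}
            if "CDS" in overlapping:
                expect = ("exon", True)
            elif "five_prime_UTR" in overlapping:
                expect = ("UTR", False)
            elif "gene" in overlapping:
                expect = ("intron", False)
            else:
                expect = ("intergenic", False)
            call = classify_region(idx, Row("c1", q, "A", "G"))
            assert (call.region, call.coding) == expect


class TestIntolerance:
    def test_sift_threshold_is_strict(self):
        snv = Row("c1", 5, "A", "G")
        rc = RegionCall("exon", True, "g1")
        assert intolerance(snv, rc, 0.04).intolerant
        assert intolerance(snv, rc, 0.04).basis == "sift_score"
        assert not intolerance(snv, rc, 0.05).intolerant
        assert not intolerance(snv, rc, None).intolerant

    def test_coding_indel_intolerant_without_score(self):
        indel = Row("c1", 5, "AT", "A")
        call = intolerance(indel, RegionCall("exon", True, "g1"))
        assert call.intolerant and call.basis == "coding_indel"
        noncoding = intolerance(indel, RegionCall("intron", False, "g1"))
        assert not noncoding.intolerant

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            intolerance(Row("c1", 5, "A", "G"),
                        RegionCall("exon", True, "g1"), 1.2)


class TestRegionSummary:
    def test_percentages_sum_to_100(self, gff_index):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(200):
            pos = int(rng.integers(1, 1200))
            rows.append(("c1", pos, "A", "G", "SNV", 0, "L1", "CK",
                         "heterozygous"))
        df = pd.DataFrame(rows, columns=[
            "contig", "pos", "ref", "alt", "vtype", "size", "line", "group",
            "zygosity"]).drop_duplicates(["contig", "pos"])
        s = SingletonSet(df, ["L1"], {"L1": "CK"})
        ann = annotate_singletons(s, gff_index)
        tab = region_summary(ann, s.groups)
        for g in ("all", "CK"):
            total = tab[tab["group"] == g]["pct"].sum()
            assert total == pytest.approx(100.0, abs=0.01)


@pytest.fixture(scope="module")
def sim_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    cfg = m.SimulationConfig(
        genome_length=100_000, n_contigs=2, n_lines_per_group=5,
        groups=("CK", "M33"), germline_variant_count=60, snv_rate=2.5e-6,
        indel_rate=6e-7, seed=21,
    )
    return emit_cohort(simulate_cohort(cfg), out)


class TestPipeline:
    def test_reports_reproducible(self, sim_paths, tmp_path):
        a = tmp_path / "a"
        b = tmp_path / "b"
        for out in (a, b):
            run_pipeline(sim_paths["vcf"], sim_paths["reference"],
                         sim_paths["groups"], out, seed=1)
        for f in sorted(a.iterdir()):
            assert filecmp.cmp(f, b / f.name, shallow=False), f.name

    def test_manifest_records_inputs_and_counts(self, sim_paths, tmp_path):
        man = run_pipeline(sim_paths["vcf"], sim_paths["reference"],
                           sim_paths["groups"], tmp_path / "r", seed=2)
        assert man["counts"]["singletons"] > 0
        assert man["counts"]["loci_raw"] >= man["counts"]["loci_filtered"]
        written = json.loads((tmp_path / "r" / "manifest.json").read_text())
        assert written["counts"] == man["counts"]
        assert written["inputs"]["reference"]["sha256"]

    def test_missing_gff_degrades_with_note(self, sim_paths, tmp_path):
        man = run_pipeline(sim_paths["vcf"], sim_paths["reference"],
                           sim_paths["groups"], tmp_path / "nogff")
        assert any("region stage skipped" in n for n in man["notes"])
        assert not (tmp_path / "nogff" / "regions.tsv").exists()

    def test_gff_and_sift_stages(self, sim_paths, tmp_path):
        # annotation over the simulated genome: one gene per contig
        genome = iof.read_reference(sim_paths["reference"])
        gff_lines = ["##gff-version 3"]
        for name, seq in genome.contigs.items():
            L = len(seq)
            gff_lines.append(f"{name}\t.\tgene\t1000\t{L // 2}\t.\t+\t.\tID={name}.g")
            gff_lines.append(
                f"{name}\t.\tCDS\t2000\t{L // 4}\t.\t+\t0\tParent={name}.g")
        gff = tmp_path / "sim.gff3"
        gff.write_text("\n".join(gff_lines) + "\n")
        # SIFT scores for a few singleton SNVs
        pre = run_pipeline(sim_paths["vcf"], sim_paths["reference"],
                           sim_paths["groups"], tmp_path / "pre")
        singles = iof.read_singletons(tmp_path / "pre" / "singletons.tsv")
        snvs = singles[singles["vtype"] == "SNV"].head(10)
        sift = tmp_path / "sift.tsv"
        sift_df = pd.DataFrame({
            "contig": snvs["contig"], "pos": snvs["pos"], "alt": snvs["alt"],
            "score": [0.01 if i % 2 == 0 else 0.5
                      for i in range(len(snvs))],
        })
        sift_df.to_csv(sift, sep="\t", index=False)
        man = run_pipeline(sim_paths["vcf"], sim_paths["reference"],
                           sim_paths["groups"], tmp_path / "full",
                           gff=gff, sift=sift)
        assert "regions" in man["tables"] and "intolerance" in man["tables"]
        reg = pd.read_csv(tmp_path / "full" / "regions.tsv", sep="\t")
        assert set(reg["region"]) == set(REGIONS)
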