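"""Substitution classes, spectrum invariants, flanks and context matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mamutspec as m
from mamutspec.singleton_filter import SingletonSet
from mamutspec.snv_spectrum import (
    BASES, SUBSTITUTION_CLASSES, TRANSITION_CLASSES, ContextMatrix,
    chromosome_distribution, context_frequency_matrix, extract_flanks,
    spectrum_table, substitution_class, transition_fraction_per_line,
)


class TestSubstitutionClass:
    def test_exhaustive_labels(self):
        purines, pyrimidines = set("AG"), set("CT")
        for ref, alt in itertools.permutations(BASES, 2):
            c = substitution_class(ref, alt)
            assert c.label == f"{ref}>{alt}"
            same_family = (
                (ref in purines and alt in purines)
                or (ref in pyrimidines and alt in pyrimidines)
            )
            assert c.is_transition == same_family
            if ref in purines and alt in purines:
                assert c.category == "pur>pur"
            elif ref in pyrimidines and alt in pyrimidines:
                assert c.category == "pyr>pyr"
            else:
                assert c.category == "cross"
        assert len(SUBSTITUTION_CLASSES) == 12
        assert len(TRANSITION_CLASSES) == 4

    @pytest.mark.parametrize("ref,alt", [("N", "A"), ("A", "A"), ("A", "N")])
    def test_invalid_inputs(self, ref, alt):
        with pytest.raises(ValueError):
            substitution_class(ref, alt)


def _snv_set(class_counts, line="L1", group="CK", lines=None, groups=None):
    rows = []
    pos = 0
    for label, n in class_counts.items():
        ref, alt = label[0], label[2]
        for _ in range(n):
            pos += 10
            rows.append(("c1", pos, ref, alt, "SNV", 0, line, group,
                         "heterozygous"))
    df = pd.DataFrame(rows, columns=[
        "contig", "pos", "ref", "alt", "vtype", "size", "line", "group",
        "zygosity"])
    if lines is None:
        lines, groups = [line], {line: group}
    return SingletonSet(df, lines, groups)


class TestSpectrumTable:
    def test_single_transition_is_100_percent(self):
        s = _snv_set({"C>T": 1})
        spec = spectrum_table(s)
        sub = spec.subtotals()
        assert sub.loc["transitions", "all"] == 1
        assert sub.loc["transversions", "all"] == 0
        assert spec.percentages().loc["C>T", "all"] == 100.0

    def test_conservation_identities(self):
        rng = np.random.default_rng(12)
        counts = {c: int(rng.integers(0, 30)) for c in SUBSTITUTION_CLASSES}
        spec = spectrum_table(_snv_set(counts))
        sub = spec.subtotals()
        assert sub.loc["total", "all"] == sum(counts.values())
        assert (sub.loc["transitions", "all"] + sub.loc["transversions", "all"]
                == sub.loc["total", "all"])
        assert sub.loc["pyr>pyr", "all"] == counts["C>T"] + counts["T>C"]
        assert sub.loc["pur>pur", "all"] == counts["A>G"] + counts["G>A"]


class TestTransitionFractions:
    def test_half_and_all(self):
        s = _snv_set({"C>T": 2, "A>C": 2})
        fr, excluded = transition_fraction_per_line(s)
        assert fr["L1"] == 0.5 and excluded == []
        s2 = _snv_set({"A>G": 3})
        fr2, _ = transition_fraction_per_line(s2)
        assert fr2["L1"] == 1.0

    def test_zero_snv_line_excluded(self):
        s = _snv_set({"C>T": 2}, lines=["L1", "L2"],
                     groups={"L1": "CK", "L2": "CK"})
        fr, excluded = transition_fraction_per_line(s)
        assert "L2" not in fr.index and excluded == ["L2"]

    def test_group_mean_matches_pooled_recount(self):
        rng = np.random.default_rng(4)
        lines = [f"L{i}" for i in range(6)]
        groups = {ln: "CK" for ln in lines}
        rows = []
        pos = 0
        for ln in lines:
            for _ in range(int(rng.integers(3, 12))):
                pos += 10
                label = SUBSTITUTION_CLASSES[int(rng.integers(0, 12))]
                rows.append(("c1", pos, label[0], label[2], "SNV", 0, ln,
                             "CK", "heterozygous"))
        df = pd.DataFrame(rows, columns=[
            "contig", "pos", "ref", "alt", "vtype", "size", "line", "group",
            "zygosity"])
        s = SingletonSet(df, lines, groups)
        fr, _ = transition_fraction_per_line(s, "CK")
        manual = {
            ln: np.mean([
                (r.ref + ">" + r.alt) in TRANSITION_CLASSES
                for r in df[df["line"] == ln].itertuples()
            ])
            for ln in lines
        }
        for ln in lines:
            assert fr[ln] == pytest.approx(manual[ln])


class TestExtractFlanks:
    def test_exact_slice(self, tiny_genome):
        # genome AAACGTAAAAA: positions 4-8 around pos 6 with k=2
        assert extract_flanks(tiny_genome, "c1", 6, k=2) == "CGTAA"

    def test_edge_site_excluded(self, tiny_genome):
        assert extract_flanks(tiny_genome, "c1", 2, k=5) is None
        with pytest.raises(IndexError):
            extract_flanks(tiny_genome, "c1", 99, k=2)

    def test_matches_naive_slicing(self):
        rng = np.random.default_rng(21)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        g = m.ReferenceGenome({"c1": seq})
        for _ in range(200):
            pos = int(rng.integers(1, 501))
            k = int(rng.integers(1, 7))
            got = extract_flanks(g, "c1", pos, k)
            if pos - k < 1 or pos + k > 500:
                assert got is None
            else:
                assert got == seq[pos - k - 1: pos + k]


class TestContextMatrix:
    def test_single_site_indicator(self, tiny_genome):
        s = _snv_set({"C>T": 0})
        df = pd.DataFrame(
            [("c1", 6, "G", "A", "SNV", 0, "L1", "CK", "heterozygous")],
            columns=["contig", "pos", "ref", "alt", "vtype", "size", "line",
                     "group", "zygosity"])
        s = SingletonSet(df, ["L1"], {"L1": "CK"})
        cm = context_frequency_matrix(s, tiny_genome, k=2)
        assert cm.n_sites == 1
        # flanks CGTAA: one-hot rows
        assert cm.freqs.loc[-2, "C"] == 1.0
        assert cm.freqs.loc[0, "T"] == 1.0
        assert np.allclose(cm.freqs.sum(axis=1), 1.0)

    def test_position_zero_matches_subset(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
        g = m.ReferenceGenome({"c1": seq})
        rows = []
        for _ in range(100):
            pos = int(rng.integers(10, 1990))
            ref = seq[pos - 1]
            alt = next(b for b in "ACGT" if b != ref)
            rows.append(("c1", pos, ref, alt, "SNV", 0, "L1", "CK",
                         "heterozygous"))
        df = pd.DataFrame(rows, columns=[
            "contig", "pos", "ref", "alt", "vtype", "size", "line", "group",
            "zygosity"]).drop_duplicates(["contig", "pos"])
        s = SingletonSet(df, ["L1"], {"L1": "CK"})
        for base in "ACGT":
            if (df["ref"] == base).sum() == 0:
                continue
            cm = context_frequency_matrix(s, g, mutated_base=base)
            assert cm.freqs.loc[0, base] == pytest.approx(1.0)
            assert np.allclose(cm.freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_consensus_tie_flagged(self):
        freqs = pd.DataFrame(
            {"A": [0.5, 0.1], "C": [0.5, 0.2], "G": [0.0, 0.3],
             "T": [0.0, 0.4]}, index=[-1, 1])
        cm = ContextMatrix(freqs, 10, 0, "test")
        cons, maxima, ties = cm.consensus([-1, 1])
        assert cons == "AT"  # lexicographic winner at the tied position
        assert ties == [-1]


class TestChromosomeDistribution:
    def test_totals_conserved_and_zero_contigs(self):
        g = m.ReferenceGenome({"c1": "A" * 100, "c2": "A" * 100,
                               "c3": "A" * 100})
        lines = ["L1", "L2", "L3", "L4"]
        groups = {"L1": "CK", "L2": "CK", "L3": "T", "L4": "T"}
        rows = [("c1", 10 * (i + 1), "A", "G", "SNV", 0,
                 lines[i % 4], groups[lines[i % 4]], "heterozygous")
                for i in range(8)]
        df = pd.DataFrame(rows, columns=[
            "contig", "pos", "ref", "alt", "vtype", "size", "line", "group",
            "zygosity"])
        s = SingletonSet(df, lines, groups)
        tab = chromosome_distribution(s, g).set_index("contig")
        assert tab["total"].sum() == 8
        assert tab.loc["c2", "total"] == 0 and tab.loc["c3", "total"] == 0
        assert tab.loc["c2", "mean_CK"] == 0.0
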