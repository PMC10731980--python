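"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest

import mamutspec as m
from mamutspec.io_formats import HET, HOM_ALT, HOM_REF, MISSING, CohortTable


@pytest.fixture
def tiny_genome():
    return m.ReferenceGenome({"c1": "AAACGTAAAAA"})


def make_cohort(loci_rows, genotype_rows, lines, groups=None):
    """Build a CohortTable from explicit locus tuples and genotype codes."""
    if groups is None:
        groups = {ln: "G1" for ln in lines}
    loci = pd.DataFrame(loci_rows, columns=["contig", "pos", "ref", "alt"])
    return CohortTable(loci, np.array(genotype_rows, dtype=np.int8),
                       list(lines), dict(groups))


def random_cohort(rng, n_loci, n_lines, p_missing=0.1, p_het=0.15,
                  p_hom=0.05, n_groups=2, dup_pos_fraction=0.05):
    """Random genotype table, with a share of positions duplicated under a
    second alt allele to exercise the positional singleton rule."""
    lines = [f"L{i:02d}" for i in range(n_lines)]
    groups = {ln: f"G{i % n_groups}" for i, ln in enumerate(lines)}
    rows, genos = [], []
    seen = set()
    pos = 0
    alts = {"A": "G", "G": "A"}
    while len(rows) < n_loci:
        pos += int(rng.integers(1, 50))
        ref = "ACGT"[rng.integers(0, 4)]
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        key = ("c1", pos, ref, alt)
        if key in seen:
            continue
        seen.add(key)
        g = rng.choice(
            [MISSING, HOM_REF, HET, HOM_ALT], size=n_lines,
            p=[p_missing, 1 - p_missing - p_het - p_hom, p_het, p_hom],
        )
        rows.append(key)
        genos.append(g)
        if rng.random() < dup_pos_fraction:
            alt2 = next(b for b in "ACGT" if b not in (ref, alt))
            g2 = rng.choice(
                [MISSING, HOM_REF, HET, HOM_ALT], size=n_lines,
                p=[p_missing, 1 - p_missing - p_het - p_hom, p_het, p_hom],
            )
            rows.append(("c1", pos, ref, alt2))
            genos.append(g2)
    return make_cohort(rows, genos, lines, groups)


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and separate from the package)
# ---------------------------------------------------------------------------

def brute_force_filter_and_singletons(table, max_missing=0.20, max_het=0.20,
                                      het_denominator="non_missing"):
    """Per-locus recount of the filters and the positional singleton rule."""
    n = len(table.lines)
    kept = []
    for i in range(table.n_loci):
        row = [int(c) for c in table.genotypes[i]]
        n_missing = sum(1 for c in row if c == MISSING)
        n_het = sum(1 for c in row if c == HET)
        if het_denominator == "non_missing":
            het_frac = 0.0 if n_missing == n else n_het / (n - n_missing)
        else:
            het_frac = n_het / n
        if n_missing / n > max_missing or het_frac > max_het:
            continue
        kept.append(i)
    carriers_at_pos: dict[tuple, set[str]] = {}
    for i in kept:
        contig, pos, ref, alt = table.loci.iloc[i]
        for j, ln in enumerate(table.lines):
            if table.genotypes[i, j] in (HET, HOM_ALT):
                carriers_at_pos.setdefault((contig, pos), set()).add(ln)
    out = set()
    for i in kept:
        contig, pos, ref, alt = table.loci.iloc[i]
        carriers = [
            (table.lines[j], int(table.genotypes[i, j]))
            for j in range(n) if table.genotypes[i, j] in (HET, HOM_ALT)
        ]
        if len(carriers) != 1:
            continue
        if len(carriers_at_pos[(contig, pos)]) != 1:
            continue
        ln, code = carriers[0]
        zyg = "homozygous" if code == HOM_ALT else "heterozygous"
        out.add((contig, int(pos), ref, alt, ln, zyg))
    return kept, out


def oracle_homopolymer_adjacent(contig_seq, pos, ref, alt, min_run=4):
    """Regex scan for adjacent single-base runs (independent of the package)."""
    if len(alt) > len(ref):
        seq, left_end, right_start = alt[1:], pos, pos + 1
    else:
        seq, left_end, right_start = ref[1:], pos, pos + len(ref)
    left = contig_seq[max(0, left_end - 40):left_end]
    right = contig_seq[right_start - 1:right_start - 1 + 40]
    lm = re.search(r"(A+|C+|G+|T+)$", left)
    rm = re.match(r"(A+|C+|G+|T+)", right)
    lb, lrun = (lm.group(0)[0], len(lm.group(0))) if lm else ("", 0)
    rb, rrun = (rm.group(0)[0], len(rm.group(0))) if rm else ("", 0)
    if lrun >= min_run or rrun >= min_run:
        return True
    if seq and len(set(seq)) == 1:
        b = seq[0]
        if lb == b and lrun + len(seq) >= min_run:
            return True
        if rb == b and rrun + len(seq) >= min_run:
            return True
    return False


def oracle_repeat_adjacent(contig_seq, pos, ref, alt, unit_sizes=(2, 3),
                           min_copies=3):
    """Regex backreference scan for adjacent tandem repeats."""
    if len(alt) > len(ref):
        seq, left_end, right_start = alt[1:], pos, pos + 1
    else:
        seq, left_end, right_start = ref[1:], pos, pos + len(ref)
    left = contig_seq[max(0, left_end - 100):left_end]
    right = contig_seq[right_start - 1:right_start - 1 + 100]
    for u in unit_sizes:
        if re.search(r"([ACGT]{%d})\1{%d,}$" % (u, min_copies - 1), left):
            return True
        if re.match(r"([ACGT]{%d})\1{%d,}" % (u, min_copies - 1), right):
            return True
        if seq and len(seq) % u == 0:
            unit_l = left[-u:] if len(left) >= u else None
            if unit_l and seq == unit_l * (len(seq) // u):
                lm = re.search(r"(%s)+$" % re.escape(unit_l), left)
                copies = len(lm.group(0)) // u if lm else 0
                if copies + len(seq) // u >= min_copies:
                    return True
            unit_r = right[:u] if len(right) >= u else None
            if unit_r and seq == unit_r * (len(seq) // u):
                rm = re.match(r"(%s)+" % re.escape(unit_r), right)
                copies = len(rm.group(0)) // u if rm else 0
                if copies + len(seq) // u >= min_copies:
                    return True
    return False


def oracle_anova(arrays):
    """Textbook one-way ANOVA from sums of squares."""
    from scipy import stats
    all_vals = np.concatenate(arrays)
    gm = all_vals.mean()
    k = len(arrays)
    N = len(all_vals)
    ssb = sum(len(a) * (a.mean() - gm) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    p = stats.f.sf(F, k - 1, N - k)
    return F, p


def oracle_tukey_p(a, b, mse, df_within, n_groups):
    """Tukey–Kramer adjusted p for one pair from the studentized range."""
    from scipy import stats
    se = np.sqrt(mse / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
    q = abs(a.mean() - b.mean()) / se
    return stats.studentized_range.sf(q, n_groups, df_within)


def oracle_welch_t(a, b):
    """Welch's two-sided t-test from the closed form."""
    from scipy import stats
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return t, 2 * stats.t.sf(abs(t), df)
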