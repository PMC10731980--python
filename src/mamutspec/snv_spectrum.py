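"""Substitution spectrum, transition statistics and flanking-context matrices.

Single-base substitutions are kept as 12 directed, reference-strand classes
(A>C … T>G) with no reverse-complement collapsing, because C>T and G>A are
reported separately in MA studies.  Transitions are the purine↔purine
(A↔G) and pyrimidine↔pyrimidine (C↔T) classes; the other eight are
transversions.  Context analysis builds a position (−k…+k) × base relative
frequency matrix from the reference sequence around each mutated site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ReferenceGenome, VALID_BASES
from .singleton_filter import SingletonSet

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = ("A", "C", "G", "T")

#: The 12 directed substitution classes in fixed reporting order.
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)
TRANSITION_CLASSES = ("A>G", "G>A", "C>T", "T>C")


@dataclass(frozen=True)
class SubstitutionClass:
    label: str
    ref: str
    alt: str
    is_transition: bool
    category: str  # "pur>pur" | "pyr>pyr" | "cross"


def substitution_class(ref: str, alt: str) -> SubstitutionClass:
    """Label one substitution on the reference strand.

    Category is purine-to-purine, pyrimidine-to-pyrimidine, or cross
    (purine↔pyrimidine); the first two are exactly the transitions.
    """
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValueError(f"bases must be ACGT, got ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in PURINES and alt in PURINES:
        cat, ts = "pur>pur", True
    elif ref in PYRIMIDINES and alt in PYRIMIDINES:
        cat, ts = "pyr>pyr", True
    else:
        cat, ts = "cross", False
    return SubstitutionClass(f"{ref}>{alt}", ref, alt, ts, cat)


@dataclass
class SpectrumSummary:
    """12-class counts per scope (group or 'all') with derived subtotals."""

    counts: pd.DataFrame  # index = SUBSTITUTION_CLASSES, columns = scopes

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def percentages(self) -> pd.DataFrame:
        tot = self.totals.replace(0, np.nan)
        return (100.0 * self.counts / tot).round(2)

    def subtotals(self) -> pd.DataFrame:
        """Transitions/transversions and pur>pur / pyr>pyr totals per scope."""
        ts = self.counts.loc[list(TRANSITION_CLASSES)].sum(axis=0)
        tv = self.totals - ts
        pur = self.counts.loc[["A>G", "G>A"]].sum(axis=0)
        pyr = self.counts.loc[["C>T", "T>C"]].sum(axis=0)
        return pd.DataFrame(
            {"transitions": ts, "transversions": tv,
             "pur>pur": pur, "pyr>pyr": pyr, "total": self.totals}
        ).T


def spectrum_table(s: SingletonSet, by_group: bool = True) -> SpectrumSummary:
    """Count the 12 substitution classes overall and per treatment group.

    Only SNV records contribute; a group with zero SNVs yields a zero column.
    """
    snv = s.df[s.df["vtype"] == "SNV"]
    scopes = ["all"] + (s.groups if by_group else [])
    counts = pd.DataFrame(0, index=list(SUBSTITUTION_CLASSES), columns=scopes)
    labels = snv["ref"] + ">" + snv["alt"]
    counts["all"] = labels.value_counts().reindex(counts.index, fill_value=0)
    if by_group:
        for g in s.groups:
            lab = labels[snv["group"] == g]
            counts[g] = lab.value_counts().reindex(counts.index, fill_value=0)
    return SpectrumSummary(counts)


def transition_fraction_per_line(
    s: SingletonSet, group: str | None = None
) -> tuple[pd.Series, list[str]]:
    """Per-line transitions/SNVs fraction.

    Lines with zero SNVs have no defined fraction; they are excluded from
    the returned series and reported in the second return value.
    """
    snv = s.df[s.df["vtype"] == "SNV"]
    lines = s.lines if group is None else s.lines_in_group(group)
    if group is not None:
        snv = snv[snv["group"] == group]
    is_ts = (snv["ref"] + ">" + snv["alt"]).isin(TRANSITION_CLASSES)
    per_line_total = snv.groupby("line").size()
    per_line_ts = snv[is_ts].groupby("line").size()
    fractions = {}
    excluded = []
    for ln in lines:
        tot = int(per_line_total.get(ln, 0))
        if tot == 0:
            excluded.append(ln)
        else:
            fractions[ln] = float(per_line_ts.get(ln, 0)) / tot
    return pd.Series(fractions, dtype=float), excluded


def extract_flanks(genome: ReferenceGenome, contig: str, pos: int, k: int = 5
                   ) -> str | None:
    """Reference-strand (2k+1)-mer centered on 1-based ``pos``.

    Returns ``None`` for sites closer than ``k`` to a contig end (such
    sites are excluded from context matrices and tallied separately).
    A position off the contig raises IndexError.
    """
    seq = genome.contigs.get(contig)
    if seq is None:
        raise KeyError(contig)
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside contig {contig!r}")
    if pos - k < 1 or pos + k > len(seq):
        return None
    return seq[pos - k - 1: pos + k]


@dataclass
class ContextMatrix:
    """Position × base relative-frequency matrix around mutated sites.

    ``freqs`` is indexed by relative position (−k…+k, 0 = the mutated
    site) with columns A/C/G/T; every row sums to 1.  ``subset`` records
    what the matrix conditions on (e.g. ``"ref=C"``, group label).
    """

    freqs: pd.DataFrame
    n_sites: int
    n_edge_excluded: int
    subset: str

    def consensus(self, positions: list[int] | None = None
                  ) -> tuple[str, dict[int, float], list[int]]:
        """Most frequent base per position (ties broken lexicographically).

        Returns the consensus string for ``positions`` (default: all
        positions except 0), the per-position max frequency, and the list
        of positions where the maximum was tied.
        """
        if positions is None:
            positions = [p for p in self.freqs.index if p != 0]
        chars, maxima, ties = [], {}, []
        for p in positions:
            row = self.freqs.loc[p]
            m = row.max()
            best = sorted(b for b in BASES if row[b] == m)
            chars.append(best[0])
            maxima[p] = float(m)
            if len(best) > 1:
                ties.append(p)
        return "".join(chars), maxima, ties


def context_frequency_matrix(
    s: SingletonSet,
    genome: ReferenceGenome,
    mutated_base: str | None = None,
    group: str | None = None,
    k: int = 5,
) -> ContextMatrix:
    """Build the flanking-base frequency matrix for a subset of SNV sites.

    ``mutated_base`` restricts to sites whose reference base matches (so
    the position-0 row is that base with frequency 1).  Flanks are taken
    on the reference (+) strand for every site.  Sites within ``k`` of a
    contig end are excluded and counted in ``n_edge_excluded``.
    """
    snv = s.df[s.df["vtype"] == "SNV"]
    parts = []
    if mutated_base is not None:
        snv = snv[snv["ref"] == mutated_base]
        parts.append(f"ref={mutated_base}")
    if group is not None:
        snv = snv[snv["group"] == group]
        parts.append(f"group={group}")
    if snv.empty:
        raise ValueError(f"empty SNV subset ({', '.join(parts) or 'all'})")
    positions = list(range(-k, k + 1))
    counts = np.zeros((2 * k + 1, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    n_sites = 0
    n_edge = 0
    for row in snv.itertuples():
        flank = extract_flanks(genome, row.contig, int(row.pos), k)
        if flank is None:
            n_edge += 1
            continue
        usable = True
        for i, ch in enumerate(flank):
            if ch not in base_idx:
                usable = False  # N in flank: skip the whole site
                break
        if not usable:
            n_edge += 1
            continue
        for i, ch in enumerate(flank):
            counts[i, base_idx[ch]] += 1
        n_sites += 1
    if n_sites == 0:
        raise ValueError("no usable sites (all edge-excluded)")
    freqs = pd.DataFrame(counts / n_sites, index=positions, columns=list(BASES))
    return ContextMatrix(freqs, n_sites, n_edge, ", ".join(parts) or "all")


def chromosome_distribution(
    s: SingletonSet, genome: ReferenceGenome, vtype: str | None = "SNV"
) -> pd.DataFrame:
    """Per-contig, per-line mean counts by group, with a cross-group ANOVA p.

    Contigs with zero variants are reported as 0 for every line.  The
    ANOVA compares per-line counts across groups independently per contig;
    the p-value is NaN when every line has the same count.
    """
    sub = s if vtype is None else s.subset(vtype=vtype)
    df = sub.df
    counts = pd.DataFrame(0, index=list(genome.contigs), columns=s.lines)
    if len(df):
        tab = df.groupby(["contig", "line"]).size()
        for (contig, line), n in tab.items():
            counts.loc[contig, line] = n
    rows = []
    for contig in counts.index:
        row = {"contig": contig}
        samples = []
        for g in s.groups:
            vals = counts.loc[contig, s.lines_in_group(g)].to_numpy(dtype=float)
            row[f"mean_{g}"] = round(float(vals.mean()), 2) if len(vals) else np.nan
            samples.append(vals)
        if len(samples) >= 2 and all(len(v) >= 2 for v in samples):
            pooled = np.concatenate(samples)
            if np.ptp(pooled) == 0:
                row["anova_p"] = np.nan
            else:
                row["anova_p"] = float(stats.f_oneway(*samples).pvalue)
        else:
            row["anova_p"] = np.nan
        row["total"] = int(counts.loc[contig].sum())
        rows.append(row)
    return pd.DataFrame(rows)
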