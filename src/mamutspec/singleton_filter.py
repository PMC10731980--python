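"""Locus-level quality filters and singleton (unique-site) selection.

In a mutation-accumulation cohort, variants present in the founder seed
stock appear in several lines, while a genuine de novo mutation is private
to one line.  The filtering stage therefore (1) drops low-quality loci —
those with too many missing calls or too much cohort-wide heterozygosity —
and (2) keeps only loci at which exactly one line carries a non-reference
genotype ("singletons"), the working proxy for heritable de novo mutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io_formats as iof
from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CohortTable,
    VariantRecord,
    variant_type,
)

__all__ = [
    "FilterConfig",
    "SingletonSet",
    "apply_locus_filters",
    "select_singletons",
    "classify_variant_type",
    "summarize_singletons",
]


def classify_variant_type(ref: str, alt: str) -> tuple[str, int]:
    """Classify anchor-form alleles as ``("SNV"|"INS"|"DEL", size)``.

    SNV size is 0; InDel size is the allele-length difference.  MNPs and
    symbolic alleles raise :class:`~mamutspec.errors.UnsupportedVariantError`.
    """
    return variant_type(ref, alt)


@dataclass(frozen=True)
class FilterConfig:
    """Locus-level filter thresholds.

    Both comparisons are strict ("greater than"): a locus is dropped when
    its missing-call fraction exceeds ``max_missing_fraction`` or its
    heterozygous-call fraction exceeds ``max_het_fraction``.  The missing
    fraction is computed over all lines; the het fraction over non-missing
    calls by default (``het_denominator="non_missing"``), or over all lines
    with ``het_denominator="all"``.
    """

    max_missing_fraction: float = 0.20
    max_het_fraction: float = 0.20
    het_denominator: str = "non_missing"  # or "all"
    allele_aware: bool = False  # singleton uniqueness on (contig,pos,ref,alt)

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "max_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if self.het_denominator not in ("non_missing", "all"):
            raise ConfigError(f"bad het_denominator {self.het_denominator!r}")


@dataclass
class SingletonSet:
    """Line-private variants surviving the filters, plus cohort context.

    ``df`` carries one row per singleton with columns
    contig, pos, ref, alt, vtype, size, line, group, zygosity.
    The full line list (including lines with zero singletons) and the
    line → group map are retained so per-line statistics can include zeros.
    """

    df: pd.DataFrame
    lines: list[str]
    line_groups: dict[str, str]
    #: under positional uniqueness (the default) no two records may share a
    #: position across lines; allele-aware selection relaxes this
    positional_unique: bool = True

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        missing = [c for c in iof.SINGLETON_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"singleton frame missing columns {missing}")
        bad_lines = set(self.df["line"]) - set(self.lines)
        if bad_lines:
            raise ValueError(f"singleton rows for unknown lines {sorted(bad_lines)}")
        if self.positional_unique and len(self.df):
            dup = self.df.groupby(["contig", "pos"])["line"].nunique()
            if (dup > 1).any():
                raise ValueError(
                    "two singleton records share (contig,pos) across lines"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for ln in self.lines:
            g = self.line_groups[ln]
            if g not in seen:
                seen.append(g)
        return seen

    def lines_in_group(self, group: str) -> list[str]:
        return [ln for ln in self.lines if self.line_groups[ln] == group]

    def subset(self, vtype: str | None = None, group: str | None = None,
               predicate: Callable[[pd.Series], bool] | None = None) -> "SingletonSet":
        df = self.df
        if vtype == "InDel":
            df = df[df["vtype"].isin(["INS", "DEL"])]
        elif vtype is not None:
            df = df[df["vtype"] == vtype]
        if group is not None:
            df = df[df["group"] == group]
        if predicate is not None:
            df = df[df.apply(predicate, axis=1)]
        return SingletonSet(df.reset_index(drop=True), list(self.lines),
                            dict(self.line_groups), self.positional_unique)

    def snvs(self) -> "SingletonSet":
        return self.subset(vtype="SNV")

    def indels(self) -> "SingletonSet":
        return self.subset(vtype="InDel")

    @property
    def records(self) -> list[VariantRecord]:
        return [
            VariantRecord(r.contig, int(r.pos), r.ref, r.alt, r.line,
                          r.zygosity, r.group)
            for r in self.df.itertuples()
        ]

    @classmethod
    def from_tsv(cls, path, lines: Iterable[str] | None = None,
                 line_groups: dict[str, str] | None = None) -> "SingletonSet":
        df = iof.read_singletons(path)
        if line_groups is None:
            line_groups = dict(zip(df["line"], df["group"]))
        if lines is None:
            lines = list(line_groups)
        return cls(df, list(lines), dict(line_groups))


def locus_fractions(table: CohortTable, cfg: FilterConfig | None = None
                    ) -> pd.DataFrame:
    """Per-locus missing and heterozygous fractions, as the filter sees them."""
    cfg = cfg or FilterConfig()
    gt = table.genotypes
    n = table.n_lines
    n_missing = (gt == MISSING).sum(axis=1)
    n_het = (gt == HET).sum(axis=1)
    missing_frac = n_missing / n
    if cfg.het_denominator == "non_missing":
        denom = np.maximum(n - n_missing, 1)
        het_frac = np.where(n_missing == n, 0.0, n_het / denom)
    else:
        het_frac = n_het / n
    return pd.DataFrame({"missing_fraction": missing_frac, "het_fraction": het_frac})


def apply_locus_filters(table: CohortTable, cfg: FilterConfig | None = None
                        ) -> CohortTable:
    """Drop loci exceeding the missing-call or heterozygosity thresholds.

    Comparisons are strict, so a locus at exactly the threshold is kept.
    Locus order is preserved; an empty result is allowed.
    """
    cfg = cfg or FilterConfig()
    fr = locus_fractions(table, cfg)
    keep = (
        (fr["missing_fraction"].to_numpy() <= cfg.max_missing_fraction)
        & (fr["het_fraction"].to_numpy() <= cfg.max_het_fraction)
    )
    return table.subset_loci(keep)


_ZYGOSITY = {HET: "heterozygous", HOM_ALT: "homozygous"}


def select_singletons(table: CohortTable, cfg: FilterConfig | None = None
                      ) -> SingletonSet:
    """Keep loci at which exactly one line carries a non-reference genotype.

    Uniqueness is positional by default: if two lines carry different alt
    alleles at the same (contig, pos), both loci are disqualified.  With
    ``cfg.allele_aware=True`` uniqueness is judged per (contig,pos,ref,alt)
    instead.  The owning line's genotype sets the zygosity.
    """
    cfg = cfg or FilterConfig()
    gt = table.genotypes
    carrier_mask = (gt == HET) | (gt == HOM_ALT)

    loci = table.loci
    rows = []
    if cfg.allele_aware:
        eligible = carrier_mask.sum(axis=1) == 1
        idx_iter = np.flatnonzero(eligible)
    else:
        # carriers pooled per position across split alt alleles
        pos_key = list(zip(loci["contig"], loci["pos"]))
        carriers_by_pos: dict[tuple, set[int]] = {}
        for i, key in enumerate(pos_key):
            cols = np.flatnonzero(carrier_mask[i])
            carriers_by_pos.setdefault(key, set()).update(cols.tolist())
        idx_iter = [
            i for i, key in enumerate(pos_key)
            if len(carriers_by_pos[key]) == 1 and carrier_mask[i].sum() == 1
        ]
    for i in idx_iter:
        j = int(np.flatnonzero(carrier_mask[i])[0])
        line = table.lines[j]
        contig, pos, ref, alt = loci.iloc[i]
        vt, size = classify_variant_type(ref, alt)
        rows.append((contig, int(pos), ref, alt, vt, size, line,
                     table.line_groups[line], _ZYGOSITY[int(gt[i, j])]))
    df = pd.DataFrame(rows, columns=iof.SINGLETON_COLUMNS)
    return SingletonSet(df, list(table.lines), dict(table.line_groups),
                        positional_unique=not cfg.allele_aware)


def summarize_singletons(s: SingletonSet, per_group: bool = True) -> pd.DataFrame:
    """Counts and 2-decimal percentages by variant type and zygosity.

    Returns a tidy frame with columns group, category, class, count, pct.
    Variant-type percentages partition 100% of the group's singletons, as
    do zygosity percentages.  An empty set yields zero counts and empty
    (NaN-free, blank) percentage cells.
    """
    scopes = [("all", s.df)]
    if per_group:
        scopes += [(g, s.df[s.df["group"] == g]) for g in s.groups]
    out = []
    for scope, df in scopes:
        total = len(df)
        for vt in ("SNV", "INS", "DEL"):
            n = int((df["vtype"] == vt).sum())
            pct = round(100.0 * n / total, 2) if total else ""
            out.append((scope, "vtype", vt, n, pct))
        for zy in ("homozygous", "heterozygous"):
            n = int((df["zygosity"] == zy).sum())
            pct = round(100.0 * n / total, 2) if total else ""
            out.append((scope, "zygosity", zy, n, pct))
        out.append((scope, "total", "all", total, 100.00 if total else ""))
    return pd.DataFrame(out, columns=["group", "category", "class", "count", "pct"])
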