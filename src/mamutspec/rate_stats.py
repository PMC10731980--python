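"""Mutation-rate estimation and group-comparison statistics.

The heritable mutation rate per site per line per generation is estimated
from singleton counts with zygosity weighting: a selfed heterozygote
transmits its mutant allele to homozygosity with probability ½, so the
effective mutation count is

    E = N_hom + ½ · N_het

and the rate is  μ̂ = E / (D · S · L · g)  with S the denominator target
size (default: reference non-N length), L the number of lines, g the
number of generations and D a diploid site factor (default 2, i.e. both
homologs are mutational targets).  S, D, L and g are always reported with
the estimate; none is hard-coded.

Group comparisons follow the standard MA-study toolkit: one-way ANOVA with
Tukey HSD post-hoc tests and a compact letter display, plus two-sample
t-tests (Welch by default) for per-line fraction comparisons against a
control group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateInputError
from .singleton_filter import SingletonSet

__all__ = [
    "RateEstimate",
    "GroupComparison",
    "per_line_counts",
    "effective_mutation_count",
    "mutation_rate",
    "estimate_group_rates",
    "group_anova_tukey",
    "proportion_t_test",
    "compact_letter_display",
]


# ---------------------------------------------------------------------------
# Counts and rates
# ---------------------------------------------------------------------------

def per_line_counts(
    s: SingletonSet, by: str | Callable[[pd.Series], bool] = "all"
) -> tuple[pd.Series, pd.Series]:
    """Singleton counts per line and mean counts per group.

    ``by`` selects "all", "SNV", "InDel" or a row predicate.  Every line in
    the cohort appears, lines without singletons counting 0; group means
    are total counts over the number of lines in the group.
    """
    if callable(by):
        sub = s.subset(predicate=by)
    elif by == "all":
        sub = s
    elif by in ("SNV", "InDel", "INS", "DEL"):
        sub = s.subset(vtype=by)
    else:
        raise ValueError(f"unknown selector {by!r}")
    raw = sub.df.groupby("line").size()
    unknown = set(raw.index) - set(s.lines)
    if unknown:
        raise ValueError(f"counts for unknown lines {sorted(unknown)}")
    counts = pd.Series(
        [int(raw.get(ln, 0)) for ln in s.lines], index=list(s.lines), dtype=int
    )
    means = pd.Series(
        {g: float(counts[s.lines_in_group(g)].mean()) for g in s.groups}
    )
    return counts, means


def effective_mutation_count(
    s: SingletonSet, group: str | None = None, vtype: str | None = None
) -> float:
    """Zygosity-weighted mutation count E = N_hom + ½·N_het."""
    sub = s.subset(vtype=vtype, group=group) if (group or vtype) else s
    n_hom = int((sub.df["zygosity"] == "homozygous").sum())
    n_het = int((sub.df["zygosity"] == "heterozygous").sum())
    return n_hom + 0.5 * n_het


def mutation_rate(
    E: float, S: float, L: int, g: int = 1, diploid_factor: float = 2.0
) -> float:
    """μ̂ = E / (D · S · L · g), per site per line per generation."""
    denom = diploid_factor * S * L * g
    if denom <= 0:
        raise ValueError(f"non-positive denominator D*S*L*g = {denom}")
    return E / denom


@dataclass(frozen=True)
class RateEstimate:
    group: str
    n_lines: int
    n_hom: int
    n_het: int
    effective_count: float
    sites: float
    generations: int
    diploid_factor: float
    rate: float


def estimate_group_rates(
    s: SingletonSet,
    sites: float,
    generations: int = 1,
    diploid_factor: float = 2.0,
    vtype: str | None = None,
) -> pd.DataFrame:
    """Per-group (and overall) rate estimates as a report table.

    ``sites`` is the denominator target size S, normally the reference
    non-N length.  The table carries every denominator component used.
    """
    rows = []
    for g in ["all"] + s.groups:
        sub = s.subset(vtype=vtype, group=None if g == "all" else g)
        lines = s.lines if g == "all" else s.lines_in_group(g)
        n_hom = int((sub.df["zygosity"] == "homozygous").sum())
        n_het = int((sub.df["zygosity"] == "heterozygous").sum())
        E = n_hom + 0.5 * n_het
        est = RateEstimate(
            g, len(lines), n_hom, n_het, E, sites, generations,
            diploid_factor,
            mutation_rate(E, sites, len(lines), generations, diploid_factor),
        )
        rows.append(est.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    groups: list[str]
    means: pd.Series
    n: pd.Series
    f_statistic: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]
    alpha: float = 0.05


def compact_letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    significant_pairs: set[frozenset],
) -> dict[str, str]:
    """Assign letters so groups share a letter iff not significantly different.

    Insert-and-absorb algorithm; groups are ordered by descending mean
    before letter allocation, which makes the display deterministic.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    rank = {g: i for i, g in enumerate(order)}
    letter_sets: list[set] = [set(order)]
    pairs = sorted(
        (tuple(sorted(p, key=rank.__getitem__)) for p in significant_pairs),
        key=lambda p: (rank[p[0]], rank[p[1]]),
    )
    for a, b in pairs:
        new_sets: list[set] = []
        for ls in letter_sets:
            if a in ls and b in ls:
                new_sets.append(ls - {a})
                new_sets.append(ls - {b})
            else:
                new_sets.append(ls)
        # absorb: drop empties, duplicates and strict subsets
        uniq: list[set] = []
        for ls in new_sets:
            if ls and ls not in uniq:
                uniq.append(ls)
        letter_sets = [ls for ls in uniq if not any(ls < other for other in uniq)]
    letter_sets.sort(key=lambda ls: min(rank[g] for g in ls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    result = {g: "" for g in order}
    for i, ls in enumerate(letter_sets):
        for g in order:
            if g in ls:
                result[g] += alphabet[i]
    return result


def group_anova_tukey(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise tests and letter groups.

    Requires ≥2 groups with ≥2 values each.  When every group is constant
    (zero within-group variance everywhere) the F statistic is undefined
    and a :class:`~mamutspec.errors.DegenerateInputError` is raised.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    for g, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    if all(np.ptp(a) == 0 for a in arrays.values()):
        if len({a[0] for a in arrays.values()}) == 1:
            # all observations identical: F = 0/0; report the trivial outcome
            means = pd.Series({g: float(a.mean()) for g, a in arrays.items()})
            n = pd.Series({g: len(a) for g, a in arrays.items()})
            tukey = pd.DataFrame(
                [(a, b, 0.0, 1.0, False)
                 for a, b in itertools.combinations(groups, 2)],
                columns=["group1", "group2", "meandiff", "p_adj", "reject"],
            )
            letters = compact_letter_display(groups, means, set())
            return GroupComparison(groups, means, n, 0.0, 1.0, tukey, letters, alpha)
        raise DegenerateInputError("zero within-group variance in every group")

    f_stat, anova_p = stats.f_oneway(*arrays.values())
    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[g] * len(arrays[g]) for g in groups])
    res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tk = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    tukey = pd.DataFrame({
        "group1": tk["group1"].astype(str),
        "group2": tk["group2"].astype(str),
        "meandiff": tk["meandiff"].astype(float),
        "p_adj": np.asarray(res.pvalues, dtype=float),
        "reject": np.asarray(res.reject, dtype=bool),
    })
    sig = {
        frozenset((r.group1, r.group2))
        for r in tukey.itertuples() if r.reject
    }
    means = pd.Series({g: float(a.mean()) for g, a in arrays.items()})
    n = pd.Series({g: len(a) for g, a in arrays.items()})
    letters = compact_letter_display(groups, means, sig)
    return GroupComparison(
        groups, means, n, float(f_stat), float(anova_p), tukey, letters, alpha
    )


def proportion_t_test(
    fractions_by_group: Mapping[str, Sequence[float]],
    reference_group: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-tests of each group against a reference.

    Welch's test by default (group sizes are typically unequal once
    gradient arms are merged).  Lines with undefined fractions must be
    excluded by the caller; a group with fewer than 2 usable values raises.
    """
    if reference_group not in fractions_by_group:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = np.asarray(fractions_by_group[reference_group], dtype=float)
    if len(ref) < 2:
        raise ValueError("reference group has fewer than 2 usable values")
    rows = []
    for g, vals in fractions_by_group.items():
        if g == reference_group:
            continue
        a = np.asarray(vals, dtype=float)
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 usable values")
        t, p = stats.ttest_ind(a, ref, equal_var=equal_var)
        rows.append({
            "group": g, "reference": reference_group,
            "n_group": len(a), "n_reference": len(ref),
            "mean_group": float(a.mean()), "mean_reference": float(ref.mean()),
            "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows)
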