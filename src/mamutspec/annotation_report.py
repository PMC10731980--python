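"""Genomic-region classification, intolerance calls and pipeline assembly.

Each singleton is assigned exactly one region with the explicit precedence
CDS(→ coding exon) > UTR > exon > intron > intergenic; InDels are
classified by any overlap of their affected interval under the same
precedence.  "Intolerant" (deleterious) variants are SNVs with a supplied
SIFT score < 0.05, plus any InDel overlapping coding sequence.  SIFT
scores are inputs, never computed here.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import io_formats as iof
from . import indel_spectrum as isp
from . import rate_stats as rs
from . import snv_spectrum as ss
from .io_formats import GffIndex
from .singleton_filter import (
    FilterConfig, SingletonSet, apply_locus_filters, select_singletons,
    summarize_singletons,
)

REGIONS = ("intergenic", "UTR", "exon", "intron")


@dataclass(frozen=True)
class RegionCall:
    region: str            # one of REGIONS
    coding: bool           # overlaps CDS (implies region == "exon")
    gene_id: str | None = None
    multi_gene: bool = False  # overlapped >1 gene; precedence call flagged


@dataclass(frozen=True)
class IntoleranceCall:
    intolerant: bool
    basis: str             # "sift_score" | "coding_indel" | "none"
    sift_score: float | None = None


def _affected_interval(row) -> tuple[int, int]:
    pos = int(row.pos)
    if len(row.ref) == 1 and len(row.alt) == 1:
        return pos, pos
    if len(row.alt) > len(row.ref):      # insertion between pos and pos+1
        return pos, pos + 1
    return pos + 1, pos + len(row.ref) - 1   # deletion


def classify_region(gff: GffIndex, row) -> RegionCall:
    """Region call for one variant row (needs contig/pos/ref/alt fields).

    Precedence: CDS overlap → coding exon; UTR feature → UTR; exon feature
    without CDS/UTR → non-coding exon; inside a gene but outside exons →
    intron; outside all genes → intergenic.
    """
    start, end = _affected_interval(row)
    feats = gff.query_interval(row.contig, start, end)
    genes = gff.genes_at(row.contig, start, end)
    gene_id = genes[0] if genes else None
    multi = len(genes) > 1
    if "CDS" in feats:
        return RegionCall("exon", True, gene_id, multi)
    if "five_prime_UTR" in feats or "three_prime_UTR" in feats:
        return RegionCall("UTR", False, gene_id, multi)
    if "exon" in feats:
        return RegionCall("exon", False, gene_id, multi)
    if "gene" in feats:
        return RegionCall("intron", False, gene_id, multi)
    return RegionCall("intergenic", False, None, False)


def read_sift_table(path) -> dict[tuple[str, int, str], float]:
    """TSV with columns contig, pos, alt, score → lookup dict."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"contig": str, "pos": int, "alt": str,
                            "score": float})
    need = {"contig", "pos", "alt", "score"}
    if not need <= set(df.columns):
        raise ValueError(f"SIFT table must have columns {sorted(need)}")
    return {(r.contig, int(r.pos), r.alt): float(r.score)
            for r in df.itertuples()}


def intolerance(row, region_call: RegionCall,
                sift_score: float | None = None) -> IntoleranceCall:
    """Intolerant ⇔ (SNV with SIFT < 0.05) or (InDel overlapping CDS).

    The SIFT comparison is strict; a missing score never makes an SNV
    intolerant.  Scores outside [0, 1] are rejected.
    """
    if sift_score is not None and not 0.0 <= sift_score <= 1.0:
        raise ValueError(f"SIFT score {sift_score} outside [0,1]")
    is_snv = len(row.ref) == 1 and len(row.alt) == 1
    if is_snv:
        if sift_score is not None and sift_score < 0.05:
            return IntoleranceCall(True, "sift_score", sift_score)
        return IntoleranceCall(False, "none", sift_score)
    if region_call.coding:
        return IntoleranceCall(True, "coding_indel", sift_score)
    return IntoleranceCall(False, "none", sift_score)


def annotate_singletons(
    s: SingletonSet,
    gff: GffIndex | None = None,
    sift: Mapping[tuple[str, int, str], float] | None = None,
) -> pd.DataFrame:
    """Per-record region + intolerance annotation table."""
    df = s.df.copy()
    if gff is not None:
        calls = [classify_region(gff, r) for r in df.itertuples()]
        df["region"] = [c.region for c in calls]
        df["coding"] = [c.coding for c in calls]
        df["gene_id"] = [c.gene_id or "" for c in calls]
        df["multi_gene"] = [c.multi_gene for c in calls]
        if sift is not None:
            tol = []
            for r, c in zip(df.itertuples(), calls):
                score = sift.get((r.contig, int(r.pos), r.alt))
                tol.append(intolerance(r, c, score))
            df["sift_score"] = [
                t.sift_score if t.sift_score is not None else np.nan for t in tol
            ]
            df["intolerant"] = [t.intolerant for t in tol]
            df["intolerance_basis"] = [t.basis for t in tol]
    return df


def region_summary(annotated: pd.DataFrame, groups: list[str]) -> pd.DataFrame:
    """Per-group region counts and percentages (summing to 100 per group)."""
    rows = []
    for g in ["all"] + groups:
        sub = annotated if g == "all" else annotated[annotated["group"] == g]
        total = len(sub)
        for region in REGIONS:
            n = int((sub["region"] == region).sum())
            rows.append({
                "group": g, "region": region, "count": n,
                "pct": round(100.0 * n / total, 2) if total else None,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    vcf,
    reference,
    groups,
    out_dir,
    gff=None,
    sift=None,
    filter_config: FilterConfig | None = None,
    diploid_factor: float = 2.0,
    generations: int = 1,
    sites: float | None = None,
    absent: str = "hom_ref",
    seed: int | None = None,
) -> dict:
    """Run filter → singletons → rates/spectrum/InDel/region reports.

    ``vcf`` is a path (joint multi-sample) or list of paths (per-line);
    ``groups`` a path to a line→group TSV or a mapping.  Writes TSV tables
    plus a JSON manifest (parameters, versions, input digests) to
    ``out_dir`` and returns the manifest.  Given identical inputs the
    report bundle is byte-identical; optional stages (GFF, SIFT) degrade
    with an explicit manifest note rather than failing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    filter_config = filter_config or FilterConfig()

    stage = "read_inputs"
    try:
        genome = iof.read_reference(reference)
        group_map = groups if isinstance(groups, Mapping) else iof.read_groups(groups)
        vcf_paths = [vcf] if isinstance(vcf, (str, Path)) else list(vcf)
        table = iof.read_cohort_vcf(vcf_paths, group_map, absent=absent)
        gff_index = iof.read_gff(gff, known_contigs=genome.names) if gff else None
        sift_map = read_sift_table(sift) if sift else None

        stage = "locus_filters"
        filtered = apply_locus_filters(table, filter_config)
        stage = "singleton_selection"
        singles = select_singletons(filtered, filter_config)

        stage = "summaries"
        tables: dict[str, pd.DataFrame] = {}
        tables["summary"] = summarize_singletons(singles)
        counts, means = rs.per_line_counts(singles)
        tables["per_line_counts"] = pd.DataFrame({
            "line": counts.index,
            "group": [singles.line_groups[ln] for ln in counts.index],
            "count": counts.to_numpy(),
        })

        stage = "rates"
        S = sites if sites is not None else genome.non_n_length
        rates = []
        for vt in (None, "SNV", "InDel"):
            r = rs.estimate_group_rates(singles, S, generations, diploid_factor,
                                        vtype=vt)
            r.insert(0, "vtype", vt or "all")
            rates.append(r)
        tables["rates"] = pd.concat(rates, ignore_index=True)

        stage = "snv_spectrum"
        spec = ss.spectrum_table(singles)
        spec_pct = spec.percentages()
        spec_tab = spec.counts.copy()
        spec_tab.insert(0, "class", spec_tab.index)
        tables["spectrum_counts"] = spec_tab.reset_index(drop=True)
        pct_tab = spec_pct.copy()
        pct_tab.insert(0, "class", pct_tab.index)
        tables["spectrum_pct"] = pct_tab.reset_index(drop=True)
        frac_rows = []
        for g in singles.groups:
            fr, excluded = ss.transition_fraction_per_line(singles, g)
            for ln, v in fr.items():
                frac_rows.append({"line": ln, "group": g,
                                  "transition_fraction": round(v, 6)})
        tables["transition_fractions"] = pd.DataFrame(frac_rows)
        tables["chromosome_distribution"] = ss.chromosome_distribution(
            singles, genome
        )
        context_tables = {}
        for base in ("C", "G"):
            for g in [None] + singles.groups:
                try:
                    cm = ss.context_frequency_matrix(singles, genome, base, g)
                except ValueError:
                    continue
                tab = cm.freqs.copy()
                tab.insert(0, "position", tab.index)
                key = f"context_{base}_{g or 'all'}"
                context_tables[key] = tab.reset_index(drop=True)
        tables.update(context_tables)

        stage = "indel_spectrum"
        tables["indel_report"] = isp.indel_report(singles, genome, anova=False)
        tables["indel_calls"] = isp.per_record_calls(singles, genome)

        stage = "annotation"
        notes = []
        annotated = annotate_singletons(singles, gff_index, sift_map)
        if gff_index is not None:
            tables["regions"] = region_summary(annotated, singles.groups)
        else:
            notes.append("region stage skipped: no GFF provided")
        if gff_index is not None and sift_map is not None:
            itab = annotated.groupby("group", sort=False).agg(
                n=("intolerant", "size"), n_intolerant=("intolerant", "sum")
            ).reset_index()
            itab["pct_intolerant"] = (
                100.0 * itab["n_intolerant"] / itab["n"]
            ).round(2)
            tables["intolerance"] = itab
        elif sift_map is None:
            notes.append("intolerance stage skipped: no SIFT table provided")

        stage = "write_reports"
        iof.write_singletons(singles.df, out_dir / "singletons.tsv")
        iof.write_report_tables(tables, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "mamutspec",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": {
            "max_missing_fraction": filter_config.max_missing_fraction,
            "max_het_fraction": filter_config.max_het_fraction,
            "het_denominator": filter_config.het_denominator,
            "allele_aware": filter_config.allele_aware,
            "diploid_factor": diploid_factor,
            "generations": generations,
            "sites": S,
            "absent_dialect": absent,
        },
        "inputs": {
            "reference": {"path": str(reference),
                          "sha256": iof.file_digest(reference)},
            "vcf": [{"path": str(p), "sha256": iof.file_digest(p)}
                    for p in vcf_paths],
            "gff": ({"path": str(gff), "sha256": iof.file_digest(gff)}
                    if gff else None),
            "sift": ({"path": str(sift), "sha256": iof.file_digest(sift)}
                     if sift else None),
        },
        "counts": {
            "loci_raw": int(table.n_loci),
            "loci_filtered": int(filtered.n_loci),
            "singletons": len(singles),
            "lines": table.n_lines,
        },
        "notes": notes,
        "tables": sorted([*tables, "singletons"]),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
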