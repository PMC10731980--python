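"""Readers/writers for the standard formats the pipeline touches.

The analysis consumes variant calls (VCF 4.x), a reference genome (FASTA)
and gene annotation (GFF3), and emits plain TSV report tables.  This module
provides the canonical in-memory containers — :class:`ReferenceGenome`,
:class:`VariantRecord` and the loci × lines :class:`CohortTable` — plus the
format plumbing around them.  Coordinates are 1-based VCF/GFF conventions
throughout; InDel alleles are kept in VCF anchor-base form after
normalization (shared-suffix then shared-prefix trimming).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from .errors import (
    DuplicateContigError,
    MalformedGenotypeError,
    UnknownContigError,
    UnsupportedVariantError,
)

# Genotype cell codes for the loci × lines matrix.
MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2

GT_LABELS = {MISSING: "missing", HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt"}
GT_VCF_STRINGS = {MISSING: "./.", HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1"}

VALID_BASES = frozenset("ACGT")
_AMBIGUITY_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})

#: Column order of the singleton report table.
SINGLETON_COLUMNS = [
    "contig", "pos", "ref", "alt", "vtype", "size", "line", "group", "zygosity",
]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by contig, insertion-ordered.

    Lookup is 1-based: ``genome.base("Chr1", 1)`` is the first base.
    """

    contigs: dict[str, str]
    _total: int = field(init=False, repr=False)
    _non_n: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("reference genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self._total = sum(len(s) for s in self.contigs.values())
        self._non_n = sum(len(s) - s.count("N") for s in self.contigs.values())

    @property
    def total_length(self) -> int:
        return self._total

    @property
    def non_n_length(self) -> int:
        return self._non_n

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def base(self, contig: str, pos: int) -> str:
        """Single base at 1-based ``pos``."""
        seq = self._seq(contig)
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (len {len(seq)})")
        return seq[pos - 1]

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        seq = self._seq(contig)
        if start < 1 or end > len(seq) or end < start:
            raise IndexError(f"interval {start}-{end} outside contig {contig!r}")
        return seq[start - 1:end]

    def _seq(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise UnknownContigError(contig) from None

    def write_fasta(self, path: str | Path, width: int = 60) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        return path


def read_reference(path: str | Path, ambiguity: str = "reject") -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome`.

    Sequences are upper-cased.  Bases outside A/C/G/T/N are rejected by
    default (``ambiguity="reject"``) because the substitution-spectrum
    classes are defined only on ACGT; ``ambiguity="map_to_n"`` converts
    IUPAC ambiguity codes to N instead.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    contigs: dict[str, str] = {}
    for rec in records:
        if rec.id in contigs:
            raise DuplicateContigError(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES - {"N"}
        if bad:
            if ambiguity == "map_to_n":
                seq = seq.translate(_AMBIGUITY_TO_N)
                if set(seq) - VALID_BASES - {"N"}:
                    raise ValueError(f"contig {rec.id!r}: unmappable characters {bad}")
            else:
                raise ValueError(
                    f"contig {rec.id!r}: ambiguity characters {sorted(bad)} "
                    "(use ambiguity='map_to_n' to accept)"
                )
        contigs[rec.id] = seq
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def variant_type(ref: str, alt: str) -> tuple[str, int]:
    """Classify an anchor-form allele pair as ``("SNV"|"INS"|"DEL", size)``.

    Size is 0 for SNVs and the absolute allele-length difference otherwise.
    Equal-length multi-base pairs (MNPs) and symbolic alleles are rejected.
    """
    if not ref or not alt:
        raise UnsupportedVariantError(f"empty allele in ({ref!r}, {alt!r})")
    if set(ref) - VALID_BASES or set(alt) - VALID_BASES:
        raise UnsupportedVariantError(f"non-ACGT allele in ({ref!r}, {alt!r})")
    if ref == alt:
        raise UnsupportedVariantError(f"ref and alt identical: {ref!r}")
    if len(ref) == 1 and len(alt) == 1:
        return "SNV", 0
    if len(alt) > len(ref):
        return "INS", len(alt) - len(ref)
    if len(alt) < len(ref):
        return "DEL", len(ref) - len(alt)
    raise UnsupportedVariantError(f"MNP not supported: ({ref!r}, {alt!r})")


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix, then shared prefix (keeping one anchor base).

    Returns the adjusted 1-based position and minimal anchor-form alleles.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantRecord:
    """One called variant owned by one line, with derived type and size."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    zygosity: str  # "homozygous" | "heterozygous"
    group: str | None = None
    vtype: str = field(init=False)
    size: int = field(init=False)

    def __post_init__(self) -> None:
        vt, size = variant_type(self.ref, self.alt)
        object.__setattr__(self, "vtype", vt)
        object.__setattr__(self, "size", size)
        if self.zygosity not in ("homozygous", "heterozygous"):
            raise ValueError(f"bad zygosity {self.zygosity!r}")


# ---------------------------------------------------------------------------
# Cohort genotype table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Loci × lines genotype matrix for one MA cohort.

    ``loci`` has columns contig, pos, ref, alt; ``genotypes`` is an int8
    matrix of :data:`MISSING`/:data:`HOM_REF`/:data:`HET`/:data:`HOM_ALT`
    codes with one row per locus and one column per line.
    """

    loci: pd.DataFrame
    genotypes: np.ndarray
    lines: list[str]
    line_groups: dict[str, str]

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.loci), len(self.lines)):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.loci)} loci x {len(self.lines)} lines"
            )
        missing = [ln for ln in self.lines if ln not in self.line_groups]
        if missing:
            raise ValueError(f"lines without group label: {missing}")
        keys = list(zip(self.loci["contig"], self.loci["pos"],
                        self.loci["ref"], self.loci["alt"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig,pos,ref,alt) locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def subset_loci(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(
            self.loci.loc[np.asarray(mask)].reset_index(drop=True),
            self.genotypes[np.asarray(mask)],
            list(self.lines),
            dict(self.line_groups),
        )


def _code_gt(gt: tuple | None, alt_index: int) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    if len(gt) != 2:
        raise MalformedGenotypeError(f"non-diploid GT {gt!r}")
    n = sum(1 for a in gt if a == alt_index)
    if n == 2:
        return HOM_ALT
    if n == 1:
        return HET
    return HOM_REF


def _records_from_vcf(path: str | Path):
    """Yield (contig, pos, ref, alt, {sample: code}) with multi-allelics split."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            ref = rec.ref.upper()
            for ai, alt in enumerate(rec.alts or (), start=1):
                alt = alt.upper()
                if set(alt) - VALID_BASES or set(ref) - VALID_BASES:
                    raise UnsupportedVariantError(
                        f"{rec.contig}:{rec.pos} unsupported alleles ({ref}, {alt})"
                    )
                pos, r, a = normalize_alleles(rec.pos, ref, alt)
                codes = {}
                for s in samples:
                    codes[s] = _code_gt(rec.samples[s].get("GT"), ai)
                yield rec.contig, pos, r, a, codes


def read_cohort_vcf(
    paths: str | Path | Sequence[str | Path],
    groups: Mapping[str, str],
    absent: str = "hom_ref",
) -> CohortTable:
    """Read one joint multi-sample VCF, or many per-line VCFs, into a cohort.

    ``groups`` maps line (sample) names to treatment labels; a sample
    without a label is an error.  Multi-allelic records are split into one
    locus per alt allele.  In the per-line dialect a locus absent from a
    line's VCF becomes ``hom_ref`` by default; ``absent="missing"`` flips
    that (for callers whose joint tables carry explicit no-calls).
    """
    if absent not in ("hom_ref", "missing"):
        raise ValueError("absent must be 'hom_ref' or 'missing'")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]

    cells: dict[tuple, dict[str, int]] = {}
    order: list[tuple] = []
    all_lines: list[str] = []
    for path in paths:
        with pysam.VariantFile(str(path)) as vf:
            samples = list(vf.header.samples)
        unlabeled = [s for s in samples if s not in groups]
        if unlabeled:
            raise ValueError(f"{path}: samples without group label: {unlabeled}")
        for s in samples:
            if s in all_lines:
                raise ValueError(f"sample {s!r} appears in more than one VCF")
        all_lines.extend(samples)
        for contig, pos, ref, alt, codes in _records_from_vcf(path):
            key = (contig, pos, ref, alt)
            if key not in cells:
                cells[key] = {}
                order.append(key)
            cells[key].update(codes)

    fill = HOM_REF if absent == "hom_ref" else MISSING
    single_file = len(paths) == 1
    order.sort(key=lambda k: (k[0], k[1], k[2], k[3]))
    gt = np.full((len(order), len(all_lines)), fill, dtype=np.int8)
    for i, key in enumerate(order):
        row = cells[key]
        for j, line in enumerate(all_lines):
            if line in row:
                gt[i, j] = row[line]
            elif single_file:
                # joint dialect: every sample has an explicit call per record
                gt[i, j] = fill
    loci = pd.DataFrame(order, columns=["contig", "pos", "ref", "alt"])
    return CohortTable(loci, gt, all_lines, {ln: groups[ln] for ln in all_lines})


def write_cohort_vcf(
    table: CohortTable,
    path: str | Path,
    reference: ReferenceGenome | None = None,
) -> Path:
    """Write a cohort as a joint multi-sample VCF 4.2 (one record per locus)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mamutspec\n")
        if reference is not None:
            for name, seq in reference.contigs.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.lines) + "\n")
        for i in range(table.n_loci):
            contig, pos, ref, alt = table.loci.iloc[i]
            gts = "\t".join(GT_VCF_STRINGS[int(c)] for c in table.genotypes[i])
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3 interval index
# ---------------------------------------------------------------------------

GFF_FEATURE_TYPES = frozenset(
    {"gene", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}
)


@dataclass
class GffIndex:
    """Per-contig interval trees over annotation features.

    Queries return the set of feature types overlapping a position or a
    1-based inclusive interval.  Querying a contig the index has never seen
    raises :class:`UnknownContigError`; contigs known to be featureless can
    be registered via ``known_contigs`` at build time.
    """

    trees: dict[str, IntervalTree]

    def _tree(self, contig: str) -> IntervalTree:
        try:
            return self.trees[contig]
        except KeyError:
            raise UnknownContigError(contig) from None

    def query(self, contig: str, pos: int) -> set[str]:
        return {iv.data[0] for iv in self._tree(contig).at(pos)}

    def query_interval(self, contig: str, start: int, end: int) -> set[str]:
        return {iv.data[0] for iv in self._tree(contig).overlap(start, end + 1)}

    def genes_at(self, contig: str, start: int, end: int) -> list[str]:
        hits = {
            iv.data[1]
            for iv in self._tree(contig).overlap(start, end + 1)
            if iv.data[0] == "gene" and iv.data[1]
        }
        return sorted(hits)


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.strip().split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def read_gff(
    path: str | Path,
    feature_types: Iterable[str] = GFF_FEATURE_TYPES,
    known_contigs: Iterable[str] = (),
) -> GffIndex:
    """Parse a GFF3 file into a :class:`GffIndex` (1-based inclusive intervals)."""
    wanted = set(feature_types)
    trees: dict[str, IntervalTree] = {c: IntervalTree() for c in known_contigs}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if ftype not in wanted:
                continue
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            gid = _gff_attr(fields[8], "ID") or _gff_attr(fields[8], "Parent")
            trees.setdefault(contig, IntervalTree())
            trees[contig].addi(start_i, end_i + 1, (ftype, gid))
    return GffIndex(trees)


# ---------------------------------------------------------------------------
# TSV report tables, groups files
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column line→group TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if list(df.iloc[0]) == ["line", "group"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("line\tgroup\n")
        for line in groups:
            fh.write(f"{line}\t{groups[line]}\n")
    return path


def write_report_tables(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    float_format: str = "%.6f",
) -> dict[str, Path]:
    """Write each named DataFrame to ``out_dir/<name>.tsv`` deterministically.

    Column order is taken from the frames as given; floats use a fixed
    format so repeated runs are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=float_format)
        paths[name] = p
    return paths


def write_singletons(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a singleton table sorted by (contig, pos, line) with fixed columns."""
    path = Path(path)
    out = df.loc[:, SINGLETON_COLUMNS].sort_values(
        ["contig", "pos", "line"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)
    return path


def read_singletons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"contig": str, "pos": int, "ref": str, "alt": str, "vtype": str,
               "size": int, "line": str, "group": str, "zygosity": str},
    )
    missing = [c for c in SINGLETON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing singleton columns {missing}")
    return df.loc[:, SINGLETON_COLUMNS]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
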