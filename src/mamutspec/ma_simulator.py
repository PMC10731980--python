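"""Synthetic mutation-accumulation cohort generator.

Emulates the statistical structure a post-calling MA analysis assumes:

* a diploid cohort of treatment groups × lines derived from one founder,
* founder ("germline") variants shared by ≥2 lines, which the singleton
  filter must remove,
* line-private de novo SNVs and InDels with a configurable zygosity mix,
  substitution-class spectrum, InDel size distribution,
  insertion:deletion ratio and repeat-adjacency share,
* optionally, a planted upstream (−3…−1) motif in the reference context
  of mutated C/G sites.

Rate semantics: ``snv_rate`` / ``indel_rate`` are *effective* (zygosity-
weighted) heritable rates per site per line per generation — the quantity
the downstream estimator  E/(D·S·L·g)  with  E = N_hom + ½·N_het  reports.
The number of planted variant records per line is therefore Poisson with
mean  rate·D·S·g / w,  w = hom_fraction + (1−hom_fraction)/2,  so that the
expected effective count equals rate·D·S·g and the estimator is unbiased,
while the observed homozygous record fraction stays at ``hom_fraction``.
Heterozygous variants are emitted as het in the sampled generation; no
further Mendelian segregation is simulated — the estimator's ½-weighting
is what the recovery tests exercise.

Everything is reproducible from the config seed; ground truth is returned
as a table so every downstream stage can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io_formats as iof
from .io_formats import HET, HOM_ALT, HOM_REF, CohortTable, ReferenceGenome
from . import indel_spectrum as isp
from .snv_spectrum import BASES, SUBSTITUTION_CLASSES, TRANSITION_CLASSES

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRUTH_COLUMNS = [
    "contig", "pos", "ref", "alt", "line", "group", "zygosity", "origin",
    "vtype", "size", "sub_class", "adjacency",
]


def default_substitution_weights(transition_fraction: float) -> np.ndarray:
    """12-class probability vector: transitions split evenly over their 4
    classes, transversions over their 8."""
    w = np.empty(12)
    for i, cls in enumerate(SUBSTITUTION_CLASSES):
        if cls in TRANSITION_CLASSES:
            w[i] = transition_fraction / 4.0
        else:
            w[i] = (1.0 - transition_fraction) / 8.0
    return w


def default_indel_length_distribution(
    short_fraction: float = 0.7706, max_size: int = 28
) -> np.ndarray:
    """Length probabilities over 1..max_size bp.

    ``short_fraction`` of the mass goes to sizes 1–3 (geometric decay,
    ratio ½) and the rest to 4..max_size (geometric decay, ratio 0.7),
    reproducing the short-InDel dominance and the 1–28 bp range seen in
    MA sequencing data.
    """
    sizes = np.arange(1, max_size + 1)
    w = np.where(sizes <= 3, 0.5 ** sizes, 0.0)
    w = np.where(sizes > 3, 0.7 ** (sizes - 3), w)
    short = sizes <= 3
    w[short] *= short_fraction / w[short].sum()
    w[~short] *= (1.0 - short_fraction) / w[~short].sum()
    return w


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-realistic defaults.

    The default cohort is 4 treatment groups × 40 selfed diploid lines on
    a 1 Mb, 36% GC, 5-contig genome.  The effective SNV and InDel rates
    default to values that yield the per-line singleton counts typical of
    an Arabidopsis MA experiment (≈4.2 SNVs and ≈0.46 InDels per line) at
    this genome size; ``hom_fraction`` defaults to the ≈17% homozygous
    share observed after one selfed generation.
    """

    genome_length: int = 1_000_000
    n_contigs: int = 5
    gc_fraction: float = 0.36
    n_lines_per_group: int = 40
    groups: tuple[str, ...] = ("CK", "M33", "M30.5", "M24.5")
    germline_variant_count: int = 1600
    snv_rate: float = 1.23e-6     # effective, per site per line per generation
    indel_rate: float = 1.35e-7
    generations: int = 1
    diploid_factor: float = 2.0
    hom_fraction: float = 0.17
    germline_hom_fraction: float = 0.7
    transition_fraction: float = 0.60
    substitution_weights: np.ndarray | None = None
    indel_len_distribution: np.ndarray | None = None
    ins_del_ratio: float = 0.76
    repeat_adjacent_fraction: float = 0.5
    repeat_density: float = 1.0 / 5000.0   # planted tracts per bp
    context_motif: str | None = None       # planted at positions −3…−1
    context_motif_strength: float = 0.0
    germline_share_p: float = 0.6          # geometric tail of carriers beyond 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError(f"gc_fraction {self.gc_fraction} outside [0,1]")
        for name in ("hom_fraction", "germline_hom_fraction",
                     "transition_fraction", "repeat_adjacent_fraction",
                     "context_motif_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        for name in ("snv_rate", "indel_rate", "repeat_density"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.ins_del_ratio < 0:
            raise ConfigError("ins_del_ratio must be >= 0")
        if self.generations < 1 or self.n_contigs < 1 or self.genome_length < 1:
            raise ConfigError("generations, n_contigs, genome_length must be >= 1")
        if self.substitution_weights is None:
            self.substitution_weights = default_substitution_weights(
                self.transition_fraction
            )
        self.substitution_weights = np.asarray(self.substitution_weights, float)
        if self.substitution_weights.shape != (12,) or np.any(
            self.substitution_weights < 0
        ) or abs(self.substitution_weights.sum() - 1.0) > 1e-9:
            raise ConfigError("substitution_weights must be a 12-class "
                              "probability vector summing to 1")
        if self.indel_len_distribution is None:
            self.indel_len_distribution = default_indel_length_distribution()
        self.indel_len_distribution = np.asarray(self.indel_len_distribution, float)
        if np.any(self.indel_len_distribution < 0) or abs(
            self.indel_len_distribution.sum() - 1.0
        ) > 1e-9:
            raise ConfigError("indel_len_distribution must sum to 1")
        if self.context_motif is not None:
            if set(self.context_motif) - set("ACGT") or len(self.context_motif) != 3:
                raise ConfigError("context_motif must be a 3-mer over ACGT")
        if self.germline_variant_count >= self.genome_length / 100:
            raise ConfigError("germline_variant_count must be < genome_length/100")

    @property
    def lines(self) -> list[str]:
        return [
            f"{g}_L{str(i + 1).zfill(2)}"
            for g in self.groups
            for i in range(self.n_lines_per_group)
        ]

    @property
    def line_groups(self) -> dict[str, str]:
        return {ln: ln.rsplit("_L", 1)[0] for ln in self.lines}

    @property
    def zygosity_weight(self) -> float:
        """Expected per-record contribution to E: h + (1−h)/2."""
        return self.hom_fraction + (1.0 - self.hom_fraction) / 2.0

    def expected_records_per_line(self, sites: int, kind: str = "snv") -> float:
        rate = self.snv_rate if kind == "snv" else self.indel_rate
        return (
            rate * self.diploid_factor * sites * self.generations
            / self.zygosity_weight
        )


@dataclass(frozen=True)
class RepeatTract:
    """A salted homopolymer (unit length 1) or tandem repeat tract,
    1-based inclusive."""
    contig: str
    start: int
    end: int
    unit: str


@dataclass
class SimulatedCohort:
    genome: ReferenceGenome
    tracts: list[RepeatTract]
    truth: pd.DataFrame
    cohort: CohortTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, list[RepeatTract]]:
    """I.i.d. random genome at the configured GC, salted with repeat tracts.

    Tracts (homopolymers of length 5–8, and di-/trinucleotide repeats of
    3–5 copies) are written at ``repeat_density`` per bp and recorded so
    repeat-adjacent InDels can be planted against them.  Deterministic for
    a given rng state.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p = _base_probs(config.gc_fraction)
    base = config.genome_length // config.n_contigs
    lengths = [base] * config.n_contigs
    lengths[-1] += config.genome_length - base * config.n_contigs
    arrays: dict[str, np.ndarray] = {}
    byte_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, L in enumerate(lengths):
        if L < 1:
            raise ConfigError("contig length < 1; genome_length too small")
        arrays[f"Chr{i + 1}"] = byte_bases[rng.choice(4, size=L, p=p)].copy()
    tracts: list[RepeatTract] = []
    for name, arr in arrays.items():
        L = len(arr)
        n_tracts = int(round(L * config.repeat_density))
        occupied: list[tuple[int, int]] = []
        for _ in range(n_tracts):
            kind = rng.integers(0, 3)  # 0 hom, 1 di, 2 tri
            if kind == 0:
                unit = "ACGT"[rng.choice(4, p=p)]
                copies = int(rng.integers(5, 9))
            else:
                usize = 2 if kind == 1 else 3
                while True:
                    unit = "".join("ACGT"[b] for b in rng.choice(4, size=usize, p=p))
                    if len(set(unit)) > 1:
                        break
                copies = int(rng.integers(3, 6))
            tract_seq = unit * copies
            tlen = len(tract_seq)
            if L < tlen + 60:
                continue
            for _try in range(20):
                start = int(rng.integers(30, L - 30 - tlen))  # 0-based
                end = start + tlen - 1
                if all(end < s - 1 or start > e + 1 for s, e in occupied):
                    arr[start:end + 1] = np.frombuffer(
                        tract_seq.encode(), dtype=np.uint8
                    )
                    occupied.append((start, end))
                    tracts.append(RepeatTract(name, start + 1, end + 1, unit))
                    break
    genome = ReferenceGenome(
        {name: arr.tobytes().decode() for name, arr in arrays.items()}
    )
    return genome, tracts


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

class _Planter:
    """Shared bookkeeping for germline + de novo planting on one genome."""

    def __init__(self, genome: ReferenceGenome, config: SimulationConfig,
                 rng: np.random.Generator, tracts: Sequence[RepeatTract] = ()):
        self.config = config
        self.rng = rng
        self.tracts = list(tracts)
        self.arrays = {
            name: np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            for name, seq in genome.contigs.items()
        }
        self.names = list(self.arrays)
        # blocked: positions reserved by tracts / motif rewrites (0-based)
        self.blocked: dict[str, set[int]] = {n: set() for n in self.names}
        # used: positions already part of a planted variant locus
        self.used: dict[str, set[int]] = {n: set() for n in self.names}
        for t in self.tracts:
            self.blocked[t.contig].update(range(t.start - 1, t.end))
        # per-base position index on the pristine sequence
        self._by_base: dict[str, dict[str, np.ndarray]] = {}
        for name, arr in self.arrays.items():
            self._by_base[name] = {
                b: np.flatnonzero(arr == ord(b)) for b in BASES
            }
        self._contig_weights = {
            b: np.array([len(self._by_base[n][b]) for n in self.names], float)
            for b in BASES
        }
        self.rows: list[tuple] = []

    # -- position sampling --------------------------------------------------
    def sample_position(self, ref_base: str, span: int = 1,
                        max_tries: int = 10_000) -> tuple[str, int]:
        """A free 0-based position whose reference base is ``ref_base``.

        ``span`` positions starting there must all be free (used for
        deletion intervals).  Raises ConfigError when the base does not
        exist or no free site is found.
        """
        weights = self._contig_weights[ref_base]
        total = weights.sum()
        if total == 0:
            raise ConfigError(f"no {ref_base} sites available in the genome")
        probs = weights / total
        for _ in range(max_tries):
            ci = self.rng.choice(len(self.names), p=probs)
            name = self.names[ci]
            idx = self._by_base[name][ref_base]
            pos0 = int(idx[self.rng.integers(0, len(idx))])
            if pos0 + span > len(self.arrays[name]) or pos0 < 5:
                continue
            blocked = self.blocked[name]
            used = self.used[name]
            if any(p in blocked or p in used for p in range(pos0, pos0 + span)):
                continue
            return name, pos0
        raise ConfigError("could not place variant; genome too saturated")

    def block(self, contig: str, start0: int, end0: int) -> None:
        self.blocked[contig].update(range(start0, end0 + 1))

    def mark_used(self, contig: str, start0: int, end0: int) -> None:
        self.used[contig].update(range(start0, end0 + 1))

    def base_at(self, contig: str, pos0: int) -> str:
        return chr(self.arrays[contig][pos0])

    def finalize_genome(self) -> ReferenceGenome:
        return ReferenceGenome(
            {n: a.tobytes().decode() for n, a in self.arrays.items()}
        )


def plant_germline_variants(
    planter: _Planter,
) -> None:
    """Plant founder SNVs, each shared by ≥2 lines.

    The carrier count is 2 plus a geometric tail (knob
    ``germline_share_p``), capped at the cohort size; carrier zygosity is
    homozygous with probability ``germline_hom_fraction``.  By
    construction none of these loci can survive the singleton filter.
    """
    cfg = planter.config
    rng = planter.rng
    lines = cfg.lines
    n_lines = len(lines)
    if n_lines < 2 and cfg.germline_variant_count > 0:
        raise ConfigError("germline variants require >= 2 lines")
    for _ in range(cfg.germline_variant_count):
        ref = "ACGT"[rng.choice(4, p=_base_probs(cfg.gc_fraction))]
        contig, pos0 = planter.sample_position(ref)
        planter.mark_used(contig, pos0, pos0)
        alt = str(rng.choice([b for b in BASES if b != ref]))
        k = min(2 + int(rng.geometric(cfg.germline_share_p)) - 1, n_lines)
        carriers = rng.choice(n_lines, size=k, replace=False)
        for j in sorted(carriers):
            line = lines[j]
            zyg = ("homozygous" if rng.random() < cfg.germline_hom_fraction
                   else "heterozygous")
            planter.rows.append((
                contig, pos0 + 1, ref, alt, line, cfg.line_groups[line],
                zyg, "germline", "SNV", 0, f"{ref}>{alt}", "",
            ))


def _plant_line_snvs(planter: _Planter, line: str, n: int) -> None:
    cfg = planter.config
    rng = planter.rng
    classes = rng.choice(12, size=n, p=cfg.substitution_weights)
    motif = cfg.context_motif
    for c in classes:
        label = SUBSTITUTION_CLASSES[c]
        ref, alt = label[0], label[2]
        contig, pos0 = planter.sample_position(ref)
        planter.mark_used(contig, pos0, pos0)
        if (
            motif is not None
            and ref in "CG"
            and pos0 >= 3
            and rng.random() < cfg.context_motif_strength
        ):
            planted = motif if ref == "C" else motif.translate(_COMPLEMENT)[::-1]
            window = range(pos0 - 3, pos0)
            if not any(p in planter.blocked[contig] or p in planter.used[contig]
                       for p in window):
                planter.arrays[contig][pos0 - 3:pos0] = np.frombuffer(
                    planted.encode(), dtype=np.uint8
                )
                planter.block(contig, pos0 - 3, pos0 - 1)
        zyg = "homozygous" if rng.random() < cfg.hom_fraction else "heterozygous"
        planter.rows.append((
            contig, pos0 + 1, ref, alt, line, cfg.line_groups[line],
            zyg, "denovo", "SNV", 0, label, "",
        ))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join("ACGT"[b] for b in rng.choice(4, size=n, p=_base_probs(gc)))


class _Probe:
    """Minimal record-like view for the adjacency classifiers."""

    __slots__ = ("contig", "pos", "ref", "alt")

    def __init__(self, contig, pos, ref, alt):
        self.contig, self.pos, self.ref, self.alt = contig, pos, ref, alt


def _plant_line_indels(planter: _Planter, line: str, n: int,
                       genome_view: ReferenceGenome) -> None:
    cfg = planter.config
    rng = planter.rng
    p_ins = cfg.ins_del_ratio / (1.0 + cfg.ins_del_ratio)
    sizes = 1 + rng.choice(len(cfg.indel_len_distribution), size=n,
                           p=cfg.indel_len_distribution)
    for size in sizes:
        size = int(size)
        is_ins = rng.random() < p_ins
        span = 1 if is_ins else 1 + size  # anchor (+ deleted bases)
        want_adjacent = bool(
            rng.random() < cfg.repeat_adjacent_fraction and planter.tracts
        )
        result = None
        if want_adjacent:
            for _try in range(100):
                t = planter.tracts[int(rng.integers(0, len(planter.tracts)))]
                arr = planter.arrays[t.contig]
                if rng.random() < 0.5:
                    # right boundary: affected interval starts at t.end + 1
                    anchor0 = t.end - 1
                else:
                    # left boundary: affected interval ends at t.start - 1
                    anchor0 = t.start - 2 - (0 if is_ins else size)
                if anchor0 < 0 or anchor0 + span > len(arr) - 1:
                    continue
                touched = range(anchor0, anchor0 + span)
                if any(p in planter.used[t.contig] for p in touched):
                    continue
                if not is_ins and any(
                    p in planter.blocked[t.contig]
                    for p in range(anchor0 + 1, anchor0 + span)
                ):
                    continue  # deleted bases must not eat another tract/motif
                result = (t.contig, anchor0)
                break
        else:
            for _try in range(200):
                ref_base = "ACGT"[rng.choice(4, p=_base_probs(cfg.gc_fraction))]
                contig, pos0 = planter.sample_position(ref_base, span=span)
                anchor = chr(planter.arrays[contig][pos0])
                if is_ins:
                    seq = _random_seq(rng, size, cfg.gc_fraction)
                    ref, alt = anchor, anchor + seq
                else:
                    deleted = planter.arrays[contig][pos0 + 1:pos0 + 1 + size]
                    ref, alt = anchor + deleted.tobytes().decode(), anchor
                probe = _Probe(contig, pos0 + 1, ref, alt)
                if isp.homopolymer_adjacent(genome_view, probe) or \
                        isp.repeat_adjacent(genome_view, probe):
                    continue  # keep the non-adjacent share clean
                result = (contig, pos0)
                break
        if result is None:
            continue  # saturated; drop this event
        contig, pos0 = result
        anchor = chr(planter.arrays[contig][pos0])
        if is_ins:
            if want_adjacent:
                seq = _random_seq(rng, size, cfg.gc_fraction)
            ref, alt = anchor, anchor + seq
        else:
            deleted = planter.arrays[contig][pos0 + 1:pos0 + 1 + size]
            ref, alt = anchor + deleted.tobytes().decode(), anchor
        planter.mark_used(contig, pos0, pos0 + span - 1)
        zyg = "homozygous" if rng.random() < cfg.hom_fraction else "heterozygous"
        vtype = "INS" if is_ins else "DEL"
        planter.rows.append((
            contig, pos0 + 1, ref, alt, line, cfg.line_groups[line],
            zyg, "denovo", vtype, size, "", "pending",
        ))


def plant_denovo_mutations(planter: _Planter) -> None:
    """Plant line-private SNVs and InDels per the configured rates.

    SNVs are drawn class-first from the 12-class weights with position
    resampling until the reference base matches, so realized class
    frequencies converge to the configured weights regardless of base
    composition.  All SNVs are planted before any InDel so that motif
    rewrites of the reference cannot retroactively change InDel adjacency.
    """
    cfg = planter.config
    rng = planter.rng
    sites = sum(len(a) for a in planter.arrays.values())
    lam_snv = cfg.expected_records_per_line(sites, "snv")
    lam_indel = cfg.expected_records_per_line(sites, "indel")
    n_snv = {ln: int(rng.poisson(lam_snv)) for ln in cfg.lines}
    n_indel = {ln: int(rng.poisson(lam_indel)) for ln in cfg.lines}
    for ln in cfg.lines:
        _plant_line_snvs(planter, ln, n_snv[ln])
    genome_view = planter.finalize_genome()  # motif rewrites applied
    for ln in cfg.lines:
        _plant_line_indels(planter, ln, n_indel[ln], genome_view)


def _truth_frame(planter: _Planter, genome: ReferenceGenome) -> pd.DataFrame:
    truth = pd.DataFrame(planter.rows, columns=TRUTH_COLUMNS)
    if len(truth):
        contig_order = {n: i for i, n in enumerate(genome.contigs)}
        truth = truth.sort_values(
            ["contig", "pos", "line"],
            key=lambda col: col.map(contig_order) if col.name == "contig" else col,
            kind="mergesort",
        ).reset_index(drop=True)
        # resolve deferred adjacency labels on the final genome
        adj = []
        for row in truth.itertuples():
            if row.adjacency != "pending":
                adj.append(row.adjacency)
            else:
                adj.append(isp.classify_indel(genome, row).adjacency)
        truth["adjacency"] = adj
    return truth


def build_cohort_table(truth: pd.DataFrame, config: SimulationConfig
                       ) -> CohortTable:
    """Assemble the loci × lines genotype matrix from a truth table."""
    lines = config.lines
    col = {ln: j for j, ln in enumerate(lines)}
    keys = truth[["contig", "pos", "ref", "alt"]].drop_duplicates()
    keys = keys.sort_values(["contig", "pos", "ref", "alt"]).reset_index(drop=True)
    index = {tuple(k): i for i, k in enumerate(keys.itertuples(index=False))}
    gt = np.full((len(keys), len(lines)), HOM_REF, dtype=np.int8)
    for row in truth.itertuples():
        i = index[(row.contig, row.pos, row.ref, row.alt)]
        gt[i, col[row.line]] = HOM_ALT if row.zygosity == "homozygous" else HET
    return CohortTable(keys, gt, lines, config.line_groups)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: reference, germline, de novo, cohort table."""
    rng = np.random.default_rng(config.seed)
    genome, tracts = simulate_reference(config, rng)
    planter = _Planter(genome, config, rng, tracts)
    plant_germline_variants(planter)
    plant_denovo_mutations(planter)
    final_genome = planter.finalize_genome()
    truth = _truth_frame(planter, final_genome)
    cohort = build_cohort_table(truth, config)
    return SimulatedCohort(final_genome, tracts, truth, cohort, config)


# ---------------------------------------------------------------------------
# Emission to files
# ---------------------------------------------------------------------------

def emit_cohort(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + joint VCF + groups TSV + truth TSV for one simulation.

    Outputs are fully determined by the simulation, so re-running with the
    same config yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": sim.genome.write_fasta(out_dir / "reference.fasta"),
        "vcf": iof.write_cohort_vcf(sim.cohort, out_dir / "cohort.vcf",
                                    sim.genome),
        "groups": iof.write_groups(sim.config.line_groups,
                                   out_dir / "groups.tsv"),
    }
    truth_path = out_dir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
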