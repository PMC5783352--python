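"""Synthetic genomes, tRNA annotations and small-RNA read sets with truth.

The generator emulates the data regime of a genome-wide tRF profiling
experiment: each simulated tRNA gene is a random 72-76 nt mature sequence
with exact canonical clover-leaf geometry (so the structural fallback of
:func:`trfbin.annotation.locate_structure` holds by construction), placed
on its own contig on a random strand with 30 nt precursor flanks.  A
configurable fraction of genes sits near a contig edge with a short flank,
and a configurable number carry exclusion flags (pseudogene, SeC, intron).

Reads are 15-21 nt exact subsequences of planned source bins with a +/-2 nt
5'-end jitter, drawn with negative-binomial counts per sample around
group-specific means, plus Poisson background reads at random positions.
Every emitted read is recorded in a truth table, and bin sequences are made
unique genome-wide (at the minimum read length) so the exact-match fixture
mapper is unambiguous unless the isoacceptor stress flag is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Bin, StructureAnnotation, TRNAGene, filter_trnas, make_bins
from .counting import revcomp
from .errors import PlanError, SizingError, ValidationError

log = logging.getLogger(__name__)

_NT = np.array(list("ACGT"))

#: isotype -> anticodon choices for ordinary simulated tRNAs
ISOTYPES = (
    ("Gly", "GCC"), ("Asp", "GTC"), ("Ala", "AGC"), ("Lys", "TTT"),
    ("Thr", "TGT"), ("Pro", "CGG"), ("Trp", "CCA"), ("Glu", "CTC"),
    ("Gln", "CTG"), ("Phe", "GAA"), ("Ser", "AGA"), ("Val", "CAC"),
    ("Arg", "ACG"), ("His", "GTG"), ("Met", "CAT"), ("Asn", "GTT"),
    ("Cys", "GCA"),
)
#: intron-containing tRNAs are drawn from these isotypes
INTRON_ISOTYPES = (("Tyr", "GTA"), ("Ile", "TAT"), ("Leu", "CAA"))

#: (region_label, mean_female, mean_male) pattern of a sex-bias experiment:
#: 4 female-biased and 12 male-biased source tRFs spanning precursor, mature
#: and loop origins at realistic read-count scales.
DEFAULT_SEX_PLAN_TABLE = (
    ("3-Pre", 17334.6, 10792.4),
    ("3-Pre", 481.4, 309.4),
    ("5-Pre", 427.4, 148.8),
    ("5-Pre", 195.2, 61.0),
    ("3-Pre", 2454.0, 4642.6),
    ("3-Pre", 2387.8, 4531.8),
    ("A-loop", 526.4, 634.8),
    ("T-loop", 159.2, 432.8),
    ("5tRF", 246.0, 329.8),
    ("T-loop", 156.0, 419.6),
    ("3-Pre", 118.8, 237.4),
    ("3-Pre", 114.8, 225.0),
    ("5-Pre", 114.6, 214.2),
    ("T-loop", 127.0, 162.0),
    ("T-loop", 120.2, 159.0),
    ("3-Pre", 45.8, 126.0),
)


@dataclass(frozen=True)
class PlannedTRF:
    """One simulated source tRF: a bin emitting reads at group means."""

    gene_id: Optional[str]  # None -> assigned to a retained gene at build time
    region_label: str
    group_means: Mapping[str, float]
    dispersion: float = 0.1

    def __post_init__(self):
        if any(m < 0 for m in self.group_means.values()):
            raise ValidationError("group means must be >= 0")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")

    @property
    def is_differential(self) -> bool:
        vals = list(self.group_means.values())
        return len(vals) > 1 and max(vals) > min(vals)

    @property
    def direction(self) -> str:
        if not self.is_differential:
            return "none"
        return "up_in_" + max(self.group_means, key=self.group_means.get)


@dataclass(frozen=True)
class SimDesign:
    """Study design of one simulation run.

    Defaults emulate the sex-bias experiment: 984 tRNA genes of which 109
    carry exclusion flags, five strains contributing one female and one
    male library each, 15-21 nt fragment reads over 15 nt bins, and 16
    source tRFs (4 female-biased / 12 male-biased) at published-scale mean
    counts with negative-binomial dispersion 0.1.
    """

    n_genes: int = 984
    n_excluded: int = 109
    fragment_window: int = 15
    groups: tuple = (("female", 5), ("male", 5))
    source_plan: Optional[tuple] = None  # None -> default sex plan
    background_rate: float = 50.0
    read_length_range: tuple = (15, 21)
    flank: int = 30
    near_edge_fraction: float = 0.0
    allow_duplicate_isoacceptors: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_excluded > self.n_genes:
            raise ValidationError("n_excluded cannot exceed n_genes")
        if self.fragment_window < 1:
            raise ValidationError("fragment_window must be >= 1")
        lo, hi = self.read_length_range
        if not (1 <= lo <= hi):
            raise ValidationError("bad read_length_range")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        if not self.groups and (self.source_plan or self.background_rate):
            # a design with no samples can still generate a genome
            pass

    @property
    def sample_ids(self) -> list:
        return [f"{label}_{r + 1}" for label, n in self.groups for r in range(n)]


def default_sex_plan(gene_ids: Sequence[str]) -> tuple:
    """The 16-tRF sex-bias plan assigned to the given genes in order."""
    if len(gene_ids) < len(DEFAULT_SEX_PLAN_TABLE):
        raise ValidationError(
            f"need >= {len(DEFAULT_SEX_PLAN_TABLE)} retained genes for the default plan"
        )
    plan = []
    for gid, (label, mf, mm) in zip(gene_ids, DEFAULT_SEX_PLAN_TABLE):
        plan.append(
            PlannedTRF(gene_id=gid, region_label=label, group_means={"female": mf, "male": mm})
        )
    return tuple(plan)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def _canonical_ss(L: int) -> str:
    """Clover-leaf structure string with loops exactly at the canonical
    fallback offsets (0-based [13,21), [32,39), [53,60))."""
    if L < 72:
        raise SizingError("mature length must be >= 72 for canonical geometry")
    parts = [
        ">" * 7,   # acceptor stem 5'
        ".." ,     # spacer
        ">" * 4,   # D stem 5'
        "." * 8,   # D-loop (14-21)
        "<" * 4,   # D stem 3'
        ".." ,     # spacer
        ">" * 5,   # anticodon stem 5'
        "." * 7,   # A-loop (33-39)
        "<" * 5,   # anticodon stem 3'
        "." * 4,   # variable region
        ">" * 5,   # T stem 5'
        "." * 7,   # T-loop (54-60)
        "<" * 5,   # T stem 3'
        "<" * 7,   # acceptor stem 3'
        "." * (L - 72),  # discriminator / tail
    ]
    ss = "".join(parts)
    assert len(ss) == L
    return ss


@dataclass
class _GeneRecipe:
    index: int
    gene_id: str
    strand: str
    mature_len: int
    flank5: int
    flank3: int
    isotype: str
    anticodon: str
    kind: str  # "ok" | "pseudo" | "sec" | "intron"
    score: float
    mature: str = ""
    f5seq: str = ""
    f3seq: str = ""

    def draw_sequence(self, rng: np.random.Generator) -> None:
        seq = list(_random_seq(rng, self.mature_len))
        seq[33:36] = list(self.anticodon)
        self.mature = "".join(seq)
        self.f5seq = _random_seq(rng, self.flank5)
        self.f3seq = _random_seq(rng, self.flank3)

    @property
    def sense(self) -> str:
        return self.f5seq + self.mature + self.f3seq

    @property
    def contig(self) -> str:
        return self.sense if self.strand == "+" else revcomp(self.sense)

    @property
    def gene_span(self) -> tuple:
        if self.strand == "+":
            return self.flank5, self.flank5 + self.mature_len
        return self.flank3, self.flank3 + self.mature_len


@dataclass
class SimulatedGenome:
    """Reference, annotation and structures of one simulated tRNA set."""

    reference: dict
    genes: list
    structures: dict
    ss_strings: dict
    mature_seqs: dict
    available_flanks: dict
    design: SimDesign

    @property
    def contig_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.reference.items()}

    def fasta_text(self) -> str:
        out = []
        for name, seq in self.reference.items():
            out.append(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.append(seq[i : i + 70] + "\n")
        return "".join(out)

    def write_fasta(self, path) -> None:
        Path(path).write_text(self.fasta_text())

    def trnascan_text(self) -> str:
        """tRNAscan-SE style tabular annotation (note-extended dialect)."""
        lines = [
            "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf\t",
            "Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote",
            "--------\t------\t-----\t----\t----\t-----\t-----\t----\t-----\t----",
        ]
        for g in self.genes:
            if g.strand == "+":
                begin, end = g.start + 1, g.end
            else:
                begin, end = g.end, g.start + 1
            if g.intron_spans:
                s, e = g.intron_spans[0]
                ib, ie = (s + 1, e) if g.strand == "+" else (e, s + 1)
            else:
                ib = ie = 0
            note = "pseudo" if g.is_pseudo else ""
            lines.append(
                "\t".join(
                    [
                        g.seq_id,
                        "1",
                        str(begin),
                        str(end),
                        g.isotype,
                        g.anticodon,
                        str(ib),
                        str(ie),
                        f"{g.score:.1f}",
                        note,
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    def write_trnascan(self, path) -> None:
        Path(path).write_text(self.trnascan_text())

    def structures_text(self) -> str:
        return "".join(
            f"{gid}\t{ss}\n" for gid, ss in self.ss_strings.items()
        )

    def write_structures(self, path) -> None:
        Path(path).write_text(self.structures_text())


def _duplicate_kmer_contigs(reference: Mapping[str, str], k: int) -> set:
    """Contigs containing a k-mer seen more than once genome-wide (either
    strand)."""
    seen: dict = {}
    dup_contigs: set = set()
    for name, seq in reference.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            key = min(kmer, revcomp(kmer))
            prev = seen.get(key)
            if prev is None:
                seen[key] = name
            elif prev != "!":
                dup_contigs.add(name)
                if prev != name:
                    dup_contigs.add(prev)
                seen[key] = "!"
            else:
                dup_contigs.add(name)
    return dup_contigs


def simulate_genes(design: SimDesign, seed: Optional[int] = None) -> SimulatedGenome:
    """Generate the reference genome, annotation and structures.

    Deterministic given the seed.  Each gene sits on its own contig named
    by its gene id.  Unless ``allow_duplicate_isoacceptors`` is set, gene
    sequences are re-drawn until every k-mer at the minimum read length is
    unique genome-wide, keeping the exact-match fixture mapper unambiguous.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    if design.n_genes == 0:
        return SimulatedGenome({}, [], {}, {}, {}, {}, design)

    excluded = set(
        rng.choice(design.n_genes, size=design.n_excluded, replace=False).tolist()
    )
    excl_list = sorted(excluded)
    kinds = {}
    n_pseudo = int(round(0.6 * len(excl_list)))
    n_sec = int(round(0.2 * len(excl_list)))
    for rank, idx in enumerate(excl_list):
        if rank < n_pseudo:
            kinds[idx] = "pseudo"
        elif rank < n_pseudo + n_sec:
            kinds[idx] = "sec"
        else:
            kinds[idx] = "intron"

    n_edge = int(round(design.near_edge_fraction * design.n_genes))
    near_edge = set(rng.choice(design.n_genes, size=n_edge, replace=False).tolist()) if n_edge else set()

    recipes = []
    width = max(5, len(str(design.n_genes)))
    for i in range(design.n_genes):
        kind = kinds.get(i, "ok")
        if kind == "sec":
            isotype, anticodon = "SeC", "TCA"
        elif kind == "intron":
            isotype, anticodon = INTRON_ISOTYPES[int(rng.integers(len(INTRON_ISOTYPES)))]
        else:
            isotype, anticodon = ISOTYPES[int(rng.integers(len(ISOTYPES)))]
        flank5 = flank3 = design.flank
        if i in near_edge:
            short = int(rng.integers(0, design.fragment_window))
            if rng.random() < 0.5:
                flank5 = short
            else:
                flank3 = short
        rec = _GeneRecipe(
            index=i,
            gene_id=f"SYN{i + 1:0{width}d}",
            strand="+" if rng.random() < 0.5 else "-",
            mature_len=int(rng.integers(72, 77)),
            flank5=flank5,
            flank3=flank3,
            isotype=isotype,
            anticodon=anticodon,
            kind=kind,
            score=float(np.round(rng.uniform(40, 90), 1)),
        )
        rec.draw_sequence(rng)
        recipes.append(rec)

    if not design.allow_duplicate_isoacceptors:
        k = design.read_length_range[0]
        for attempt in range(25):
            reference = {r.gene_id: r.contig for r in recipes}
            dups = _duplicate_kmer_contigs(reference, k)
            if not dups:
                break
            for r in recipes:
                if r.gene_id in dups:
                    r.draw_sequence(rng)
        else:
            raise SizingError("could not make bin sequences unique genome-wide")

    reference = {r.gene_id: r.contig for r in recipes}
    genes, structures, ss_strings, mature_seqs, flanks = [], {}, {}, {}, {}
    for r in recipes:
        start, end = r.gene_span
        introns = ((start + 20, start + 30),) if r.kind == "intron" else ()
        genes.append(
            TRNAGene(
                gene_id=r.gene_id,
                seq_id=r.gene_id,
                start=start,
                end=end,
                strand=r.strand,
                isotype=r.isotype,
                anticodon=r.anticodon,
                is_pseudo=(r.kind == "pseudo"),
                is_selenocysteine=(r.kind == "sec"),
                intron_spans=introns,
                score=r.score,
            )
        )
        L = r.mature_len
        structures[r.gene_id] = StructureAnnotation(0, L, (13, 21), (32, 39), (53, 60))
        ss_strings[r.gene_id] = _canonical_ss(L)
        mature_seqs[r.gene_id] = r.mature
        flanks[r.gene_id] = (r.flank5, r.flank3)
    return SimulatedGenome(reference, genes, structures, ss_strings, mature_seqs, flanks, design)


def build_bins(
    genome: SimulatedGenome, window: Optional[int] = None, flank: Optional[int] = None
) -> list:
    """Structure-anchored bins over the retained genes of a simulated set."""
    win = genome.design.fragment_window if window is None else window
    flk = genome.design.flank if flank is None else flank
    bins = []
    for g in filter_trnas(genome.genes):
        af5, af3 = genome.available_flanks[g.gene_id]
        bins.extend(
            make_bins(
                g,
                genome.structures[g.gene_id],
                window=win,
                flank=flk,
                available_flank_5=af5,
                available_flank_3=af3,
            )
        )
    return bins


@dataclass
class SimReads:
    """Per-sample synthetic reads plus the emission truth table."""

    samples: dict  # sample_id -> list of (read_id, sequence)
    sample_table: pd.DataFrame
    truth: pd.DataFrame

    def fastq_text(self, sample_id: str) -> str:
        out = []
        for read_id, seq in self.samples[sample_id]:
            out.append(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        return "".join(out)

    def write_fastq(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sid in self.samples:
            p = outdir / f"{sid}.fastq"
            p.write_text(self.fastq_text(sid))
            paths[sid] = p
        return paths


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with the RNA-seq (mean, dispersion) parameterization:
    variance = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    r = 1.0 / dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _emit_read(
    rng: np.random.Generator,
    contig: str,
    b: Bin,
    lo: int,
    hi: int,
) -> str:
    """One exact-subsequence read from a bin.

    The 5' end is uniform within +/-2 nt of the bin's transcriptional
    start and the length uniform in [lo, hi], truncated so the 3' end
    also stays within +2 nt of the bin end.  Keeping both fragment ends
    within 2 nt of the bin models imprecise biogenesis while guaranteeing
    the source bin keeps maximal overlap under the assignment rule
    (adjacent loop/boundary bins can overlap by up to 9 nt).
    """
    d = int(rng.integers(-2, 3))
    max_len = min(hi, b.width + 2 - d)
    ell = int(rng.integers(lo, max(lo, max_len) + 1))
    clen = len(contig)
    if b.strand == "+":
        g5 = max(0, min(b.start + d, clen - ell))
        frag = contig[g5 : g5 + ell]
    else:
        pos5 = min(clen - 1, max(b.end - 1 - d, ell - 1))
        frag = revcomp(contig[pos5 - ell + 1 : pos5 + 1])
    return frag


def simulate_reads(
    design: SimDesign,
    genome: SimulatedGenome,
    bins: Sequence[Bin],
    seed: Optional[int] = None,
) -> SimReads:
    """Draw per-sample reads for every planned source tRF plus background.

    Counts are negative binomial around the group mean; the truth table
    records exactly how many reads were emitted per (bin, sample).
    Deterministic given the seed.
    """
    rng = np.random.default_rng((design.seed + 1) if seed is None else seed)
    sample_rows = []
    for label, n in design.groups:
        for r in range(n):
            sample_rows.append({"sample_id": f"{label}_{r + 1}", "group": label, "replicate": r + 1})
    if not sample_rows:
        raise ValidationError("zero-sample design")
    sample_table = pd.DataFrame(sample_rows).set_index("sample_id")
    labels = {row["group"] for row in sample_rows}
    if labels == {"female", "male"}:
        # the paired-strain sex design: replicate r of each sex is strain r
        sample_table["sex"] = sample_table["group"]
        sample_table["strain"] = ["strain" + str(r) for r in sample_table["replicate"]]

    bin_by_id = {b.bin_id: b for b in bins}
    plan = design.source_plan
    if plan is None:
        retained = [g.gene_id for g in filter_trnas(genome.genes)]
        usable = []
        for gid in retained:
            usable.append(gid)
        plan = default_sex_plan(usable[: len(DEFAULT_SEX_PLAN_TABLE)])
    resolved = []
    used = set()
    retained_ids = [g.gene_id for g in filter_trnas(genome.genes)]
    for p in plan:
        if p.gene_id is None:
            # assign to the next unused retained gene carrying that bin
            gid = next(
                (
                    g
                    for g in retained_ids
                    if g not in used and f"{g}:{p.region_label}" in bin_by_id
                ),
                None,
            )
            if gid is None:
                raise PlanError(
                    f"no retained gene has an unused {p.region_label} bin for the plan"
                )
            p = replace(p, gene_id=gid)
        used.add(p.gene_id)
        bid = f"{p.gene_id}:{p.region_label}"
        if bid not in bin_by_id:
            raise PlanError(f"planned source bin {bid} was not constructed")
        resolved.append((p, bin_by_id[bid]))

    lo, hi = design.read_length_range
    contigs = list(genome.reference)
    samples: dict = {}
    truth_rows = []
    for row in sample_rows:
        sid, group, rep = row["sample_id"], row["group"], row["replicate"]
        reads: list = []
        for p, b in resolved:
            mean = float(p.group_means.get(group, 0.0))
            n_reads = _nb_draw(rng, mean, p.dispersion)
            contig = genome.reference[b.seq_id]
            for j in range(n_reads):
                frag = _emit_read(rng, contig, b, lo, hi)
                reads.append((f"{sid}:{b.bin_id}:{j}", frag))
            truth_rows.append(
                {
                    "bin_id": b.bin_id,
                    "sample_id": sid,
                    "group": group,
                    "replicate": rep,
                    "true_mean": mean,
                    "drawn_count": n_reads,
                    "is_differential": p.is_differential,
                    "direction": p.direction,
                }
            )
        n_bg = int(rng.poisson(design.background_rate))
        for j in range(n_bg):
            name = contigs[int(rng.integers(len(contigs)))]
            seq = genome.reference[name]
            ell = int(rng.integers(lo, hi + 1))
            if len(seq) <= ell:
                continue
            pos = int(rng.integers(0, len(seq) - ell + 1))
            frag = seq[pos : pos + ell]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            reads.append((f"{sid}:bg:{j}", frag))
        samples[sid] = reads
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "bin_id",
            "sample_id",
            "group",
            "replicate",
            "true_mean",
            "drawn_count",
            "is_differential",
            "direction",
        ],
    )
    return SimReads(samples=samples, sample_table=sample_table, truth=truth)


def truth_counts(truth: pd.DataFrame) -> pd.DataFrame:
    """Pivot the truth table into a bins x samples drawn-count matrix."""
    if truth.empty:
        return pd.DataFrame()
    return (
        truth.pivot_table(
            index="bin_id", columns="sample_id", values="drawn_count", aggfunc="sum"
        )
        .fillna(0)
        .astype(int)
    )
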