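"""Assignment of aligned small-RNA reads to tRF bins.

Alignments are consumed from SAM/BAM (the product of any external small-RNA
aligner); a minimal exact-match mapper is provided so that synthetic
fixtures need no aligner at all.  Each primary mapped read is assigned to
at most one bin — the bin with maximal overlap, requiring a minimum overlap
so that most of a bin must be covered for a read to count toward it.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import Bin
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment; unmapped records carry no coordinates."""

    read_id: str
    seq_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: str = "+"
    mapq: int = 255
    is_unmapped: bool = False
    is_secondary: bool = False

    def __post_init__(self):
        if not self.is_unmapped:
            if self.seq_id is None or self.start is None or self.end is None:
                raise ValidationError(f"{self.read_id}: mapped record without coordinates")
            if self.end <= self.start:
                raise ValidationError(f"{self.read_id}: empty aligned span")


def read_alignments(path) -> Iterable[AlignmentRecord]:
    """Stream alignment records from a SAM or BAM file in file order."""
    try:
        af = pysam.AlignmentFile(os.fspath(path), check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read alignments from {path}: {exc}") from exc
    with af:
        try:
            for a in af:
                if a.is_unmapped:
                    yield AlignmentRecord(read_id=a.query_name, is_unmapped=True)
                else:
                    yield AlignmentRecord(
                        read_id=a.query_name,
                        seq_id=a.reference_name,
                        start=a.reference_start,
                        end=a.reference_end,
                        strand="-" if a.is_reverse else "+",
                        mapq=a.mapping_quality,
                        is_secondary=a.is_secondary,
                    )
        except (ValueError, OSError) as exc:
            raise FormatError(f"error while reading {path}: {exc}") from exc


class MappingResult(NamedTuple):
    """Output of :func:`exact_match_map`."""

    records: list
    n_multi_hit: int
    n_no_hit: int


class ExactMatcher:
    """Exact-substring read mapper over a small reference.

    Indexes every forward-strand k-mer once; a query is located by seeding
    on its first k-mer (and that of its reverse complement) and verifying
    the full match.  Intended for synthetic fixtures where every fragment
    sequence is unique genome-wide, not as a general-purpose aligner.
    """

    def __init__(self, reference: Mapping[str, str], k: int = 10):
        self.k = k
        self.ref = {name: str(seq).upper() for name, seq in reference.items()}
        index: dict = defaultdict(list)
        for name, seq in self.ref.items():
            for i in range(len(seq) - k + 1):
                index[seq[i : i + k]].append((name, i))
        self._index = dict(index)

    def find(self, seq: str) -> list:
        """All (seq_id, start, strand) exact occurrences on both strands."""
        s = seq.upper().replace("U", "T")
        hits = []
        if len(s) < self.k:
            for name, ref in self.ref.items():
                for q, strand in ((s, "+"), (revcomp(s), "-")):
                    i = ref.find(q)
                    while i != -1:
                        hits.append((name, i, strand))
                        i = ref.find(q, i + 1)
            return hits
        for q, strand in ((s, "+"), (revcomp(s), "-")):
            for name, pos in self._index.get(q[: self.k], ()):
                if self.ref[name].startswith(q, pos):
                    hits.append((name, pos, strand))
        return hits


def _iter_reads(reads):
    """Yield (read_id, sequence) from FASTQ paths/handles or pairs."""
    if isinstance(reads, (str, Path)) or hasattr(reads, "read"):
        from Bio import SeqIO

        for rec in SeqIO.parse(reads, "fastq"):
            yield rec.id, str(rec.seq)
        return
    for item in reads:
        if isinstance(item, tuple):
            yield item[0], item[1]
        else:  # Bio.SeqRecord
            yield item.id, str(item.seq)


def exact_match_map(reads, reference, k: int = 10) -> MappingResult:
    """Map reads by exact substring search on both strands of the reference.

    A unique hit yields one mapped record; zero or multiple hits yield an
    unmapped record (ambiguous reads are discarded rather than assigned
    arbitrarily, and the multi-hit count is reported).
    """
    matcher = reference if isinstance(reference, ExactMatcher) else ExactMatcher(reference, k=k)
    records: list = []
    n_multi = n_none = 0
    for read_id, seq in _iter_reads(reads):
        hits = matcher.find(seq)
        if len(hits) == 1:
            name, pos, strand = hits[0]
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    seq_id=name,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                )
            )
        else:
            records.append(AlignmentRecord(read_id=read_id, is_unmapped=True))
            if hits:
                n_multi += 1
            else:
                n_none += 1
    if n_multi:
        log.info("exact_match_map: %d multi-hit reads discarded", n_multi)
    return MappingResult(records, n_multi, n_none)


class BinIndex:
    """Interval index over bins for overlap queries, keyed by contig."""

    def __init__(self, bins: Iterable[Bin]):
        self.bins = list(bins)
        self._trees: dict = {}
        for b in self.bins:
            self._trees.setdefault(b.seq_id, IntervalTree()).addi(b.start, b.end, b)

    def overlapping(self, seq_id: str, start: int, end: int) -> list:
        tree = self._trees.get(seq_id)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_read(
    aln: AlignmentRecord,
    bins: BinIndex,
    min_overlap: int = 10,
    stranded: bool = True,
) -> Optional[str]:
    """Assign one mapped primary read to the bin with maximal overlap.

    Returns the winning ``bin_id`` or ``None`` when no bin overlaps the
    aligned span by at least ``min_overlap`` nt.  With ``stranded`` only
    same-strand bins are eligible.  Ties are broken by smaller bin start,
    then lexicographic bin id.
    """
    if aln.is_unmapped or aln.is_secondary:
        return None
    best = None
    for b in bins.overlapping(aln.seq_id, aln.start, aln.end):
        if stranded and b.strand != aln.strand:
            continue
        ov = min(aln.end, b.end) - max(aln.start, b.start)
        if ov < min_overlap:
            continue
        key = (-ov, b.start, b.bin_id)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


@dataclass
class CountMatrix:
    """Bins x samples integer read counts plus per-sample bookkeeping.

    ``library_sizes`` holds the number of mapped primary reads per sample
    (the denominator used downstream); ``assigned`` the subset of those
    assigned to a bin.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    assigned: pd.Series
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")
        if list(self.counts.columns) != list(self.library_sizes.index):
            raise ValidationError("library_sizes do not match count columns")
        colsums = self.counts.sum(axis=0)
        if (self.library_sizes < colsums).any():
            raise ValidationError("library sizes below assigned column sums")

    @property
    def bin_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def subset_bins(self, bin_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[bin_ids],
            library_sizes=self.library_sizes,
            assigned=self.assigned,
            sample_meta=self.sample_meta,
        )

    def write(self, counts_path, libsizes_path) -> None:
        out = self.counts.copy()
        out.index.name = "bin_id"
        out.to_csv(counts_path, sep="\t")
        side = pd.DataFrame(
            {"mapped": self.library_sizes, "assigned": self.assigned}
        )
        side.index.name = "sample_id"
        side.to_csv(libsizes_path, sep="\t")

    @classmethod
    def read(cls, counts_path, libsizes_path, sample_meta=None) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="bin_id")
        side = pd.read_csv(libsizes_path, sep="\t", index_col="sample_id")
        meta = sample_meta if sample_meta is not None else pd.DataFrame(index=counts.columns)
        return cls(
            counts=counts.astype(int),
            library_sizes=side["mapped"].reindex(counts.columns),
            assigned=side["assigned"].reindex(counts.columns),
            sample_meta=meta,
        )


def build_count_matrix(
    samples,
    bins: Sequence[Bin],
    sample_meta: Optional[pd.DataFrame] = None,
    min_overlap: int = 10,
    stranded: bool = True,
) -> CountMatrix:
    """Assemble the bins x samples count matrix.

    ``samples`` is a mapping or sequence of ``(sample_id, source)`` pairs
    where each source is an iterable of :class:`AlignmentRecord` or a
    SAM/BAM path.  Counting is order-invariant: each primary mapped read is
    assigned independently via :func:`assign_read`.
    """
    if isinstance(samples, Mapping):
        pairs = list(samples.items())
    else:
        pairs = list(samples)
    ids = [sid for sid, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample_ids in count configuration")
    if not pairs:
        raise ValidationError("at least one sample required")
    if not bins:
        raise ValidationError("bins must be non-empty")

    index = BinIndex(bins)
    bin_ids = [b.bin_id for b in bins]
    row_of = {bid: i for i, bid in enumerate(bin_ids)}
    mat = np.zeros((len(bin_ids), len(ids)), dtype=int)
    mapped = pd.Series(0, index=ids, dtype=int)
    assigned = pd.Series(0, index=ids, dtype=int)
    for col, (sid, source) in enumerate(pairs):
        records = read_alignments(source) if isinstance(source, (str, Path)) else source
        n_mapped = n_assigned = 0
        for aln in records:
            if aln.is_unmapped or aln.is_secondary:
                continue
            n_mapped += 1
            bid = assign_read(aln, index, min_overlap=min_overlap, stranded=stranded)
            if bid is not None:
                mat[row_of[bid], col] += 1
                n_assigned += 1
        mapped[sid] = n_mapped
        assigned[sid] = n_assigned
    counts = pd.DataFrame(mat, index=bin_ids, columns=ids)
    meta = sample_meta if sample_meta is not None else pd.DataFrame(index=ids)
    return CountMatrix(counts=counts, library_sizes=mapped, assigned=assigned, sample_meta=meta)
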