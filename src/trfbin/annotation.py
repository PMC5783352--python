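"""tRNA gene annotation, clover-leaf landmarks, and structure-anchored tRF bins.

tRNA-derived fragments (tRFs) are short (13-32 nt) small RNAs released by
site-specific cleavage from mature tRNAs or from the leader/trailer regions
of their precursor transcripts.  Because the cleavage sites track the
clover-leaf secondary structure, fragments can be quantified by assigning
sequencing reads to a small set of fixed-width genomic windows ("bins")
anchored at structural landmarks of each tRNA gene:

=========  =============================================================
label      anchor
=========  =============================================================
5-Pre      ends at the mature 5' boundary (precursor leader)
5tRF       starts at the mature 5' boundary
D-loop     centered on the dihydrouridine loop midpoint
A-loop     centered on the anticodon loop midpoint
T-loop     centered on the T-Psi-C loop midpoint
3tRF       ends at the mature 3' boundary
3-Pre      starts at the mature 3' boundary (precursor trailer)
=========  =============================================================

This module parses tRNAscan-SE tabular annotations, applies the standard
exclusion filter (pseudogenes, selenocysteine tRNAs, intron-containing
tRNAs), locates the three loops either from a secondary-structure string or
from canonical clover-leaf geometry, emits the labeled bins, and serializes
them as GTF.

Internal coordinates are 0-based half-open on the forward genomic strand;
GTF output is 1-based inclusive.  "5'" always refers to the transcriptional
5' end of the gene, so all bin anchoring is strand-aware.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from .errors import (
    ConsistencyError,
    InvalidRecordError,
    ParseError,
    StructureError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: The seven structural region labels, in transcript 5'->3' order.
REGION_LABELS = ("5-Pre", "5tRF", "D-loop", "A-loop", "T-loop", "3tRF", "3-Pre")

_VALID_ANTICODON = set("ACGTN")

# Canonical clover-leaf fallback geometry, 0-based offsets within the mature
# sequence (equivalent to 1-based mature positions 14-21, 33-39, 54-60).
_CANONICAL_D_LOOP = (13, 21)
_CANONICAL_A_LOOP = (32, 39)
_CANONICAL_T_LOOP = (53, 60)

_SS_OPEN = frozenset(">([{")
_SS_CLOSE = frozenset("<)]}")


@dataclass(frozen=True)
class TRNAGene:
    """One annotated tRNA locus.

    Coordinates are 0-based half-open on the forward genomic strand
    regardless of the gene's transcriptional orientation.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    is_pseudo: bool = False
    is_selenocysteine: bool = False
    intron_spans: tuple = ()
    score: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidRecordError(
                f"{self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise InvalidRecordError(f"{self.gene_id}: bad strand {self.strand!r}")
        ac = self.anticodon.upper().replace("U", "T")
        if len(ac) != 3 or not set(ac) <= _VALID_ANTICODON:
            raise InvalidRecordError(
                f"{self.gene_id}: bad anticodon {self.anticodon!r}"
            )
        object.__setattr__(self, "anticodon", ac)
        for s, e in self.intron_spans:
            if not (self.start <= s < e <= self.end):
                raise InvalidRecordError(
                    f"{self.gene_id}: intron [{s},{e}) outside gene span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_intron(self) -> bool:
        return len(self.intron_spans) > 0

    @property
    def is_excluded(self) -> bool:
        """True when any exclusion flag applies."""
        return self.is_pseudo or self.is_selenocysteine or self.has_intron


@dataclass(frozen=True)
class StructureAnnotation:
    """Clover-leaf landmarks within one mature tRNA sequence.

    All loop intervals are 0-based half-open offsets relative to the mature
    5' end (i.e. in mature-sequence coordinates).
    """

    mature_start_offset: int
    mature_end_offset: int
    d_loop: tuple
    a_loop: tuple
    t_loop: tuple

    def __post_init__(self):
        L = self.mature_length
        if L <= 0:
            raise StructureError("empty mature span")
        loops = (self.d_loop, self.a_loop, self.t_loop)
        for name, (s, e) in zip(("D", "A", "T"), loops):
            if not (0 <= s < e <= L):
                raise StructureError(f"{name}-loop [{s},{e}) outside mature [0,{L})")
        if not (self.d_loop[0] < self.a_loop[0] < self.t_loop[0]):
            raise StructureError("loops out of 5'->3' order")

    @property
    def mature_length(self) -> int:
        return self.mature_end_offset - self.mature_start_offset


@dataclass(frozen=True)
class Bin:
    """One fixed-width genomic interval labeled with its structural region."""

    bin_id: str
    gene_id: str
    region_label: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.region_label not in REGION_LABELS:
            raise ValidationError(f"unknown region label {self.region_label!r}")
        if self.start >= self.end:
            raise ValidationError(f"{self.bin_id}: empty interval")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.bin_id}: bad strand")

    @property
    def width(self) -> int:
        return self.end - self.start


def _open_text(source) -> IO[str]:
    if isinstance(source, (str, Path)):
        return open(source, "rt")
    return source


def parse_trnascan_table(source) -> list:
    """Parse tRNAscan-SE tabular output into :class:`TRNAGene` records.

    Accepts a path or an open text stream.  Both the classic 9-column and
    the note-extended 10-column dialects are handled; the "pseudo" flag is
    read from the note column when present.  Rows with begin > end encode
    the minus strand and are reflected into the internal 0-based half-open
    forward-strand convention.

    Since the table carries no gene identifier, the sequence name is used
    as ``gene_id`` when it annotates a single tRNA, and ``<name>.trna<N>``
    otherwise.
    """
    handle = _open_text(source)
    rows = []
    data_started = False
    for lineno, line in enumerate(handle, 1):
        s = line.rstrip("\n")
        if not s.strip():
            continue
        fields = s.split()
        if not data_started:
            # Skip the up-to-three header lines (column titles + dashes).
            if fields[0].startswith("-") or len(fields) < 9 or not _is_int(fields[2]):
                continue
            data_started = True
        try:
            rows.append(_parse_row(fields, lineno))
        except (ParseError, ConsistencyError):
            raise
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed tRNAscan row at line {lineno}: {exc}") from exc

    name_counts: dict = {}
    for r in rows:
        name_counts[r["name"]] = name_counts.get(r["name"], 0) + 1
    genes = []
    for r in rows:
        gene_id = (
            r["name"] if name_counts[r["name"]] == 1 else f"{r['name']}.trna{r['num']}"
        )
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                seq_id=r["name"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                isotype=r["isotype"],
                anticodon=r["anticodon"],
                is_pseudo=r["is_pseudo"],
                is_selenocysteine=r["is_sec"],
                intron_spans=r["introns"],
                score=r["score"],
            )
        )
    return genes


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _parse_row(fields: Sequence[str], lineno: int) -> dict:
    if len(fields) < 9:
        raise ParseError(f"malformed tRNAscan row at line {lineno}: expected >=9 columns")
    name = fields[0]
    num = fields[1]
    begin, end = int(fields[2]), int(fields[3])
    if begin == end:
        raise InvalidRecordError(f"line {lineno}: begin == end ({begin})")
    strand = "+" if begin < end else "-"
    start, stop = (begin - 1, end) if strand == "+" else (end - 1, begin)
    isotype = fields[4]
    anticodon = fields[5].upper().replace("U", "T")
    ib, ie = int(fields[6]), int(fields[7])
    introns: tuple = ()
    if ib != 0 and ie != 0:
        lo, hi = min(ib, ie), max(ib, ie)
        introns = ((lo - 1, hi),)
    score = float(fields[8])
    note = " ".join(fields[9:]).lower()
    return {
        "name": name,
        "num": num,
        "start": start,
        "end": stop,
        "strand": strand,
        "isotype": isotype,
        "anticodon": anticodon,
        "introns": introns,
        "score": score,
        "is_pseudo": "pseudo" in note,
        "is_sec": isotype.lower().startswith("sec"),
    }


def filter_trnas(genes: Iterable[TRNAGene]) -> list:
    """Drop pseudogenes, selenocysteine tRNAs and intron-containing tRNAs.

    Input order is preserved.  This is the standard simplification applied
    before bin construction so that every retained gene's annotated span is
    its mature sequence.
    """
    return [g for g in genes if not g.is_excluded]


def _hairpin_loops(ss: str) -> list:
    """Unpaired runs enclosed by an opening arm and a closing arm.

    In a clover leaf these are exactly the D-, anticodon- and T-loops;
    inter-arm spacers and the variable region sit between a closing and an
    opening arm and are not returned.
    """
    loops = []
    i, n = 0, len(ss)
    while i < n:
        c = ss[i]
        if c not in _SS_OPEN and c not in _SS_CLOSE:
            j = i
            while j < n and ss[j] not in _SS_OPEN and ss[j] not in _SS_CLOSE:
                j += 1
            if i > 0 and j < n and ss[i - 1] in _SS_OPEN and ss[j] in _SS_CLOSE:
                loops.append((i, j))
            i = j
        else:
            i += 1
    return loops


def locate_structure(
    gene: TRNAGene,
    mature_seq: str,
    ss_string: Optional[str] = None,
) -> StructureAnnotation:
    """Locate the D-, anticodon- and T-loops within a mature tRNA sequence.

    With a secondary-structure string (tRNAscan ``>``/``<`` or dot-bracket
    notation) the loops are the three unpaired hairpin runs in 5'->3'
    order.  Without one, canonical clover-leaf geometry is assumed: a 7-bp
    acceptor stem, D-loop at mature positions 14-21, a 7-nt anticodon loop
    over positions 33-39 (anticodon at 34-36) and T-loop at 54-60 (1-based;
    converted internally to 0-based offsets).

    Raises :class:`StructureError` when fewer than three loops resolve and
    :class:`ConsistencyError` when the anticodon is absent from the
    inferred anticodon loop.
    """
    seq = mature_seq.upper().replace("U", "T")
    L = len(seq)
    if not (60 <= L <= 100):
        raise StructureError(f"{gene.gene_id}: mature length {L} outside 60-100 nt")
    if ss_string is not None:
        if len(ss_string) != L:
            raise StructureError(
                f"{gene.gene_id}: ss length {len(ss_string)} != mature length {L}"
            )
        loops = _hairpin_loops(ss_string)
        if len(loops) < 3:
            raise StructureError(
                f"{gene.gene_id}: only {len(loops)} loops resolvable from structure"
            )
        if len(loops) > 3:
            # keep the three longest (a real clover leaf has exactly three)
            loops = sorted(sorted(loops, key=lambda iv: (iv[0] - iv[1], iv[0]))[:3])
        d_loop, a_loop, t_loop = loops
    else:
        d_loop, a_loop, t_loop = _CANONICAL_D_LOOP, _CANONICAL_A_LOOP, _CANONICAL_T_LOOP
        if t_loop[1] > L:
            raise StructureError(f"{gene.gene_id}: mature too short for canonical geometry")
    if "N" not in gene.anticodon and gene.anticodon not in seq[a_loop[0] : a_loop[1]]:
        raise ConsistencyError(
            f"{gene.gene_id}: anticodon {gene.anticodon} not inside A-loop "
            f"[{a_loop[0]},{a_loop[1]})"
        )
    return StructureAnnotation(0, L, tuple(d_loop), tuple(a_loop), tuple(t_loop))


def _mature_to_genomic(gene: TRNAGene, structure: StructureAnnotation, x1: int, x2: int):
    """Map a mature-coordinate interval [x1,x2) to forward genomic coords."""
    if gene.strand == "+":
        base = gene.start + structure.mature_start_offset
        return base + x1, base + x2
    base = gene.end - structure.mature_start_offset
    return base - x2, base - x1


def make_bins(
    gene: TRNAGene,
    structure: StructureAnnotation,
    window: int = 15,
    flank: int = 30,
    available_flank_5: Optional[int] = None,
    available_flank_3: Optional[int] = None,
) -> list:
    """Emit up to seven fixed-width bins anchored at structural landmarks.

    Parameters
    ----------
    window:
        Bin width in nt.
    flank:
        Precursor flank search length; a Pre bin is emitted only when at
        least ``window`` nt of flank are available on that side.
    available_flank_5, available_flank_3:
        Actual flanking sequence available on the transcript 5' / 3' side
        (e.g. limited by a contig edge).  Defaults to ``flank``.

    Loop bins are centered on the loop midpoint with ties broken toward
    the 5' side, and are dropped when they would extend beyond the mature
    span.  Pre bins lie entirely outside the mature span.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    af5 = flank if available_flank_5 is None else min(flank, available_flank_5)
    af3 = flank if available_flank_3 is None else min(flank, available_flank_3)
    L = structure.mature_length
    mature_ok = window <= L
    if not mature_ok:
        log.warning(
            "%s: window %d exceeds mature length %d; no mature bins emitted",
            gene.gene_id,
            window,
            L,
        )
    spans = []  # (label, mature_start, mature_end)
    if af5 >= window:
        spans.append(("5-Pre", -window, 0))
    if mature_ok:
        spans.append(("5tRF", 0, window))
        for label, (ls, le) in (
            ("D-loop", structure.d_loop),
            ("A-loop", structure.a_loop),
            ("T-loop", structure.t_loop),
        ):
            # midpoint centering; floor division shifts odd remainders 5'-ward
            start = ls + math.floor((le - ls - window) / 2)
            if start >= 0 and start + window <= L:
                spans.append((label, start, start + window))
        spans.append(("3tRF", L - window, L))
    if af3 >= window:
        spans.append(("3-Pre", L, L + window))

    bins = []
    for label, ms, me in spans:
        gs, ge = _mature_to_genomic(gene, structure, ms, me)
        if gs < 0:
            log.warning("%s:%s would start before the contig; dropped", gene.gene_id, label)
            continue
        bins.append(
            Bin(
                bin_id=f"{gene.gene_id}:{label}",
                gene_id=gene.gene_id,
                region_label=label,
                seq_id=gene.seq_id,
                start=gs,
                end=ge,
                strand=gene.strand,
            )
        )
    bins.sort(key=lambda b: REGION_LABELS.index(b.region_label))
    return bins


def write_gtf(bins: Iterable[Bin], out) -> None:
    """Serialize bins as 9-column GTF (1-based inclusive coordinates).

    Lines are sorted deterministically by (seq_id, start, bin_id).
    """
    close = False
    if isinstance(out, (str, Path)):
        out = open(out, "wt")
        close = True
    try:
        for b in sorted(bins, key=lambda b: (b.seq_id, b.start, b.bin_id)):
            attrs = (
                f'gene_id "{b.gene_id}"; bin_id "{b.bin_id}"; '
                f'region_label "{b.region_label}";'
            )
            out.write(
                "\t".join(
                    [
                        b.seq_id,
                        "trfbin",
                        "tRF_bin",
                        str(b.start + 1),
                        str(b.end),
                        ".",
                        b.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            out.close()


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf(source) -> list:
    """Inverse of :func:`write_gtf`."""
    handle = _open_text(source)
    bins = []
    for lineno, line in enumerate(handle, 1):
        s = line.rstrip("\n")
        if not s.strip() or s.startswith("#"):
            continue
        cols = s.split("\t")
        if len(cols) != 9:
            raise ParseError(f"GTF line {lineno}: expected 9 columns, got {len(cols)}")
        attrs = dict(_ATTR_RE.findall(cols[8]))
        try:
            bins.append(
                Bin(
                    bin_id=attrs["bin_id"],
                    gene_id=attrs["gene_id"],
                    region_label=attrs["region_label"],
                    seq_id=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"GTF line {lineno}: {exc}") from exc
    return bins
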