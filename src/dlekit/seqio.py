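"""Sequence, annotation and alignment I/O, and the coordinate contract.

All coordinates inside the package are 0-based half-open intervals on the
given (sense) strand.  GFF3 output converts to 1-based inclusive.  DNA-form
input (T) is accepted and normalized to RNA (U); lowercase is uppercased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "Transcript",
    "Interval",
    "AlignmentSet",
    "ValidationError",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "write_hits_gff3",
    "read_hits_gff3",
    "select_longest_utr",
    "read_alignment_fasta",
    "write_alignment_fasta",
]


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FastaParseError(ValueError):
    """Malformed FASTA; the message names the offending record."""


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Interval:
    """0-based half-open [start, end) interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValidationError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class Transcript:
    """A named RNA sequence with an annotated 3'UTR start.

    ``utr_start`` is the 0-based offset where the 3'UTR begins within
    ``seq``; everything before it is trailing CDS context included for
    folding (``cds_end_context == utr_start`` by construction).
    """

    id: str
    seq: str
    utr_start: int = 0
    gene: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        bad = [i for i, c in enumerate(self.seq) if c not in RNA_ALPHABET]
        if bad:
            raise ValidationError(
                f"transcript {self.id!r}: non-ACGTU characters at positions {bad[:10]}"
            )
        if not (0 <= self.utr_start <= len(self.seq)):
            raise ValidationError(
                f"transcript {self.id!r}: utr_start {self.utr_start} outside "
                f"[0, {len(self.seq)}]"
            )

    @property
    def cds_end_context(self) -> int:
        return self.utr_start

    @property
    def utr_length(self) -> int:
        return len(self.seq) - self.utr_start

    @property
    def utr(self) -> str:
        return self.seq[self.utr_start:]

    def subseq(self, iv: Interval) -> str:
        if iv.end > len(self.seq):
            raise ValidationError(
                f"interval [{iv.start},{iv.end}) outside transcript {self.id!r} "
                f"of length {len(self.seq)}"
            )
        return self.seq[iv.start:iv.end]


@dataclass
class AlignmentSet:
    """A multiple alignment: rows of (id, gapped sequence) of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValidationError(f"unequal gapped row lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index][1].replace("-", "")


_TAG_RE = re.compile(r"(\w+)=(\S+)")


def _parse_header_tags(description: str) -> dict[str, str]:
    return dict(_TAG_RE.findall(description))


def read_fasta(path) -> list[Transcript]:
    """Read transcripts from FASTA.

    Optional ``key=value`` tags in the header are honoured:
    ``utr_start=N`` (default 0), ``gene=NAME``, ``source=TEXT``.
    """
    transcripts = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FastaParseError(f"{path}: record with empty identifier")
            tags = _parse_header_tags(rec.description)
            try:
                utr_start = int(tags.get("utr_start", "0"))
            except ValueError as exc:
                raise FastaParseError(
                    f"{path}: record {rec.id!r}: bad utr_start tag"
                ) from exc
            transcripts.append(
                Transcript(
                    id=rec.id,
                    seq=str(rec.seq),
                    utr_start=utr_start,
                    gene=tags.get("gene", ""),
                    source=tags.get("source", ""),
                )
            )
    if not transcripts:
        raise FastaParseError(f"{path}: no FASTA records found")
    return transcripts


def write_fasta(transcripts: list[Transcript], path) -> None:
    records = []
    for t in transcripts:
        desc = f"utr_start={t.utr_start}"
        if t.gene:
            desc += f" gene={t.gene}"
        if t.source:
            desc += f" source={t.source}"
        records.append(SeqRecord(Seq(t.seq), id=t.id, description=desc))
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def write_hits_gff3(hits, path) -> None:
    """Write DLE matches as GFF3 features (1-based inclusive on output).

    Each match becomes one ``RNA_motif`` feature spanning anchor..stem3,
    with anchor/spacer/stem/loop sub-intervals in the attributes column
    (still 1-based inclusive there, for consistency with columns 4-5).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in hits:
            start1 = h.anchor.start + 1          # 1-based inclusive
            end1 = h.stem3.end                   # half-open end == inclusive end
            attrs = [
                f"ID={h.transcript_id}.dle.{h.anchor.start}",
                f"descriptor={h.descriptor_name}",
                f"anchor={h.anchor.start + 1}-{h.anchor.end}",
                f"spacer={h.spacer.start + 1}-{h.spacer.end}",
                f"stem5={h.stem5.start + 1}-{h.stem5.end}",
                f"loop={h.loop.start + 1}-{h.loop.end}",
                f"stem3={h.stem3.start + 1}-{h.stem3.end}",
                "pairs=" + "|".join(f"{i + 1}:{j + 1}" for i, j in h.pairs),
            ]
            cols = [
                h.transcript_id,
                "dlekit",
                "RNA_motif",
                str(start1),
                str(end1),
                ".",
                "+",
                ".",
                ";".join(attrs),
            ]
            fh.write("\t".join(cols) + "\n")


def read_hits_gff3(path):
    """Round-trip reader for :func:`write_hits_gff3` output.

    Returns :class:`~dlekit.dle_scan.DleMatch` objects with internal
    0-based half-open coordinates restored.
    """
    from .dle_scan import DleMatch  # local import avoids a cycle

    def _iv(text: str) -> Interval:
        a, b = text.split("-")
        return Interval(int(a) - 1, int(b))

    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FastaParseError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(item.split("=", 1) for item in cols[8].split(";"))
            pairs = []
            if attrs.get("pairs"):
                for token in attrs["pairs"].split("|"):
                    i, j = token.split(":")
                    pairs.append((int(i) - 1, int(j) - 1))
            hits.append(
                DleMatch(
                    transcript_id=cols[0],
                    anchor=_iv(attrs["anchor"]),
                    spacer=_iv(attrs["spacer"]),
                    stem5=_iv(attrs["stem5"]),
                    loop=_iv(attrs["loop"]),
                    stem3=_iv(attrs["stem3"]),
                    pairs=tuple(pairs),
                    descriptor_name=attrs.get("descriptor", ""),
                )
            )
    return hits


def select_longest_utr(candidates: list[Transcript]) -> list[Transcript]:
    """One transcript per gene group, the one with the longest 3'UTR.

    Transcripts with an empty ``gene`` label form their own singleton
    groups keyed by transcript id.  Ties break to the lexicographically
    smallest transcript id, for determinism.  Output is ordered by first
    appearance of each group in the input.
    """
    best: dict[str, Transcript] = {}
    order: list[str] = []
    for t in candidates:
        key = t.gene or t.id
        if key not in best:
            best[key] = t
            order.append(key)
        else:
            cur = best[key]
            if t.utr_length > cur.utr_length or (
                t.utr_length == cur.utr_length and t.id < cur.id
            ):
                best[key] = t
    return [best[k] for k in order]


def read_alignment_fasta(path) -> AlignmentSet:
    rows = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            rows.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    if not rows:
        raise FastaParseError(f"{path}: no alignment rows")
    return AlignmentSet(rows=rows)


def write_alignment_fasta(aln: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        for rid, row in aln.rows:
            fh.write(f">{rid}\n{row}\n")
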