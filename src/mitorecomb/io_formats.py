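"""Readers/writers for the formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; this module layers
the pipeline's contracts on top (uppercase DNA over {A,C,G,T,N}, U->T,
unique ids, non-empty files).  GFA1 handling covers S and L lines only;
all coordinates in written reports are 1-based inclusive and percentages
are printed with exactly two decimals, round-half-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


class GraphError(ValueError):
    """Raised when a GFA graph is internally inconsistent."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as used in all reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(fraction: float) -> str:
    """Render a fraction as a percent string with 2 decimals, half-up."""
    q = Decimal("0.01")
    return str((Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named DNA sequence.

    Attributes
    ----------
    id : str
        Non-empty identifier, unique within a file.
    sequence : str
        Uppercase DNA over {A, C, G, T, N}.
    circular : bool
        Whether the molecule is circular (affects window extraction and
        read simulation, not storage).
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise FormatError(
            f"record {rec_id!r} contains invalid characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Sequences are uppercased, U is mapped to T, and any character outside
    {A, C, G, T, N} is rejected.  Empty files and duplicate ids raise
    :class:`FormatError`.
    """
    return _read_seqfile(path, "fasta")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a FASTQ file; qualities are discarded."""
    return _read_seqfile(path, "fastq")


def read_reads(path: str | Path) -> list[SeqRecord]:
    """Read long reads from FASTA or FASTQ, sniffing by first character."""
    p = Path(path)
    with open(p) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(p)
    return read_fasta(p)


def _read_seqfile(path: str | Path, fmt: str) -> list[SeqRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(rec.id, _normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"{path} contains no sequence records")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path, quality_char: str = "I") -> None:
    """Write records as FASTQ with flat qualities (placeholder scores)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{quality_char * len(rec.sequence)}\n")


# ---------------------------------------------------------------------------
# GFA1
# ---------------------------------------------------------------------------


@dataclass
class GfaSegment:
    name: str
    length: int
    sequence: str | None = None
    depth: float | None = None


@dataclass
class GfaLink:
    from_segment: str
    from_orient: str
    to_segment: str
    to_orient: str
    overlap: str = "0M"

    def key(self) -> tuple[str, str, str, str]:
        return (self.from_segment, self.from_orient, self.to_segment, self.to_orient)


@dataclass
class GfaGraph:
    """Minimal GFA1 model: S lines and L lines.

    Overlaps are accepted on input but treated as 0M throughout; the
    pipeline models non-overlapping contigs with repeats as separate
    segments.
    """

    segments: dict[str, GfaSegment] = field(default_factory=dict)
    links: list[GfaLink] = field(default_factory=list)

    def add_segment(self, seg: GfaSegment) -> None:
        if seg.name in self.segments:
            raise GraphError(f"duplicate segment {seg.name!r}")
        self.segments[seg.name] = seg

    def add_link(self, link: GfaLink) -> None:
        for end in (link.from_segment, link.to_segment):
            if end not in self.segments:
                raise GraphError(f"link references missing segment {end!r}")
        if link.from_orient not in "+-" or link.to_orient not in "+-":
            raise GraphError("link orientations must be '+' or '-'")
        self.links.append(link)


def read_gfa(path: str | Path) -> GfaGraph:
    """Parse GFA1 S/L lines; other line types are ignored with a warning."""
    graph = GfaGraph()
    pending_links: list[GfaLink] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag == "S":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                length = None
                depth = None
                for opt in fields[3:]:
                    if opt.startswith("LN:i:"):
                        length = int(opt[5:])
                    elif opt.startswith(("DP:f:", "dp:f:")):
                        depth = float(opt[5:])
                if seq == "*":
                    if length is None:
                        raise FormatError(
                            f"{path}:{lineno}: segment {name} has no sequence and no LN tag"
                        )
                    graph.add_segment(GfaSegment(name, length, None, depth))
                else:
                    seq = _normalize_sequence(seq, name)
                    graph.add_segment(GfaSegment(name, len(seq), seq, depth))
            elif tag == "L":
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: malformed L line")
                pending_links.append(GfaLink(fields[1], fields[2], fields[3], fields[4], fields[5]))
            elif tag in ("H", "#"):
                continue
            else:
                logger.warning("%s:%d: ignoring GFA line of type %r", path, lineno, tag)
    for link in pending_links:
        graph.add_link(link)
    return graph


def write_gfa(graph: GfaGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for seg in graph.segments.values():
            seq = seg.sequence if seg.sequence is not None else "*"
            line = f"S\t{seg.name}\t{seq}\tLN:i:{seg.length}"
            if seg.depth is not None:
                line += f"\tDP:f:{seg.depth}"
            fh.write(line + "\n")
        for link in graph.links:
            fh.write(
                f"L\t{link.from_segment}\t{link.from_orient}"
                f"\t{link.to_segment}\t{link.to_orient}\t{link.overlap}\n"
            )


# ---------------------------------------------------------------------------
# annotations (GFF3 / BED) — used for MTPT gene containment
# ---------------------------------------------------------------------------


@dataclass
class GeneAnnotation:
    name: str
    category: str  # "PCG" | "rRNA" | "tRNA" | other
    start: int  # 1-based inclusive
    end: int


_GFF_TYPE_MAP = {
    "gene": "PCG",
    "cds": "PCG",
    "rrna": "rRNA",
    "trna": "tRNA",
}


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED (sniffed by extension).

    BED rows may carry a fifth column with the category; GFF3 categories
    are derived from the feature type (tRNA/rRNA/gene).
    """
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed(path)
    return _read_gff3(path)


def _read_bed(path: Path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            category = f[4] if len(f) > 4 else "gene"
            # BED is 0-based half-open; reports are 1-based inclusive
            out.append(GeneAnnotation(name, category, int(f[1]) + 1, int(f[2])))
    return out


def _read_gff3(path: Path) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            ftype = f[2].lower()
            if ftype not in _GFF_TYPE_MAP:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or f[2]
            out.append(GeneAnnotation(name, _GFF_TYPE_MAP[ftype], int(f[3]), int(f[4])))
    return out


# ---------------------------------------------------------------------------
# support-table report
# ---------------------------------------------------------------------------

SUPPORT_COLUMNS = (
    "repeat_id",
    "path_label",
    "path_count",
    "conformation_total",
    "conformation_percent",
)


def write_support_table(table, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a finalized support table as TSV.

    One row per path label; the conformation total and percentage are
    repeated on each of the conformation's rows.  With zero valid reads
    the percent columns are written as NA.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(SUPPORT_COLUMNS) + "\n")
        for row in table.rows():
            fh.write(
                "\t".join(
                    [
                        row.repeat_id,
                        row.path_label,
                        str(row.path_count),
                        str(row.conformation_total),
                        row.percent_str,
                    ]
                )
                + "\n"
            )
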