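"""Spanning-read support for repeat-mediated recombination.

For each two-copy repeat, both conformations are materialized as repeat
windows (repeat copy plus up to 5 kb of flank on each side), long reads
are aligned to every window, and a read counts as support only when a
single contiguous alignment covers the repeat with at least ``min_flank``
bp of unique flank on both sides.  Path counts are tallied per
conformation and converted to isoform proportions with binomial
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from statsmodels.stats.proportion import proportion_confint

from .align import AlignParams, LocalAlignment, WindowIndex, align_query
from .graph_model import GenomeModel, Oriented, RepeatElement, enumerate_pairings
from .io_formats import SeqRecord, format_percent, revcomp


class WindowError(ValueError):
    pass


@dataclass
class RepeatWindow:
    """One repeat copy embedded in one conformation, with flanks.

    ``repeat_interval`` is 1-based inclusive within ``sequence``;
    ``left_flank_len + (repeat span) + right_flank_len`` equals the window
    length.  Flanks shorter than the requested size are recorded as
    truncated.
    """

    window_id: str
    sequence: str
    repeat_interval: tuple[int, int]
    left_flank_len: int
    right_flank_len: int
    conformation: str  # "reference" | "crossover"
    truncated_left: bool = False
    truncated_right: bool = False

    def __post_init__(self) -> None:
        rs, re = self.repeat_interval
        if rs != self.left_flank_len + 1:
            raise WindowError(f"{self.window_id}: repeat start inconsistent with left flank")
        if len(self.sequence) - re != self.right_flank_len:
            raise WindowError(f"{self.window_id}: repeat end inconsistent with right flank")


def _oriented_seq(model: GenomeModel, el: Oriented) -> str:
    seq = model.element_sequence(el.name)
    if seq is None:
        raise WindowError(f"element {el.name} has no sequence")
    return seq if el.orient == "+" else revcomp(seq)


def build_windows(
    model: GenomeModel, repeat: RepeatElement, flank: int = 5000
) -> list[RepeatWindow]:
    """Materialize the four windows of a repeat (two per conformation).

    Each window is ``tail(flank)`` of the oriented left neighbor, the
    repeat sequence, and ``head(flank)`` of the oriented right neighbor.
    Neighbors shorter than ``flank`` yield truncated flanks (recorded).
    """
    if flank < 1:
        raise WindowError("flank must be >= 1")
    windows: list[RepeatWindow] = []
    rep_seq = model.element_sequence(repeat.id)
    if rep_seq is None:
        raise WindowError(f"repeat {repeat.id} has no sequence")
    for pairing in enumerate_pairings(model, repeat):
        for (left, right), label in zip(pairing.placements, pairing.path_labels):
            lseq = _oriented_seq(model, left)
            rseq = _oriented_seq(model, right)
            lf = lseq[-flank:]
            rf = rseq[:flank]
            windows.append(
                RepeatWindow(
                    window_id=label,
                    sequence=lf + rep_seq + rf,
                    repeat_interval=(len(lf) + 1, len(lf) + len(rep_seq)),
                    left_flank_len=len(lf),
                    right_flank_len=len(rf),
                    conformation=pairing.name,
                    truncated_left=len(lf) < flank,
                    truncated_right=len(rf) < flank,
                )
            )
    return windows


def build_window_from_path(
    model: GenomeModel,
    elements: list[Oriented],
    window_id: str,
    conformation: str,
    flank: int = 5000,
) -> RepeatWindow:
    """Window over an explicit element path (multi-copy spanning mode).

    The first and last elements supply the flanks; everything between
    them — e.g. copy1-interior-copy2 of a short repeat — is the spanned
    repeat unit, so the flank rule applies outside the whole unit.
    """
    if len(elements) < 3:
        raise WindowError("path window needs flanking elements on both sides")
    lf = _oriented_seq(model, elements[0])[-flank:]
    rf = _oriented_seq(model, elements[-1])[:flank]
    core = "".join(_oriented_seq(model, el) for el in elements[1:-1])
    return RepeatWindow(
        window_id=window_id,
        sequence=lf + core + rf,
        repeat_interval=(len(lf) + 1, len(lf) + len(core)),
        left_flank_len=len(lf),
        right_flank_len=len(rf),
        conformation=conformation,
        truncated_left=len(lf) < flank,
        truncated_right=len(rf) < flank,
    )


# ---------------------------------------------------------------------------
# alignment and classification
# ---------------------------------------------------------------------------


@dataclass
class ReadAlignment:
    read_id: str
    window_id: str
    window_cover: tuple[int, int]  # 1-based inclusive on the window
    read_cover: tuple[int, int]
    strand: str
    identity: float
    score: int


def _to_read_alignment(aln: LocalAlignment, params: AlignParams) -> ReadAlignment:
    return ReadAlignment(
        read_id=aln.query_id,
        window_id=aln.target_id,
        window_cover=(aln.target_start, aln.target_end),
        read_cover=(aln.query_start, aln.query_end),
        strand=aln.strand,
        identity=aln.identity,
        score=aln.score(params),
    )


def align_reads(
    reads: Iterable[SeqRecord],
    windows: list[RepeatWindow],
    params: AlignParams = AlignParams(),
) -> list[ReadAlignment]:
    """Best local alignment of every read against every window.

    Both strands are searched; per read and window at most one alignment
    (the best-scoring strand) is returned, subject to the identity and
    length minima in ``params``.
    """
    windows = list(windows)
    if not windows:
        raise WindowError("no windows to align against")
    indexes = [
        WindowIndex(w.window_id, w.sequence, params.k, params.max_kmer_hits)
        for w in windows
    ]
    out: list[ReadAlignment] = []
    for read in reads:
        for aln in align_query(read.id, read.sequence, indexes, params):
            out.append(_to_read_alignment(aln, params))
    return out


def classify_support(
    aln: ReadAlignment, window: RepeatWindow, min_flank: int = 50
) -> bool:
    """The flank rule: a single contiguous alignment spanning the repeat.

    Supports iff the window cover starts at least ``min_flank`` bp before
    the repeat and ends at least ``min_flank`` bp after it.
    """
    rs, re = window.repeat_interval
    cs, ce = aln.window_cover
    return cs <= rs - min_flank and ce >= re + min_flank


@dataclass
class MultimapResult:
    assignments: dict[str, str]  # read_id -> window_id
    ambiguous: int = 0


def resolve_multimapping(
    alignments: list[ReadAlignment],
    windows: list[RepeatWindow],
    min_flank: int = 50,
    min_score_margin: int = 0,
) -> MultimapResult:
    """Assign each read to at most one window of a repeat.

    Only supporting alignments compete.  The highest-scoring one wins;
    reads whose top two scores differ by no more than
    ``min_score_margin`` are discarded as ambiguous and counted.
    """
    win_by_id = {w.window_id: w for w in windows}
    per_read: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        window = win_by_id.get(aln.window_id)
        if window is None:
            continue
        if classify_support(aln, window, min_flank):
            per_read.setdefault(aln.read_id, []).append(aln)
    result = MultimapResult({})
    for read_id, alns in per_read.items():
        alns.sort(key=lambda a: a.score, reverse=True)
        if len(alns) > 1 and alns[0].score - alns[1].score <= min_score_margin:
            result.ambiguous += 1
            continue
        result.assignments[read_id] = alns[0].window_id
    return result


# ---------------------------------------------------------------------------
# tallying
# ---------------------------------------------------------------------------


class SupportRow(NamedTuple):
    repeat_id: str
    path_label: str
    path_count: int
    conformation_total: int
    percent_str: str


@dataclass
class RepeatSupport:
    """Per-repeat support: path counts, conformation totals, proportions."""

    repeat_id: str
    mode: str  # "standard" | "multicopy"
    path_counts: dict[str, int]
    path_conformation: dict[str, str]
    totals: dict[str, int] = field(default_factory=dict)
    proportions: dict[str, float | None] = field(default_factory=dict)

    def conformations(self) -> list[str]:
        seen: list[str] = []
        for conf in self.path_conformation.values():
            if conf not in seen:
                seen.append(conf)
        return seen


def tally(
    path_counts: dict[str, int],
    path_conformation: dict[str, str],
    repeat_id: str,
    mode: str = "standard",
    combine: str = "sum",
) -> RepeatSupport:
    """Combine per-path counts into conformation totals and proportions.

    Standard mode sums the two path counts of each conformation (with
    ``combine="average"`` both totals are halved — the proportions are
    identical under either reading).  Multi-copy mode takes each
    conformation's single direct count.  Zero reads overall yields
    proportions of ``None`` (rendered NA).
    """
    if mode not in ("standard", "multicopy"):
        raise ValueError(f"unknown tally mode {mode!r}")
    if combine not in ("sum", "average"):
        raise ValueError(f"unknown combine rule {combine!r}")
    support = RepeatSupport(repeat_id, mode, dict(path_counts), dict(path_conformation))
    totals: dict[str, float] = {}
    for label, count in path_counts.items():
        conf = path_conformation[label]
        totals[conf] = totals.get(conf, 0.0) + count
    if mode == "standard" and combine == "average":
        totals = {conf: t / 2.0 for conf, t in totals.items()}
    grand = sum(totals.values())
    support.totals = {conf: int(t) if float(t).is_integer() else t for conf, t in totals.items()}
    for conf, t in totals.items():
        support.proportions[conf] = (t / grand) if grand > 0 else None
    return support


class SupportTable:
    """The Table-3-shaped report object: one entry per repeat."""

    def __init__(self, entries: list[RepeatSupport] | None = None):
        self.entries: list[RepeatSupport] = entries or []

    def add(self, entry: RepeatSupport) -> None:
        self.entries.append(entry)

    def rows(self) -> Iterable[SupportRow]:
        for entry in self.entries:
            for label, count in entry.path_counts.items():
                conf = entry.path_conformation[label]
                prop = entry.proportions.get(conf)
                yield SupportRow(
                    repeat_id=entry.repeat_id,
                    path_label=label,
                    path_count=count,
                    conformation_total=entry.totals.get(conf, 0),
                    percent_str="NA" if prop is None else format_percent(prop),
                )


@dataclass
class RatioEstimate:
    point: float
    lower: float
    upper: float
    n: int


def estimate_ratio(
    support: RepeatSupport, confidence: float = 0.95
) -> dict[str, RatioEstimate]:
    """Point estimates with Wilson score intervals per conformation."""
    grand = sum(support.totals.values())
    out: dict[str, RatioEstimate] = {}
    for conf, total in support.totals.items():
        if grand == 0:
            out[conf] = RatioEstimate(float("nan"), 0.0, 1.0, 0)
            continue
        lo, hi = proportion_confint(total, grand, alpha=1 - confidence, method="wilson")
        out[conf] = RatioEstimate(total / grand, float(lo), float(hi), int(grand))
    return out


# ---------------------------------------------------------------------------
# end-to-end per-repeat quantification
# ---------------------------------------------------------------------------


def quantify_repeat(
    model: GenomeModel,
    repeat: RepeatElement,
    reads: Iterable[SeqRecord],
    flank: int = 5000,
    min_flank: int = 50,
    params: AlignParams = AlignParams(),
) -> tuple[RepeatSupport, MultimapResult]:
    """Windows -> alignment -> flank rule -> multimapping -> tally."""
    windows = build_windows(model, repeat, flank)
    alignments = align_reads(reads, windows, params)
    resolved = resolve_multimapping(alignments, windows, min_flank)
    path_counts = {w.window_id: 0 for w in windows}
    path_conf = {w.window_id: w.conformation for w in windows}
    for window_id in resolved.assignments.values():
        path_counts[window_id] += 1
    return tally(path_counts, path_conf, repeat.id, "standard"), resolved
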