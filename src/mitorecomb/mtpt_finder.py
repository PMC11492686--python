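"""Mitochondrial plastid DNA (MTPT) identification.

Chloroplast-derived segments are found by seed-and-extend local search of
the mitogenome against the chloroplast genome on both strands, scored
with ungapped nucleotide defaults (match +1, mismatch -2) and filtered by
a Karlin-Altschul E-value (lambda ~ 1.28, K ~ 0.46).  Hits landing in the
chloroplast's large duplications (the inverted repeat) can be
deduplicated per mitochondrial locus, then merged intervals give the
total transferred length, genome fraction, and fully contained genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import GeneAnnotation, SeqRecord, revcomp, round_half_up
from .repeat_finder import find_dispersed


class SearchError(ValueError):
    pass


@dataclass
class MtptParams:
    word_size: int = 11
    evalue_max: float = 1e-5
    match: int = 1
    mismatch: int = -2
    xdrop: int = 30
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46


@dataclass
class MtptHit:
    mt_interval: tuple[int, int]  # 1-based inclusive on the mitogenome
    cp_interval: tuple[int, int]
    strand: str
    identity: float
    length: int
    score: int
    evalue: float


def _evalue(score: int, m: int, n: int, p: MtptParams) -> float:
    x = p.karlin_lambda * score
    try:
        return p.karlin_k * m * n * math.exp(-x)
    except OverflowError:
        return float("inf")


def _extend_seed(
    a: str, b: str, i: int, j: int, word: int, p: MtptParams
) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact word hit.

    Returns (a_start, length, matches, mismatches, score) with a_start
    0-based on ``a``; the b start follows from the shared diagonal.
    """
    # right extension
    score = best = word * p.match
    qi, ti = i + word, j + word
    best_right = 0
    steps = 0
    while qi + steps < len(a) and ti + steps < len(b):
        score += p.match if a[qi + steps] == b[ti + steps] else p.mismatch
        steps += 1
        if score > best:
            best, best_right = score, steps
        elif score < best - p.xdrop:
            break
    # left extension
    score = best
    steps = 0
    best_left = 0
    while i - steps > 0 and j - steps > 0:
        steps += 1
        score += p.match if a[i - steps] == b[j - steps] else p.mismatch
        if score > best:
            best, best_left = score, steps
        elif score < best - p.xdrop:
            break
    start = i - best_left
    length = best_left + word + best_right
    matches = sum(
        1 for t in range(length) if a[start + t] == b[j - best_left + t]
    )
    return start, length, matches, length - matches, best


def _search_strand(mt: str, cp: str, strand: str, p: MtptParams) -> list[MtptHit]:
    w = p.word_size
    index: dict[str, list[int]] = {}
    for j in range(len(cp) - w + 1):
        index.setdefault(cp[j : j + w], []).append(j)
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> extended spans
    hits: list[MtptHit] = []
    m, n = len(mt), len(cp)
    for i in range(len(mt) - w + 1):
        positions = index.get(mt[i : i + w])
        if not positions:
            continue
        for j in positions:
            d = i - j
            spans = covered.get(d)
            if spans and any(s <= i < e for s, e in spans):
                continue
            start, length, matches, mismatches, score = _extend_seed(mt, cp, i, j, w, p)
            covered.setdefault(d, []).append((start, start + length))
            ev = _evalue(score, m, n, p)
            if ev > p.evalue_max:
                continue
            cp_start = start - d
            if strand == "+":
                cp_iv = (cp_start + 1, cp_start + length)
            else:
                # cp was reverse-complemented for the scan: map back
                cp_iv = (n - (cp_start + length) + 1, n - cp_start)
            hits.append(
                MtptHit(
                    mt_interval=(start + 1, start + length),
                    cp_interval=cp_iv,
                    strand=strand,
                    identity=matches / length,
                    length=length,
                    score=score,
                    evalue=ev,
                )
            )
    return hits


def local_search(
    mt: SeqRecord, cp: SeqRecord, params: MtptParams = MtptParams()
) -> list[MtptHit]:
    """Seed-and-extend local alignments of mt against cp, both strands.

    Hits with E-value above ``params.evalue_max`` are dropped; nested
    re-extensions of seeds inside an already-extended diagonal span are
    suppressed.
    """
    if len(mt.sequence) < params.word_size or len(cp.sequence) < params.word_size:
        raise SearchError("genome shorter than the seed word size")
    hits = _search_strand(mt.sequence, cp.sequence, "+", params)
    hits += _search_strand(mt.sequence, revcomp(cp.sequence), "-", params)
    hits.sort(key=lambda h: (h.mt_interval, h.evalue))
    return hits


# ---------------------------------------------------------------------------
# chloroplast repeat handling
# ---------------------------------------------------------------------------


def mask_cp_repeats(cp: SeqRecord, min_len: int = 1000) -> list[tuple[int, int]]:
    """Intervals of large intra-chloroplast duplications (IR-like).

    Runs the dispersed-repeat finder on the cp genome alone at a high
    length floor and returns the union of both copies' intervals, so MTPT
    hits duplicated by the chloroplast's own repeats can be collapsed.
    """
    out: list[tuple[int, int]] = []
    for rep in find_dispersed([cp], min_len=min_len, max_mismatch=3):
        out.append(rep.interval1)
        out.append(rep.interval2)
    out.sort()
    merged: list[tuple[int, int]] = []
    for iv in out:
        if merged and iv[0] <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(iv)
    return merged


def _within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return inner[0] >= outer[0] and inner[1] <= outer[1]


def dedup_cp_repeat_hits(
    hits: list[MtptHit], cp_repeat_intervals: list[tuple[int, int]]
) -> list[MtptHit]:
    """Collapse hits that are cp-repeat duplicates of one mt locus.

    Hits whose cp interval lies inside a cp repeat copy are grouped by
    overlapping mt interval; each group keeps its best (lowest E-value)
    hit.  Hits outside cp repeats pass through untouched.
    """
    in_rep = [
        h
        for h in hits
        if any(_within(h.cp_interval, iv) for iv in cp_repeat_intervals)
    ]
    rest = [h for h in hits if h not in in_rep]
    in_rep.sort(key=lambda h: h.mt_interval)
    kept: list[MtptHit] = []
    group: list[MtptHit] = []
    group_end = -1
    for h in in_rep:
        if group and h.mt_interval[0] > group_end:
            kept.append(min(group, key=lambda g: (g.evalue, -g.length)))
            group = []
        group.append(h)
        group_end = max(group_end, h.mt_interval[1])
    if group:
        kept.append(min(group, key=lambda g: (g.evalue, -g.length)))
    return sorted(rest + kept, key=lambda h: h.mt_interval)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


@dataclass
class MtptSummary:
    merged_intervals: list[tuple[int, int]]
    total_length: int
    fraction_percent: float
    contained_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_fragments(self) -> int:
        return len(self.merged_intervals)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals (abutting intervals merge)."""
    merged: list[tuple[int, int]] = []
    for iv in sorted(intervals):
        if merged and iv[0] <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv[1]))
        else:
            merged.append(tuple(iv))
    return merged


def summarize(
    hits: list[MtptHit],
    mt_length: int,
    cp_repeat_intervals: list[tuple[int, int]] | None = None,
    annotations: list[GeneAnnotation] | None = None,
) -> MtptSummary:
    """Merge retained hits on the mitogenome and compute coverage totals.

    The MTPT total is a genome-coverage quantity: the union of hit
    intervals on mt coordinates.  The fraction is reported as a percent
    rounded half-up to two decimals.  If annotations are supplied, genes
    whose full chloroplast span lies inside some hit's cp interval are
    listed by category.
    """
    if cp_repeat_intervals:
        hits = dedup_cp_repeat_hits(hits, cp_repeat_intervals)
    merged = merge_intervals([h.mt_interval for h in hits])
    total = sum(b - a + 1 for a, b in merged)
    fraction = round_half_up(total / mt_length * 100, 2) if mt_length else 0.0
    genes: dict[str, list[str]] = {}
    if annotations:
        for gene in annotations:
            span = (gene.start, gene.end)
            if any(_within(span, h.cp_interval) for h in hits):
                genes.setdefault(gene.category, []).append(gene.name)
        for names in genes.values():
            names.sort()
    return MtptSummary(merged, total, fraction, genes)


def summarize_totals(total_length: int, mt_length: int) -> float:
    """Fraction (percent, 2 decimals) from a precomputed merged total."""
    return round_half_up(total_length / mt_length * 100, 2)
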