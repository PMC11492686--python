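"""Long-read to window alignment: k-mer anchoring with banded extension.

The engine seeds alignments with sampled exact k-mers, chains co-linear
anchors, fills inter-anchor gaps (direct comparison when lengths agree,
affine-gap dynamic programming otherwise), and extends past the terminal
anchors with an ungapped X-drop walk.  It is a contract implementation —
any aligner producing equivalent local coordinates could be swapped in.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from Bio import Align

from .io_formats import revcomp


class AlignmentError(ValueError):
    pass


@dataclass
class AlignParams:
    k: int = 15
    stride: int = 10
    min_identity: float = 0.70
    min_aligned: int = 100
    min_anchors: int = 2
    xdrop: int = 20
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    max_kmer_hits: int = 64


@dataclass
class LocalAlignment:
    """A local alignment of a read against one window (1-based inclusive)."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    mismatches: int
    gap_columns: int

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_columns

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def score(self, p: AlignParams) -> int:
        # affine cost approximated per gap column (open charged once per run
        # is not tracked; adequate for ranking near-identical candidates)
        return (
            p.match * self.matches
            + p.mismatch * self.mismatches
            + p.gap_extend * self.gap_columns
        )


class WindowIndex:
    """Sampled k-mer index over a target sequence (every position)."""

    def __init__(self, target_id: str, sequence: str, k: int, max_hits: int = 64):
        if len(sequence) < k:
            raise AlignmentError(
                f"window {target_id!r} ({len(sequence)} bp) shorter than k={k}"
            )
        self.target_id = target_id
        self.sequence = sequence
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            index.setdefault(sequence[i : i + k], []).append(i)
        # drop hyper-repetitive k-mers: they anchor nothing useful
        self.index = {km: pos for km, pos in index.items() if len(pos) <= max_hits}


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain with strictly increasing query and target positions.

    Anchors must be sorted by (query, target).  Patience-style LIS on the
    target coordinate.
    """
    tails: list[int] = []  # target positions of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, t) in enumerate(anchors):
        pos = bisect.bisect_left(tails, t)
        if pos == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[pos] = t
            tails_idx[pos] = i
        parent[i] = tails_idx[pos - 1] if pos > 0 else -1
    if not tails_idx:
        return []
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return chain


_dp_aligner = Align.PairwiseAligner()
_dp_aligner.mode = "global"
_dp_aligner.match_score = 1
_dp_aligner.mismatch_score = -1
_dp_aligner.open_gap_score = -2
_dp_aligner.extend_gap_score = -1


def _segment_stats(a: str, b: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap_columns) for aligning segment a to b."""
    if a == b:
        return len(a), 0, 0
    if len(a) == len(b):
        mism = sum(x != y for x, y in zip(a, b))
        return len(a) - mism, mism, 0
    if not a or not b:
        return 0, 0, len(a) + len(b)
    aln = _dp_aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities, counts.mismatches, counts.gaps


def _xdrop_extend(
    query: str, target: str, q: int, t: int, direction: int, xdrop: int
) -> tuple[int, int, int]:
    """Ungapped extension from (q, t); returns (steps, matches, mismatches).

    ``direction`` +1 extends rightward starting at (q, t); -1 leftward
    starting at (q, t) inclusive.  Stops at sequence bounds or when the
    running score drops ``xdrop`` below its best; trailing mismatches are
    trimmed back to the best-scoring prefix.
    """
    score = best = 0
    best_steps = 0
    steps = matches = 0
    while True:
        qi = q + direction * steps
        ti = t + direction * steps
        if qi < 0 or ti < 0 or qi >= len(query) or ti >= len(target):
            break
        if query[qi] == target[ti]:
            score += 1
            matches += 1
        else:
            score -= 1
        steps += 1
        if score > best:
            best = score
            best_steps = steps
        if score < best - xdrop:
            break
    # recount matches within the retained prefix
    kept_matches = 0
    for s in range(best_steps):
        if query[q + direction * s] == target[t + direction * s]:
            kept_matches += 1
    return best_steps, kept_matches, best_steps - kept_matches


def align_query(
    query_id: str,
    query_seq: str,
    windows: list[WindowIndex],
    params: AlignParams = AlignParams(),
) -> list[LocalAlignment]:
    """Best local alignment of one read against each window, both strands.

    Returns at most one alignment per window (the higher-scoring strand),
    filtered by ``min_identity`` and ``min_aligned``.
    """
    best: dict[str, LocalAlignment] = {}
    for strand in "+-":
        seq = query_seq if strand == "+" else revcomp(query_seq)
        kmers = [
            (i, seq[i : i + params.k])
            for i in range(0, max(len(seq) - params.k + 1, 0), params.stride)
        ]
        for win in windows:
            anchors = []
            for qpos, km in kmers:
                for tpos in win.index.get(km, ()):
                    anchors.append((qpos, tpos))
            if len(anchors) < params.min_anchors:
                continue
            anchors.sort()
            chain = _chain_anchors(anchors)
            if len(chain) < params.min_anchors:
                continue
            aln = _alignment_from_chain(query_id, seq, win, chain, strand, params)
            if aln is None:
                continue
            if aln.identity < params.min_identity:
                continue
            if aln.query_end - aln.query_start + 1 < params.min_aligned:
                continue
            prev = best.get(win.target_id)
            if prev is None or aln.score(params) > prev.score(params):
                best[win.target_id] = aln
    return list(best.values())


def _alignment_from_chain(
    query_id: str,
    seq: str,
    win: WindowIndex,
    chain: list[tuple[int, int]],
    strand: str,
    params: AlignParams,
) -> LocalAlignment | None:
    k = params.k
    target = win.sequence
    matches = mismatches = gaps = 0
    q0, t0 = chain[0]
    qe, te = q0 + k, t0 + k
    matches += k
    for q, t in chain[1:]:
        if q + k <= qe:
            continue  # anchor fully behind the current frontier
        if q < qe:
            # overlapping anchor: only consistent same-diagonal overlaps extend
            if t - q == te - qe:
                ext = q + k - qe
                matches += ext
                qe, te = q + k, t + k
            continue
        if t < te:
            continue  # target going backwards relative to frontier: skip
        m, x, g = _segment_stats(seq[qe:q], target[te:t])
        matches += m + k
        mismatches += x
        gaps += g
        qe, te = q + k, t + k
    # extend outward past the terminal anchors
    lsteps, lm, lx = _xdrop_extend(seq, target, q0 - 1, t0 - 1, -1, params.xdrop)
    rsteps, rm, rx = _xdrop_extend(seq, target, qe, te, +1, params.xdrop)
    matches += lm + rm
    mismatches += lx + rx
    qs, ts = q0 - lsteps, t0 - lsteps
    qend, tend = qe + rsteps, te + rsteps
    if matches == 0:
        return None
    # report read coordinates on the original (forward) read
    if strand == "+":
        rs, re = qs, qend
    else:
        rs, re = len(seq) - qend, len(seq) - qs
    return LocalAlignment(
        query_id=query_id,
        target_id=win.target_id,
        query_start=rs + 1,
        query_end=re,
        target_start=ts + 1,
        target_end=tend,
        strand=strand,
        matches=matches,
        mismatches=mismatches,
        gap_columns=gaps,
    )
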