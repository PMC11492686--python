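"""SSR and dispersed-repeat detection.

SSRs are maximal perfect tandem runs of 1-6 bp primitive motifs with
class-specific minimum copy numbers.  Dispersed repeats are maximal pairs
of similar intervals in four orientation classes (forward, reverse,
complement, palindromic), found by exact seeding (pigeonhole-sized seeds)
followed by per-diagonal mismatch scanning, so the reported set equals
the exhaustive definition whenever the seed guarantee holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SeqRecord, complement

DEFAULT_SSR_THRESHOLDS = (10, 5, 4, 3, 3, 3)

CLASSES = ("forward", "palindromic", "reverse", "complement")

LENGTH_BINS = ((30, 39), (40, 49), (50, 99), (100, 399), (400, None))


@dataclass
class SsrRecord:
    sequence_id: str
    motif: str
    repeat_count: int
    interval: tuple[int, int]  # 1-based inclusive; length = len(motif) * count


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def find_ssrs(
    record: SeqRecord | str,
    thresholds: tuple[int, ...] = DEFAULT_SSR_THRESHOLDS,
    sequence_id: str = "seq",
) -> list[SsrRecord]:
    """Maximal perfect tandem runs meeting per-motif-class thresholds.

    Runs are reported once, under their shortest primitive motif, at the
    start of the maximal run; trailing partial copies are not counted
    (interval length is motif length x copy number).
    """
    if isinstance(record, SeqRecord):
        seq, sequence_id = record.sequence, record.id
    else:
        seq = record
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    records: list[SsrRecord] = []
    for m, threshold in enumerate(thresholds, start=1):
        if n < m * threshold:
            continue
        eq = arr[: n - m] == arr[m:]
        # maximal runs of equal-at-lag-m positions
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for run_start, run_end in zip(idx[::2], idx[1::2]):
            region_len = (run_end - run_start) + m
            copies = region_len // m
            if copies < threshold:
                continue
            motif = seq[run_start : run_start + m]
            # a non-primitive motif means the run is a rotation/extension of
            # a shorter-period run already reported (Fine-Wilf)
            if not _is_primitive(motif):
                continue
            records.append(
                SsrRecord(
                    sequence_id,
                    motif,
                    copies,
                    (run_start + 1, run_start + m * copies),
                )
            )
    records.sort(key=lambda r: (r.interval, len(r.motif)))
    return records


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DispersedRepeat:
    repeat_class: str
    seq1_id: str
    interval1: tuple[int, int]  # 1-based inclusive
    seq2_id: str
    interval2: tuple[int, int]
    length: int
    mismatches: int


def _transform(seq: str, repeat_class: str) -> str:
    if repeat_class == "forward":
        return seq
    if repeat_class == "reverse":
        return seq[::-1]
    if repeat_class == "complement":
        return complement(seq)
    if repeat_class == "palindromic":
        return complement(seq)[::-1]
    raise ValueError(f"unknown repeat class {repeat_class!r}")


def _second_interval(b0: int, length: int, n: int, repeat_class: str) -> tuple[int, int]:
    """Map a run interval on the transformed sequence back to the original."""
    if repeat_class in ("forward", "complement"):
        return (b0, b0 + length - 1)
    # reversal classes flip coordinates
    return (n - length - b0, n - 1 - b0)


def _seed_length(min_len: int, max_mismatch: int) -> int:
    # pigeonhole: k mismatches split a qualifying run into k+1 exact
    # pieces, the longest of which is >= floor(min_len / (k+1)); a longer
    # seed would lose sensitivity, a shorter one only costs time
    return max(min(min_len // (max_mismatch + 1), 2000), 1)


def _candidate_diagonals(a: str, b: str, s: int) -> set[int]:
    index: dict[str, list[int]] = {}
    for j in range(len(b) - s + 1):
        index.setdefault(b[j : j + s], []).append(j)
    diagonals: set[int] = set()
    for i in range(len(a) - s + 1):
        for j in index.get(a[i : i + s], ()):
            diagonals.add(i - j)
    return diagonals


def _maximal_runs(
    mismatch_pos: np.ndarray, total: int, max_mismatch: int
) -> list[tuple[int, int, int]]:
    """Maximal windows with <= max_mismatch mismatches on one diagonal.

    Returns (start, end_exclusive, n_mismatches) tuples over [0, total).
    """
    t = len(mismatch_pos)
    if t <= max_mismatch:
        return [(0, total, t)] if total > 0 else []
    m = np.concatenate(([-1], mismatch_pos, [total]))
    runs = []
    for i in range(t - max_mismatch + 1):
        start = int(m[i]) + 1
        end = int(m[i + max_mismatch + 1])
        if end > start:
            runs.append((start, end, max_mismatch))
    return runs


def find_dispersed(
    seqs: list[SeqRecord] | SeqRecord,
    min_len: int = 30,
    max_mismatch: int = 3,
    cap: int = 5000,
    classes: tuple[str, ...] = CLASSES,
) -> list[DispersedRepeat]:
    """Maximal dispersed repeat pairs in four orientation classes.

    A pair is two equal-length intervals whose sequences agree up to
    ``max_mismatch`` mismatches after the class transform of the second
    copy, of length >= ``min_len``, and not extendable in either direction
    without breaking the mismatch bound or the sequence bounds.
    Self-overlapping intra-sequence pairs are excluded; unordered pairs
    are reported once.  Output is truncated to ``cap`` by descending
    length.
    """
    if isinstance(seqs, SeqRecord):
        seqs = [seqs]
    s = _seed_length(min_len, max_mismatch)
    found: set[DispersedRepeat] = set()
    for i, rec_a in enumerate(seqs):
        for j in range(i, len(seqs)):
            rec_b = seqs[j]
            for cls in classes:
                _scan_pair(rec_a, rec_b, i == j, cls, min_len, max_mismatch, s, found)
    out = sorted(
        found,
        key=lambda r: (-r.length, r.seq1_id, r.interval1, r.seq2_id, r.interval2, r.repeat_class),
    )
    return out[:cap]


def _scan_pair(
    rec_a: SeqRecord,
    rec_b: SeqRecord,
    same: bool,
    cls: str,
    min_len: int,
    max_mismatch: int,
    seed: int,
    found: set[DispersedRepeat],
) -> None:
    a = rec_a.sequence
    b = _transform(rec_b.sequence, cls)
    n_b = len(rec_b.sequence)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    for d in sorted(_candidate_diagonals(a, b, seed)):
        a0 = max(0, d)
        a1 = min(len(a), len(b) + d)
        if a1 - a0 < min_len:
            continue
        if same and cls == "forward" and d == 0:
            continue  # trivial identity diagonal
        neq = arr_a[a0:a1] != arr_b[a0 - d : a1 - d]
        mismatch_pos = np.flatnonzero(neq)
        for start, end, n_mis in _maximal_runs(mismatch_pos, a1 - a0, max_mismatch):
            length = end - start
            if length < min_len:
                continue
            ia_start = a0 + start
            i1 = (ia_start, ia_start + length - 1)
            i2 = _second_interval(ia_start - d, length, n_b, cls)
            if same:
                if max(i1[0], i2[0]) <= min(i1[1], i2[1]):
                    continue  # overlapping copies: tandem territory
                if (i2, i1) < (i1, i2):
                    i1, i2 = i2, i1
            found.add(
                DispersedRepeat(
                    cls,
                    rec_a.id,
                    (i1[0] + 1, i1[1] + 1),
                    rec_b.id,
                    (i2[0] + 1, i2[1] + 1),
                    length,
                    int(n_mis),
                )
            )


def verify_dispersed(repeat: DispersedRepeat, seqs: dict[str, str]) -> bool:
    """Naive re-check of a reported pair's class transform and mismatches."""
    s1 = seqs[repeat.seq1_id][repeat.interval1[0] - 1 : repeat.interval1[1]]
    s2 = seqs[repeat.seq2_id][repeat.interval2[0] - 1 : repeat.interval2[1]]
    if len(s1) != len(s2) or len(s1) != repeat.length:
        return False
    t2 = _transform(s2, repeat.repeat_class) if repeat.repeat_class in ("reverse", "palindromic") else s2
    if repeat.repeat_class == "complement":
        t2 = complement(s2)
    elif repeat.repeat_class == "palindromic":
        t2 = complement(s2)[::-1]
    elif repeat.repeat_class == "reverse":
        t2 = s2[::-1]
    else:
        t2 = s2
    mism = sum(x != y for x, y in zip(s1, t2))
    return mism == repeat.mismatches


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def bin_dispersed(
    repeats: list[DispersedRepeat],
) -> dict[str, dict[str, int | float]]:
    """Counts per length bin and per class, with fractions of the total."""
    labels = [
        f"{lo}-{hi}" if hi is not None else f">={lo}" for lo, hi in LENGTH_BINS
    ]
    counts = {label: {cls: 0 for cls in CLASSES} for label in labels}
    for rep in repeats:
        for (lo, hi), label in zip(LENGTH_BINS, labels):
            if rep.length >= lo and (hi is None or rep.length <= hi):
                counts[label][rep.repeat_class] += 1
                break
    total = len(repeats)
    out: dict[str, dict[str, int | float]] = {}
    for label in labels:
        row: dict[str, int | float] = dict(counts[label])
        row["total"] = sum(counts[label].values())
        row["fraction"] = row["total"] / total if total else 0.0
        out[label] = row
    return out
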