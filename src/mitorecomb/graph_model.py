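"""Contigs, two-copy repeat elements, and conformation resolution.

A repeat element with two copies admits exactly two pairings of its
flanking neighbors: the reference pairing (each copy keeps its own
left/right neighbors) and the crossover pairing (left neighbors swap
right neighbors).  Choosing one pairing per repeat and walking the
adjacencies yields a set of representative linear/circular molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import GfaGraph, revcomp

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


class PairingError(ModelError):
    pass


class ResolutionError(ModelError):
    pass


@dataclass(frozen=True)
class Oriented:
    """A signed element reference: segment name plus orientation."""

    name: str
    orient: str = "+"

    def flipped(self) -> "Oriented":
        return Oriented(self.name, "-" if self.orient == "+" else "+")

    def __str__(self) -> str:
        return f"{self.name}{'' if self.orient == '+' else '-'}"


@dataclass
class ContigDef:
    id: str
    length: int
    depth: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ModelError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ModelError(f"contig {self.id}: sequence/length mismatch")


@dataclass
class RepeatElement:
    """A two-copy repeat with its placements in the reference conformation.

    ``copies`` holds exactly two (left, right) neighbor pairs; the
    crossover conformation is derived by swapping the right neighbors.
    """

    id: str
    length: int
    copies: list[tuple[Oriented, Oriented]]
    depth: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ModelError(f"repeat {self.id}: length must be >= 1")
        if len(self.copies) != 2:
            raise ModelError(f"repeat {self.id}: exactly 2 copies required")


@dataclass
class GenomeModel:
    """Assembly-graph model: contigs, repeats, and direct adjacencies."""

    contigs: dict[str, ContigDef] = field(default_factory=dict)
    repeats: dict[str, RepeatElement] = field(default_factory=dict)
    direct_links: list[tuple[Oriented, Oriented]] = field(default_factory=list)

    def element_length(self, name: str) -> int:
        if name in self.contigs:
            return self.contigs[name].length
        if name in self.repeats:
            return self.repeats[name].length
        raise ModelError(f"unknown element {name!r}")

    def element_depth(self, name: str) -> float | None:
        if name in self.contigs:
            return self.contigs[name].depth
        if name in self.repeats:
            return self.repeats[name].depth
        raise ModelError(f"unknown element {name!r}")

    def element_sequence(self, name: str) -> str | None:
        if name in self.contigs:
            return self.contigs[name].sequence
        if name in self.repeats:
            return self.repeats[name].sequence
        raise ModelError(f"unknown element {name!r}")

    def validate(self) -> None:
        for rep in self.repeats.values():
            for left, right in rep.copies:
                for side, ref in (("left", left), ("right", right)):
                    if ref.name not in self.contigs and ref.name not in self.repeats:
                        raise PairingError(
                            f"repeat {rep.id}: {side} neighbor {ref.name!r} "
                            "does not exist in the graph"
                        )

    def to_gfa(self) -> GfaGraph:
        from .io_formats import GfaLink, GfaSegment

        g = GfaGraph()
        for c in self.contigs.values():
            g.add_segment(GfaSegment(c.id, c.length, c.sequence, c.depth))
        for r in self.repeats.values():
            g.add_segment(GfaSegment(r.id, r.length, r.sequence, r.depth))
        for r in self.repeats.values():
            for left, right in r.copies:
                g.add_link(GfaLink(left.name, left.orient, r.id, "+"))
                g.add_link(GfaLink(r.id, "+", right.name, right.orient))
        for a, b in self.direct_links:
            g.add_link(GfaLink(a.name, a.orient, b.name, b.orient))
        return g


def model_from_gfa(
    graph: GfaGraph,
    repeat_ids: list[str],
    reference_copies: dict[str, list[tuple[Oriented, Oriented]]] | None = None,
) -> GenomeModel:
    """Build a :class:`GenomeModel` from a GFA graph.

    ``repeat_ids`` names the segments to treat as two-copy repeats.  If
    ``reference_copies`` is not given, each repeat's left neighbors are
    paired with right neighbors in sorted order (an arbitrary but
    deterministic reference conformation).
    """
    model = GenomeModel()
    repeat_set = set(repeat_ids)
    for seg in graph.segments.values():
        if seg.name not in repeat_set:
            model.contigs[seg.name] = ContigDef(seg.name, seg.length, seg.depth, seg.sequence)
    lefts: dict[str, list[Oriented]] = {r: [] for r in repeat_ids}
    rights: dict[str, list[Oriented]] = {r: [] for r in repeat_ids}
    for link in graph.links:
        f_rep = link.from_segment in repeat_set
        t_rep = link.to_segment in repeat_set
        if f_rep and t_rep:
            raise ModelError("repeat-to-repeat links are not supported")
        if t_rep:
            lefts[link.to_segment].append(Oriented(link.from_segment, link.from_orient))
        elif f_rep:
            rights[link.from_segment].append(Oriented(link.to_segment, link.to_orient))
        else:
            model.direct_links.append(
                (
                    Oriented(link.from_segment, link.from_orient),
                    Oriented(link.to_segment, link.to_orient),
                )
            )
    for rid in repeat_ids:
        seg = graph.segments[rid]
        if reference_copies and rid in reference_copies:
            copies = reference_copies[rid]
        else:
            ls = sorted(lefts[rid], key=str)
            rs = sorted(rights[rid], key=str)
            if len(ls) != 2 or len(rs) != 2:
                raise PairingError(
                    f"repeat {rid}: expected 2 left and 2 right neighbors, "
                    f"got {len(ls)} and {len(rs)}"
                )
            copies = [(ls[0], rs[0]), (ls[1], rs[1])]
        model.repeats[rid] = RepeatElement(rid, seg.length, copies, seg.depth, seg.sequence)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# pairings
# ---------------------------------------------------------------------------


@dataclass
class PairingOption:
    """One of the two conformations of a repeat: two (left, right) placements."""

    repeat_id: str
    name: str  # "reference" | "crossover"
    placements: list[tuple[Oriented, Oriented]]

    @property
    def path_labels(self) -> list[str]:
        return [f"{l.name}-{self.repeat_id}-{r.name}" for l, r in self.placements]


def enumerate_pairings(model: GenomeModel, repeat: RepeatElement) -> tuple[PairingOption, PairingOption]:
    """Return the reference and crossover pairings for a two-copy repeat.

    The reference pairing keeps each copy's own neighbors; the crossover
    pairing exchanges the right neighbors between copies.
    """
    (l1, r1), (l2, r2) = repeat.copies
    for side, ref in (("left", l1), ("right", r1), ("left", l2), ("right", r2)):
        if ref is None:
            raise PairingError(f"repeat {repeat.id}: dangling {side} side")
    reference = PairingOption(repeat.id, "reference", [(l1, r1), (l2, r2)])
    crossover = PairingOption(repeat.id, "crossover", [(l1, r2), (l2, r1)])
    return reference, crossover


# ---------------------------------------------------------------------------
# conformations and molecules
# ---------------------------------------------------------------------------


@dataclass
class Conformation:
    molecule_id: str
    path: list[Oriented]
    topology: str  # "linear" | "circular"

    def path_string(self) -> str:
        return "-".join(el.name for el in self.path)


def parse_path(path_string: str, molecule_id: str = "molecule", topology: str = "linear") -> Conformation:
    """Parse a path like ``contig1-LR11-contig5`` into a Conformation.

    Element names must not contain '-'.  A trailing repetition of the
    first element (closure notation for circles) is not expected here.
    """
    names = [tok for tok in path_string.split("-") if tok]
    if not names:
        raise ModelError("empty path string")
    return Conformation(molecule_id, [Oriented(n) for n in names], topology)


def molecule_length(conf: Conformation, model: GenomeModel) -> int:
    """Total bp of a molecule: sum of element lengths along the path.

    Each traversal counts, so a repeat crossed twice contributes twice.
    Linear and circular molecules are summed identically (contigs do not
    overlap; repeat copies are separate path elements).
    """
    return sum(model.element_length(el.name) for el in conf.path)


def stitch_sequence(conf: Conformation, model: GenomeModel) -> str:
    """Concatenate element sequences along the path (for length checks)."""
    parts = []
    for el in conf.path:
        seq = model.element_sequence(el.name)
        if seq is None:
            raise ModelError(f"element {el.name} has no sequence")
        parts.append(seq if el.orient == "+" else revcomp(seq))
    return "".join(parts)


@dataclass
class Molecule:
    conformation: Conformation
    length: int
    mean_depth: float | None = None


@dataclass
class MoleculeSet:
    molecules: list[Molecule]

    def total_length(self) -> int:
        return sum(m.length for m in self.molecules)

    def validate(self, model: GenomeModel) -> None:
        contig_seen: dict[str, int] = {}
        repeat_seen: dict[str, int] = {}
        for mol in self.molecules:
            for el in mol.conformation.path:
                if el.name in model.contigs:
                    contig_seen[el.name] = contig_seen.get(el.name, 0) + 1
                else:
                    repeat_seen[el.name] = repeat_seen.get(el.name, 0) + 1
        for cid in model.contigs:
            if contig_seen.get(cid, 0) != 1:
                raise ResolutionError(
                    f"contig {cid} appears {contig_seen.get(cid, 0)} times across molecules"
                )
        for rid, rep in model.repeats.items():
            if repeat_seen.get(rid, 0) != len(rep.copies):
                raise ResolutionError(
                    f"repeat {rid} traversed {repeat_seen.get(rid, 0)} times, "
                    f"expected {len(rep.copies)}"
                )


# --- resolution ------------------------------------------------------------

# a contig "end": (contig_id, side) with side in {"L", "R"}
_End = tuple[str, str]


def _exit_end(el: Oriented) -> _End:
    return (el.name, "R" if el.orient == "+" else "L")


def _entry_end(el: Oriented) -> _End:
    return (el.name, "L" if el.orient == "+" else "R")


@dataclass
class _Connector:
    end_a: _End
    end_b: _End
    via: str | None  # repeat id or None for a direct link
    used: bool = False

    def other(self, end: _End) -> _End:
        return self.end_b if end == self.end_a else self.end_a


def _select_pairings(
    model: GenomeModel,
    ratios: dict[str, tuple[float, float] | float],
) -> dict[str, PairingOption]:
    chosen: dict[str, PairingOption] = {}
    for rid, rep in model.repeats.items():
        if rid not in ratios:
            raise ResolutionError(f"no pairing proportion supplied for repeat {rid}")
        reference, crossover = enumerate_pairings(model, rep)
        val = ratios[rid]
        if isinstance(val, (int, float)):
            ref_support, cross_support = 1.0 - float(val), float(val)
        else:
            ref_support, cross_support = float(val[0]), float(val[1])
        if cross_support > ref_support:
            chosen[rid] = crossover
        else:
            if cross_support == ref_support:
                logger.info("repeat %s: tied support, keeping reference pairing", rid)
            chosen[rid] = reference
    return chosen


def resolve_major(
    model: GenomeModel,
    ratios: dict[str, tuple[float, float] | float],
) -> MoleculeSet:
    """Resolve the graph into molecules under each repeat's major pairing.

    ``ratios`` maps repeat id to either a crossover proportion in [0, 1]
    or a (reference_support, crossover_support) pair.  The larger side is
    chosen (ties keep the reference pairing, logged).  Molecules are then
    obtained by walking contig ends through chosen repeat placements and
    direct links; walks start at the lexicographically smallest unused
    contig in '+' orientation, and ambiguous branches take the smallest
    neighbor id, making the output deterministic.
    """
    chosen = _select_pairings(model, ratios)

    connectors: list[_Connector] = []
    for pairing in chosen.values():
        for left, right in pairing.placements:
            connectors.append(_Connector(_exit_end(left), _entry_end(right), pairing.repeat_id))
    for a, b in model.direct_links:
        connectors.append(_Connector(_exit_end(a), _entry_end(b), None))

    by_end: dict[_End, list[_Connector]] = {}
    for conn in connectors:
        by_end.setdefault(conn.end_a, []).append(conn)
        by_end.setdefault(conn.end_b, []).append(conn)

    used_contigs: set[str] = set()

    def pick(end: _End, walk_start: str) -> _Connector | None:
        candidates = [c for c in by_end.get(end, []) if not c.used]
        if not candidates:
            return None
        # prefer closing the current molecule, then links into fresh
        # contigs; among equals take repeat connectors and small ids
        candidates.sort(
            key=lambda c: (
                c.other(end)[0] != walk_start,
                c.other(end)[0] in used_contigs,
                c.via is None,
                c.via or "",
                c.other(end)[0],
            )
        )
        return candidates[0]

    molecules: list[Molecule] = []

    for start in sorted(model.contigs):
        if start in used_contigs:
            continue
        used_contigs.add(start)
        path: list[Oriented] = [Oriented(start, "+")]
        topology = "linear"
        # forward walk from the right end of the start contig
        end = (start, "R")
        while True:
            conn = pick(end, start)
            if conn is None:
                break
            conn.used = True
            if conn.via is not None:
                path.append(Oriented(conn.via, "+"))
            nxt = conn.other(end)
            contig, side = nxt
            orient = "+" if side == "L" else "-"
            if contig == start and len(path) > 1 and orient == "+":
                topology = "circular"
                break
            if contig in used_contigs and contig != start:
                raise ResolutionError(
                    f"walk re-entered contig {contig} already assigned to a molecule"
                )
            if contig == start:  # self-loop in reverse orientation: unsupported
                topology = "circular"
                break
            used_contigs.add(contig)
            path.append(Oriented(contig, orient))
            end = (contig, "R" if orient == "+" else "L")
        if topology == "linear":
            # extend backwards from the left end of the start contig
            end = (start, "L")
            while True:
                conn = pick(end, start)
                if conn is None:
                    break
                conn.used = True
                prefix: list[Oriented] = []
                if conn.via is not None:
                    prefix.append(Oriented(conn.via, "+"))
                prv = conn.other(end)
                contig, side = prv
                orient = "+" if side == "R" else "-"
                if contig in used_contigs:
                    raise ResolutionError(
                        f"walk re-entered contig {contig} already assigned to a molecule"
                    )
                used_contigs.add(contig)
                path = [Oriented(contig, orient)] + prefix + path
                end = (contig, "L" if orient == "+" else "R")

        conf = Conformation(f"molecule{len(molecules) + 1}", path, topology)
        molecules.append(Molecule(conf, molecule_length(conf, model), _path_depth(conf, model)))

    unused = [c for c in connectors if c.via is not None and not c.used]
    if unused:
        raise ResolutionError(
            f"{len(unused)} chosen repeat placements were not walkable: "
            + ", ".join(c.via for c in unused if c.via)
        )
    result = MoleculeSet(molecules)
    result.validate(model)
    return result


def _path_depth(conf: Conformation, model: GenomeModel) -> float | None:
    total_bp = 0
    acc = 0.0
    for el in conf.path:
        d = model.element_depth(el.name)
        if d is None:
            return None
        length = model.element_length(el.name)
        # a two-copy repeat's depth is shared between traversals
        if el.name in model.repeats:
            d = d / len(model.repeats[el.name].copies)
        acc += d * length
        total_bp += length
    return acc / total_bp if total_bp else None


# ---------------------------------------------------------------------------
# depth consistency
# ---------------------------------------------------------------------------


@dataclass
class DepthReport:
    repeat_id: str
    observed: float
    expected: float
    ratio: float
    flagged: bool


def depth_consistency(model: GenomeModel, tolerance: float = 0.10) -> list[DepthReport]:
    """Check that each repeat's depth matches the sum over its copies.

    A two-copy repeat should be covered roughly as deep as the sum of the
    mean depths of its two flanking contig pairs; repeats deviating by
    more than ``tolerance`` (relative) are flagged.  Repeats or neighbors
    without depth values are skipped with a warning.
    """
    reports: list[DepthReport] = []
    for rid, rep in model.repeats.items():
        if rep.depth is None:
            logger.warning("repeat %s: no depth recorded, skipped", rid)
            continue
        expected = 0.0
        ok = True
        for left, right in rep.copies:
            dl = model.element_depth(left.name)
            dr = model.element_depth(right.name)
            if dl is None or dr is None:
                logger.warning("repeat %s: neighbor depth missing, skipped", rid)
                ok = False
                break
            expected += (dl + dr) / 2.0
        if not ok or expected == 0:
            continue
        ratio = rep.depth / expected
        reports.append(
            DepthReport(rid, rep.depth, expected, ratio, abs(ratio - 1.0) > tolerance)
        )
    return reports
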