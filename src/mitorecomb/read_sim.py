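"""Synthetic-data generators.

Everything here is seeded and bit-reproducible: toy multi-contig genomes
with two-copy repeats, conformational isoform mixtures, long reads with a
truncated log-normal length distribution and per-base error rates, plant
chloroplast/mitochondrion pairs with planted homologous segments, and CDS
sets with controlled codon bias.  Each generator returns ground truth
alongside the sequences so recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import (
    Conformation,
    ContigDef,
    GenomeModel,
    Molecule,
    MoleculeSet,
    Oriented,
    RepeatElement,
    resolve_major,
    stitch_sequence,
)
from .io_formats import SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    contig_lengths: list[int] = field(default_factory=lambda: [9000, 9000, 9000, 9000])
    repeat_lengths: list[int] = field(default_factory=lambda: [2000])
    mixture: list[float] = field(default_factory=lambda: [0.5])
    read_length_mean: float = 12_000.0
    read_length_sd: float = 6_000.0
    read_length_min: int = 1_000
    read_count: int = 1_000
    error_rates: tuple[float, float, float] = (0.05, 0.03, 0.03)
    length_weighted: bool = False

    def __post_init__(self) -> None:
        if len(self.contig_lengths) != 4 * len(self.repeat_lengths):
            raise ConfigError("need exactly 4 contigs per repeat")
        for p in self.mixture:
            if not 0.0 <= p <= 1.0:
                raise ConfigError("mixture proportions must lie in [0, 1]")
        if len(self.mixture) != len(self.repeat_lengths):
            raise ConfigError("one mixture proportion per repeat required")
        for rl in self.repeat_lengths:
            if rl < 1:
                raise ConfigError("repeat length must be >= 1")
        for cl in self.contig_lengths:
            if cl < 1:
                raise ConfigError("contig length must be >= 1")
        s, i, d = self.error_rates
        if min(s, i, d) < 0 or s + i + d >= 1:
            raise ConfigError("error rates must be >= 0 and sum to < 1")
        if self.read_length_min < 1:
            raise ConfigError("minimum read length must be >= 1")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------


@dataclass
class ReadProvenance:
    read_id: str
    source: str  # molecule label
    start: int  # 0-based on source molecule
    end: int  # exclusive; may exceed molecule length for circular wrap
    strand: str
    conformation: str  # "reference" | "crossover"


@dataclass
class TruthSet:
    true_crossover: dict[str, float] = field(default_factory=dict)
    reads: list[ReadProvenance] = field(default_factory=list)

    def conformation_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.conformation] = out.get(r.conformation, 0) + 1
        return out


def make_toy_genome(config: SimulationConfig) -> tuple[GenomeModel, TruthSet]:
    """Build a toy assembly graph with 2-copy repeats and random sequences.

    Per repeat, four contigs (a, b, c, d) surround the repeat R with
    reference placements (a, b) and (c, d) and closure links making both
    conformations circular: reference molecules a-R-b and c-R-d, crossover
    molecules a-R-d and c-R-b.  The repeat sequence is inserted
    identically at both placements.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = GenomeModel()
    truth = TruthSet()
    for k, rep_len in enumerate(config.repeat_lengths):
        cl = config.contig_lengths[4 * k : 4 * k + 4]
        if rep_len > min(cl):
            raise ConfigError(
                f"repeat {k + 1} ({rep_len} bp) is longer than a flanking contig"
            )
        names = [f"contig{4 * k + j + 1}" for j in range(4)]
        for name, length in zip(names, cl):
            model.contigs[name] = ContigDef(name, length, sequence=random_dna(rng, length))
        rid = f"R{k + 1}"
        a, b, c, d = (Oriented(n) for n in names)
        model.repeats[rid] = RepeatElement(
            rid, rep_len, [(a, b), (c, d)], sequence=random_dna(rng, rep_len)
        )
        # closure links keep both conformations circular (reference: b->a,
        # d->c; crossover: b->c, d->a)
        model.direct_links += [(b, a), (d, c), (b, c), (d, a)]
        truth.true_crossover[rid] = config.mixture[k]
    model.validate()
    return model, truth


def toy_isoforms(model: GenomeModel, truth: TruthSet) -> list[tuple[str, Molecule, str]]:
    """Molecules of both conformations with labels and conformation tags.

    Returns (label, molecule, conformation) triples; reference and
    crossover sets each cover every contig once.
    """
    zeros = {rid: 0.0 for rid in model.repeats}
    ones = {rid: 1.0 for rid in model.repeats}
    out = []
    for tag, ratios in (("reference", zeros), ("crossover", ones)):
        mols = resolve_major(model, ratios)
        for mol in mols.molecules:
            label = f"{tag}:{mol.conformation.path_string()}"
            out.append((label, mol, tag))
    return out


def mixture_weights(
    isoforms: list[tuple[str, Molecule, str]],
    crossover: float | dict[str, float],
    model: GenomeModel | None = None,
) -> list[float]:
    """Per-molecule weights realizing the requested crossover proportions.

    ``crossover`` is either one global proportion or a per-repeat map; in
    the latter case each molecule is weighted by the proportion of the
    repeat it traverses (toy molecules carry exactly one repeat).
    """

    def repeat_of(mol: Molecule) -> str | None:
        if model is None:
            return None
        for el in mol.conformation.path:
            if el.name in model.repeats:
                return el.name
        return None

    raw = []
    for _, mol, tag in isoforms:
        if isinstance(crossover, dict):
            rid = repeat_of(mol)
            if rid is None or rid not in crossover:
                raise ConfigError("per-repeat mixture requires a model with repeats")
            p = crossover[rid]
        else:
            p = float(crossover)
        raw.append(p if tag == "crossover" else 1.0 - p)
    total = sum(raw)
    if total <= 0:
        raise ConfigError("mixture weights sum to zero")
    return [w / total for w in raw]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _apply_errors(seq: str, rates: tuple[float, float, float], rng: np.random.Generator) -> str:
    sub, ins, dele = rates
    if sub == ins == dele == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    # substitutions: shift by 1..3 within {A,C,G,T}
    idx = np.searchsorted(_BASES, arr)  # _BASES sorted: A<C<G<T
    u = rng.random(arr.size)
    sub_mask = u < sub
    shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
    idx[sub_mask] = (idx[sub_mask] + shifts) % 4
    arr = _BASES[idx]
    # deletions / insertions via per-base copy counts
    u2 = rng.random(arr.size)
    counts = np.ones(arr.size, dtype=np.int64)
    counts[u2 < dele] = 0
    u3 = rng.random(arr.size)
    counts[u3 < ins] += 1
    out = np.repeat(arr, counts)
    # the second copy at insertion sites becomes a random base
    ins_sites = np.cumsum(counts)[counts == 2] - 1
    out[ins_sites] = rng.choice(_BASES, size=ins_sites.size)
    return out.tobytes().decode()


def _draw_lengths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    m, s = config.read_length_mean, config.read_length_sd
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    lengths = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.maximum(lengths, config.read_length_min).astype(np.int64)


def simulate_reads(
    isoforms: list[tuple[str, Molecule, str]],
    weights: list[float],
    config: SimulationConfig,
    model: GenomeModel,
    rng: np.random.Generator | None = None,
) -> tuple[list[SeqRecord], TruthSet]:
    """Draw reads from a mixture of isoform molecules.

    Each read picks a molecule with probability equal to its weight
    (optionally multiplied by molecule length and renormalized), a uniform
    start (wrapping on circular molecules), a truncated log-normal length,
    per-base errors, and a random strand.  Provenance is recorded for
    every read.
    """
    if not isoforms:
        raise ConfigError("no molecules to simulate from")
    w = np.asarray(weights, dtype=float)
    if w.size != len(isoforms) or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ConfigError("weights must be nonnegative and sum to 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.length_weighted:
        w = w * np.array([mol.length for _, mol, _ in isoforms], dtype=float)
        w = w / w.sum()

    seqs = [stitch_sequence(mol.conformation, model) for _, mol, _ in isoforms]
    circular = [mol.conformation.topology == "circular" for _, mol, _ in isoforms]

    choices = rng.choice(len(isoforms), size=config.read_count, p=w)
    lengths = _draw_lengths(config, config.read_count, rng)
    records: list[SeqRecord] = []
    truth = TruthSet()
    for i in range(config.read_count):
        j = int(choices[i])
        label, mol, tag = isoforms[j]
        src = seqs[j]
        n = len(src)
        length = int(min(lengths[i], n))
        if circular[j]:
            start = int(rng.integers(0, n))
            end = start + length
            frag = src[start:end] if end <= n else src[start:] + src[: end - n]
        else:
            start = int(rng.integers(0, n - length + 1))
            end = start + length
            frag = src[start:end]
        frag = _apply_errors(frag, config.error_rates, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        rid = f"read{i + 1}"
        records.append(SeqRecord(rid, frag))
        truth.reads.append(ReadProvenance(rid, label, start, end, strand, tag))
    return records, truth


def element_depths(
    truth: TruthSet,
    isoforms: list[tuple[str, Molecule, str]],
    model: GenomeModel,
    conformation: str = "reference",
) -> dict[str, float]:
    """Observed per-element depth from read provenance (truth-based oracle).

    Projects each read's source interval onto the elements of its source
    molecule; a repeat traversed by several molecules (or twice in one)
    accumulates coverage from all traversals, so its depth reflects the
    combined copy coverage.
    """
    layouts: dict[str, list[tuple[str, int, int]]] = {}
    lengths: dict[str, int] = {}
    for label, mol, tag in isoforms:
        offset = 0
        spans = []
        for el in mol.conformation.path:
            ln = model.element_length(el.name)
            spans.append((el.name, offset, offset + ln))
            offset += ln
        layouts[label] = spans
        lengths[label] = offset

    covered: dict[str, int] = {}
    for read in truth.reads:
        if read.source not in layouts:
            continue
        spans = layouts[read.source]
        total = lengths[read.source]
        intervals = [(read.start, min(read.end, total))]
        if read.end > total:  # circular wrap
            intervals.append((0, read.end - total))
        for a, b in intervals:
            for name, s, e in spans:
                ov = min(b, e) - max(a, s)
                if ov > 0:
                    covered[name] = covered.get(name, 0) + ov
    return {
        name: covered.get(name, 0) / model.element_length(name)
        for name in list(model.contigs) + list(model.repeats)
    }


# ---------------------------------------------------------------------------
# MTPT planting
# ---------------------------------------------------------------------------


@dataclass
class PlantedSegment:
    mt_interval: tuple[int, int]  # 1-based inclusive
    cp_interval: tuple[int, int]
    identity: float
    mutations: int


def _place_nonoverlapping(
    rng: np.random.Generator,
    total: int,
    lengths: list[int],
    forbidden: list[tuple[int, int]],
    max_tries: int = 1000,
) -> list[int]:
    placed: list[tuple[int, int]] = list(forbidden)
    starts: list[int] = []
    for ln in lengths:
        if ln > total:
            raise ConfigError(f"segment of {ln} bp does not fit in {total} bp")
        for _ in range(max_tries):
            s = int(rng.integers(0, total - ln + 1))
            if all(s + ln <= a or s >= b for a, b in placed):
                placed.append((s, s + ln))
                starts.append(s)
                break
        else:
            raise ConfigError("could not place segments without overlap")
    return starts


def plant_mtpt(
    mt_seq: str,
    cp_seq: str,
    segments: list[tuple[int, float]],
    rng: np.random.Generator,
    genic_intervals: list[tuple[int, int]] | None = None,
) -> tuple[str, list[PlantedSegment]]:
    """Copy chloroplast intervals into the mitogenome at target identity.

    ``segments`` is a list of (length, identity) pairs.  Source intervals
    are drawn without overlap from the cp genome and written over random
    non-overlapping, non-genic mt positions (mt length is preserved).
    Point substitutions are applied per base with probability
    1 - identity.  Returns the modified mt sequence and exact truth
    intervals (1-based inclusive) on both genomes.
    """
    lengths = [ln for ln, _ in segments]
    forbidden = [(a - 1, b) for a, b in (genic_intervals or [])]
    cp_starts = _place_nonoverlapping(rng, len(cp_seq), lengths, [])
    mt_starts = _place_nonoverlapping(rng, len(mt_seq), lengths, forbidden)
    mt = np.frombuffer(mt_seq.encode(), dtype=np.uint8).copy()
    truth: list[PlantedSegment] = []
    for (ln, identity), cs, ms in zip(segments, cp_starts, mt_starts):
        frag = np.frombuffer(cp_seq[cs : cs + ln].encode(), dtype=np.uint8).copy()
        n_mut = 0
        if identity < 1.0:
            mask = rng.random(ln) < (1.0 - identity)
            idx = np.searchsorted(_BASES, frag[mask])
            shifts = rng.integers(1, 4, size=int(mask.sum()))
            frag[mask] = _BASES[(idx + shifts) % 4]
            n_mut = int(mask.sum())
        mt[ms : ms + ln] = frag
        truth.append(
            PlantedSegment((ms + 1, ms + ln), (cs + 1, cs + ln), identity, n_mut)
        )
    return mt.tobytes().decode(), truth


# ---------------------------------------------------------------------------
# CDS sets with controlled codon bias
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def make_cds_set(
    codon_weights: dict[str, float],
    n_genes: int,
    gene_length_range: tuple[int, int],
    seed: int,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Generate CDS records with internal codons drawn from given weights.

    Genes begin with ATG, end with a stop codon (uniform over the three),
    and draw their internal codons from ``codon_weights`` with stop
    weights forced to zero.  ``gene_length_range`` is in internal codons.
    Returns the records and the exact tally of internal codons drawn.
    """
    rng = np.random.default_rng(seed)
    codons = sorted(c for c in codon_weights if c not in _STOPS)
    w = np.array([max(codon_weights[c], 0.0) for c in codons], dtype=float)
    if w.sum() <= 0:
        raise ConfigError("codon weights must include a positive non-stop weight")
    w = w / w.sum()
    lo, hi = gene_length_range
    if lo < 1 or hi < lo:
        raise ConfigError("invalid gene length range")
    records: list[SeqRecord] = []
    tally: dict[str, int] = {}
    for g in range(n_genes):
        n_internal = int(rng.integers(lo, hi + 1))
        drawn = rng.choice(len(codons), size=n_internal, p=w)
        internal = [codons[int(i)] for i in drawn]
        for c in internal:
            tally[c] = tally.get(c, 0) + 1
        stop = _STOPS[int(rng.integers(0, 3))]
        records.append(SeqRecord(f"gene{g + 1}", "ATG" + "".join(internal) + stop))
    return records, tally


# ---------------------------------------------------------------------------
# synthetic organelle genome pairs
# ---------------------------------------------------------------------------


def make_cp_genome(
    rng: np.random.Generator,
    length: int = 160_000,
    ir_length: int = 10_000,
) -> tuple[str, list[tuple[int, int]]]:
    """Random chloroplast-like genome with an inverted repeat pair.

    The IR copy is planted as the exact reverse complement of a segment in
    the first half, mimicking the canonical quadripartite structure.
    Returns the sequence and the two IR intervals (1-based inclusive).
    """
    if ir_length * 2 >= length:
        raise ConfigError("IR length too large for genome")
    seq = np.frombuffer(random_dna(rng, length).encode(), dtype=np.uint8).copy()
    a = length // 4
    b = 3 * length // 4
    ira = seq[a : a + ir_length].tobytes().decode()
    irb = revcomp(ira)
    seq[b : b + ir_length] = np.frombuffer(irb.encode(), dtype=np.uint8)
    return seq.tobytes().decode(), [(a + 1, a + ir_length), (b + 1, b + ir_length)]
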