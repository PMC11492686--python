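"""Codon counting and relative synonymous codon usage (RSCU).

RSCU(c) = n_c * k / sum(n_c' over the synonymous family of c), where k is
the family size; 1 means no bias.  Stop codons are tallied separately and
excluded; families with zero observations get an undefined (None) RSCU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .io_formats import SeqRecord

logger = logging.getLogger(__name__)


def _genetic_code(table_id: int) -> tuple[dict[str, str], tuple[str, ...]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), tuple(table.stop_codons)


@dataclass
class CodonCounts:
    counts: dict[str, int]
    stop_counts: dict[str, int]
    n_sequences: int
    skipped_codons: int
    table_id: int = 1

    @property
    def n_codons_total(self) -> int:
        return sum(self.counts.values())


def count_codons(cds_records: list[SeqRecord], table_id: int = 1) -> CodonCounts:
    """Frame-0 codon counts over a CDS set.

    Trailing incomplete codons are trimmed with a warning; codons
    containing N are skipped and tallied; stop codons are counted apart
    from sense codons.  Sequences shorter than 6 nt are skipped.
    """
    forward, stops = _genetic_code(table_id)
    counts: dict[str, int] = {}
    stop_counts: dict[str, int] = {}
    skipped = 0
    n_used = 0
    for rec in cds_records:
        seq = rec.sequence
        if len(seq) < 6:
            logger.warning("CDS %s shorter than 6 nt, skipped", rec.id)
            continue
        if len(seq) % 3:
            logger.warning("CDS %s length not a multiple of 3; trailing bases trimmed", rec.id)
            seq = seq[: len(seq) - len(seq) % 3]
        n_used += 1
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                skipped += 1
            elif codon in stops:
                stop_counts[codon] = stop_counts.get(codon, 0) + 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
    _ = forward  # families resolved at RSCU time
    return CodonCounts(counts, stop_counts, n_used, skipped, table_id)


@dataclass
class RscuTable:
    rscu: dict[str, float | None]
    amino_acid: dict[str, str]
    aa_frequency: dict[str, float] = field(default_factory=dict)

    def family(self, aa: str) -> list[str]:
        return [c for c, a in self.amino_acid.items() if a == aa]


def rscu(counts: CodonCounts) -> RscuTable:
    """RSCU per sense codon plus amino-acid frequency fractions.

    Within each synonymous family the mean RSCU is 1 whenever the family
    is observed; single-codon families (Met/ATG, Trp/TGG in the standard
    code) therefore sit at exactly 1.
    """
    forward, _ = _genetic_code(counts.table_id)
    families: dict[str, list[str]] = {}
    for codon, aa in forward.items():
        families.setdefault(aa, []).append(codon)
    values: dict[str, float | None] = {}
    aa_freq: dict[str, float] = {}
    total_sense = sum(counts.counts.get(c, 0) for c in forward)
    for aa, codons in families.items():
        family_total = sum(counts.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            if family_total == 0:
                values[c] = None
            else:
                values[c] = counts.counts.get(c, 0) * k / family_total
        aa_freq[aa] = family_total / total_sense if total_sense else 0.0
    return RscuTable(values, forward, aa_freq)


def write_rscu_table(table: RscuTable, counts: CodonCounts, path) -> None:
    """TSV: codon, amino acid, count, family fraction, RSCU."""
    total = counts.n_codons_total
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\tfraction\trscu\n")
        for codon in sorted(table.amino_acid):
            aa = table.amino_acid[codon]
            n = counts.counts.get(codon, 0)
            frac = n / total if total else 0.0
            val = table.rscu[codon]
            fh.write(
                f"{codon}\t{aa}\t{n}\t{frac:.6f}\t"
                f"{'NA' if val is None else f'{val:.4f}'}\n"
            )
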