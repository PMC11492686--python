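"""Packaged machine-readable transcriptions of the published contig
geometry, spanning-read counts, and transfer-segment totals for the two
study mitogenomes, so every in-paper number can be recomputed offline.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources

from .graph_model import ContigDef, GenomeModel, Oriented, RepeatElement

SPECIES = ("C_carlesii", "Ca_henryi")


def _data_text(name: str) -> str:
    return resources.files("mitorecomb.data").joinpath(name).read_text()


def _read_tsv(name: str) -> list[dict[str, str]]:
    return list(csv.DictReader(_data_text(name).splitlines(), delimiter="\t"))


def table1_rows(species: str) -> list[dict[str, str]]:
    return [r for r in _read_tsv("table1.tsv") if r["species"] == species]


def table1_fixture(species: str) -> GenomeModel:
    """Genome model for one species: contig/repeat lengths and depths from
    the published assembly table, reference placements and direct links
    from the published molecule paths."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    conf = json.loads(_data_text("conformations.json"))[species]
    model = GenomeModel()
    repeat_copies = conf["repeat_copies"]
    for row in table1_rows(species):
        length = int(row["length"])
        depth = float(row["depth"])
        if row["kind"] == "contig":
            model.contigs[row["id"]] = ContigDef(row["id"], length, depth)
        else:
            copies = [
                (Oriented(*left), Oriented(*right))
                for left, right in repeat_copies[row["id"]]
            ]
            model.repeats[row["id"]] = RepeatElement(row["id"], length, copies, depth)
    model.direct_links = [
        (Oriented(*a), Oriented(*b)) for a, b in conf["direct_links"]
    ]
    model.validate()
    return model


def published_molecules(species: str) -> list[dict[str, str]]:
    """Published representative molecule paths: path string + topology."""
    conf = json.loads(_data_text("conformations.json"))[species]
    return conf["molecules"]


@dataclass
class Table3Entry:
    repeat_id: str
    mode: str  # "standard" | "multicopy"
    path_counts: dict[str, int]
    path_conformation: dict[str, str]  # label -> "A" | "B"


def table3_counts(species: str) -> list[Table3Entry]:
    """Published per-path valid spanning-read counts, grouped by repeat."""
    entries: dict[str, Table3Entry] = {}
    for row in _read_tsv("table3.tsv"):
        if row["species"] != species:
            continue
        entry = entries.setdefault(
            row["repeat"], Table3Entry(row["repeat"], row["mode"], {}, {})
        )
        entry.path_counts[row["path_label"]] = int(row["count"])
        entry.path_conformation[row["path_label"]] = row["conformation"]
    return list(entries.values())


def mtpt_totals(species: str) -> tuple[int, int]:
    """(published MTPT merged total bp, published mitogenome length)."""
    for row in _read_tsv("mtpt_totals.tsv"):
        if row["species"] == species:
            return int(row["mtpt_total_bp"]), int(row["genome_size"])
    raise ValueError(f"unknown species {species!r}")
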