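"""Interaction ingest: pairwise lists, TAP bait-prey expansion, unions.

Tandem affinity purification (TAP-MS) reports one bait protein with the
set of preys that co-purified with it.  Pairwise interactions are derived
under one of two models: the *spoke* model links the bait to each prey;
the *matrix* model additionally links every pair of preys, i.e. all
unordered pairs over {bait} ∪ preys.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .network import WeightedNetwork, union_networks

logger = logging.getLogger(__name__)

__all__ = [
    "TAPRecord",
    "spoke_expand",
    "matrix_expand",
    "expand_records",
    "read_pairwise_tsv",
    "read_psimi_tab",
    "read_tap_tsv",
    "write_edges_tsv",
    "union_networks",
]


@dataclass
class TAPRecord:
    """One purification: a single bait and its (possibly empty) prey list."""

    bait: str
    preys: list[str] = field(default_factory=list)
    source_tag: str = ""


def spoke_expand(record: TAPRecord) -> set[frozenset[str]]:
    """Bait-to-each-prey pairs; duplicates and bait-as-prey collapse."""
    return {
        frozenset((record.bait, p)) for p in record.preys if p != record.bait
    }


def matrix_expand(record: TAPRecord) -> set[frozenset[str]]:
    """All unordered pairs over {bait} ∪ preys, no self-pairs."""
    members = sorted({record.bait, *record.preys})
    return {
        frozenset((members[i], members[j]))
        for i in range(len(members))
        for j in range(i + 1, len(members))
    }


def expand_records(
    records: Iterable[TAPRecord], model: Literal["spoke", "matrix"] = "spoke"
) -> WeightedNetwork:
    """Expand TAP records to a pairwise network under the chosen model.

    Each purification is expanded independently; duplicate purifications of
    the same bait are merged implicitly by the edge-set union.
    """
    expand = {"spoke": spoke_expand, "matrix": matrix_expand}[model]
    pairs: set[frozenset[str]] = set()
    for rec in records:
        pairs |= expand(rec)
    return WeightedNetwork.from_edges(tuple(sorted(p)) for p in pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _strip_accession(field_value: str) -> str:
    """Map a PSI-MI column-1/2 value like ``uniprotkb:P12345`` to an ID."""
    first = field_value.split("|")[0].strip()
    return first.split(":", 1)[1] if ":" in first else first


def read_pairwise_tsv(
    path: str | Path, allow_list: set[str] | None = None
) -> WeightedNetwork:
    """Read a two-column (plus optional source) TSV with a header line.

    Self-interactions are dropped with a warning; an optional allow-list
    restricts both interactors.
    """
    net = WeightedNetwork()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header required
        for row in reader:
            if len(row) < 2 or not row[0]:
                continue
            a, b = row[0].strip(), row[1].strip()
            if allow_list is not None and (a not in allow_list or b not in allow_list):
                continue
            net.add_edge(a, b)
    return net


def read_psimi_tab(
    path: str | Path, allow_list: set[str] | None = None
) -> WeightedNetwork:
    """Read PSI-MI TAB 2.5: interactor accessions from columns 1-2 only."""
    net = WeightedNetwork()
    with open(path, newline="") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            a, b = _strip_accession(cols[0]), _strip_accession(cols[1])
            if allow_list is not None and (a not in allow_list or b not in allow_list):
                continue
            net.add_edge(a, b)
    return net


def read_tap_tsv(path: str | Path) -> list[TAPRecord]:
    """Read TAP records: ``bait<TAB>prey1,prey2,...[<TAB>source]``; header line."""
    records: list[TAPRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if not row or not row[0]:
                continue
            preys = [p for p in row[1].split(",") if p] if len(row) > 1 else []
            tag = row[2] if len(row) > 2 else ""
            records.append(TAPRecord(bait=row[0].strip(), preys=preys, source_tag=tag))
    return records


def write_edges_tsv(net: WeightedNetwork, path: str | Path) -> None:
    """Write ``protein_a<TAB>protein_b<TAB>weight`` with a header line."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_a", "protein_b", "weight"])
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            writer.writerow([a, b, f"{net.weight(a, b):.10g}"])


def read_weighted_edges_tsv(path: str | Path) -> WeightedNetwork:
    """Read an edge TSV produced by :func:`write_edges_tsv` (weights kept)."""
    net = WeightedNetwork()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) < 2 or not row[0]:
                continue
            w = float(row[2]) if len(row) > 2 and row[2] else 1.0
            net.add_edge(row[0].strip(), row[1].strip(), weight=w)
    return net
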