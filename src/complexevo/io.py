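"""Readers and writers for the package's plain-text artefact formats.

All tabular formats are TSV with a header line; the ontology is OBO 1.2.
Every writer emits rows in sorted order so regeneration is byte-stable.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .complexes import ComplexDataset
from .ontology import GOResource

__all__ = [
    "read_complexes_tsv",
    "write_complexes_tsv",
    "write_obo",
    "write_gaf_tsv",
    "write_funcat_tsv",
    "write_tap_tsv",
]


def read_complexes_tsv(
    path: str | Path, provenance: str = "predicted"
) -> ComplexDataset:
    """Read ``complex_id<TAB>protein`` membership rows (header line)."""
    members: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) >= 2 and row[0]:
                members.setdefault(row[0], set()).add(row[1])
    return ComplexDataset(
        [frozenset(members[k]) for k in sorted(members)],
        provenance=provenance,  # type: ignore[arg-type]
    )


def write_complexes_tsv(ds: ComplexDataset, path: str | Path) -> None:
    """One row per membership: ``complex_id<TAB>protein``."""
    width = len(str(max(len(ds), 1)))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["complex_id", "protein"])
        for i, c in enumerate(ds):
            cid = f"C{i + 1:0{width}d}"
            for p in sorted(c):
                writer.writerow([cid, p])


def write_obo(
    parents: dict[str, set[str]],
    path: str | Path,
    namespace: str = "biological_process",
) -> None:
    """Write a minimal OBO 1.2 file of ``is_a`` term stanzas."""
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for term in sorted(parents):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {term}")
        lines.append(f"namespace: {namespace}")
        for parent in sorted(parents[term]):
            lines.append(f"is_a: {parent} ! {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf_tsv(
    annotations: dict[str, set[str]],
    path: str | Path,
    evidence: str = "EXP",
    aspect: str = "P",
) -> None:
    """Write protein, term, evidence, aspect rows (header line)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "term", "evidence", "aspect"])
        for p in sorted(annotations):
            for t in sorted(annotations[p]):
                writer.writerow([p, t, evidence, aspect])


def write_funcat_tsv(assignments: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "term"])
        for p in sorted(assignments):
            for t in sorted(assignments[p]):
                writer.writerow([p, t])


def write_tap_tsv(records, path: str | Path) -> None:
    """Write TAP records: ``bait<TAB>preys<TAB>source`` (header line)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["bait", "preys", "source"])
        for rec in records:
            writer.writerow([rec.bait, ",".join(rec.preys), rec.source_tag])


def go_resource_annotations(go: GOResource) -> dict[str, set[str]]:
    """Direct annotation sets of a GO resource (for GAF round-trips)."""
    return {p: set(ts) for p, ts in go.annotations.items()}
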