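"""Functional annotation of complexes by their modal level-1 term.

Each complex is labelled with the functional-category term carried by the
largest number of its annotated members (FunCat-style level-1 vocabulary;
proteins may carry several terms and count once towards each).  Complexes
with fewer than two annotated members are excluded rather than labelled.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .complexes import ComplexDataset

logger = logging.getLogger(__name__)

__all__ = ["FunctionTable", "modal_term", "function_profile", "read_funcat_tsv"]


@dataclass
class FunctionTable:
    """Protein → set of level-1 functional terms."""

    assignments: dict[str, set[str]] = field(default_factory=dict)

    def terms_of(self, protein: str) -> set[str]:
        return self.assignments.get(protein, set())


def modal_term(
    complex_members: frozenset[str] | set[str], ft: FunctionTable
) -> tuple[str, float] | None:
    """Most common term among annotated members and its coverage fraction.

    Coverage is counted over annotated members only.  Returns ``None`` for
    complexes with fewer than two annotated members (excluded, not an
    error).  Ties are broken towards the lexicographically smallest term
    and logged.
    """
    annotated = [p for p in sorted(complex_members) if ft.terms_of(p)]
    if len(annotated) < 2:
        return None
    counts: dict[str, int] = {}
    for p in annotated:
        for t in ft.terms_of(p):
            counts[t] = counts.get(t, 0) + 1
    best = max(counts.values())
    winners = sorted(t for t, c in counts.items() if c == best)
    if len(winners) > 1:
        logger.info("modal-term tie %s broken lexicographically", winners)
    return winners[0], best / len(annotated)


def function_profile(ds: ComplexDataset, ft: FunctionTable) -> pd.DataFrame:
    """Distribution of complexes over modal terms.

    Returns one row per modal term with columns ``term``, ``n_complexes``
    and ``proportion`` (over included complexes); the number of excluded
    complexes (<2 annotated members) is in ``frame.attrs["n_excluded"]``
    and per-complex coverages in ``frame.attrs["coverages"]``.
    """
    term_counts: dict[str, int] = {}
    coverages: list[float] = []
    n_excluded = 0
    for c in ds:
        res = modal_term(c, ft)
        if res is None:
            n_excluded += 1
            continue
        term, cov = res
        term_counts[term] = term_counts.get(term, 0) + 1
        coverages.append(cov)
    total = sum(term_counts.values())
    frame = pd.DataFrame(
        [
            {"term": t, "n_complexes": c, "proportion": c / total}
            for t, c in sorted(term_counts.items())
        ],
        columns=["term", "n_complexes", "proportion"],
    )
    frame.attrs["n_excluded"] = n_excluded
    frame.attrs["coverages"] = coverages
    return frame


def read_funcat_tsv(path: str | Path) -> FunctionTable:
    """Read ``protein<TAB>term`` rows (header line) into a FunctionTable."""
    table = FunctionTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) >= 2 and row[0]:
                table.assignments.setdefault(row[0], set()).add(row[1])
    return table
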