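"""Gene Ontology semantics: information content, Resnik similarity, GOSS.

Terms form a rooted DAG of ``is_a`` relations.  A term's information
content is IC(t) = −ln(n(t)/n(root)), where n(t) counts distinct proteins
whose *propagated* annotation set (direct terms plus all ancestors)
contains t.  The Resnik similarity of two terms is the IC of their
most-informative common ancestor; the protein-level GOSS score is the
maximum Resnik similarity over all pairs of their directly annotated
terms.  Network edges are weighted 1 + GOSS, so the unannotated case
degrades gracefully to the unweighted network.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GOResource",
    "information_content",
    "resnik_similarity",
    "protein_goss",
    "weight_edges",
    "filter_annotations",
    "read_obo",
    "read_gaf_tsv",
]


@dataclass
class GOResource:
    """A GO DAG plus propagated protein annotations and IC table.

    Parameters
    ----------
    parents
        ``is_a`` edges, child → set of parents.  Must be acyclic with a
        single root (a term with no parents).
    annotations
        Direct protein → term-set assignments.
    """

    parents: dict[str, set[str]]
    annotations: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(init=False)
    ic: dict[str, float] = field(init=False)
    root: str = field(init=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a relation contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root term, found {roots!r}")
        self.root = roots[0]
        self._dag = g
        self._ancestors: dict[str, frozenset[str]] = {
            t: frozenset(nx.descendants(g, t)) | {t} for t in g.nodes
        }
        unknown = {
            t for ts in self.annotations.values() for t in ts if t not in self.parents
        }
        if unknown:
            raise ValueError(f"annotations reference unknown terms: {sorted(unknown)[:5]}")
        self.propagated = {
            p: set().union(*(self._ancestors[t] for t in ts)) if ts else set()
            for p, ts in self.annotations.items()
        }
        # term frequency = number of distinct proteins carrying the term
        # after propagation; IC relative to the root's count.
        counts: dict[str, int] = {t: 0 for t in self.parents}
        for ts in self.propagated.values():
            for t in ts:
                counts[t] += 1
        self.term_counts = counts
        total = counts[self.root]
        self.ic = {
            t: -math.log(c / total) for t, c in counts.items() if c > 0 and total > 0
        }

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of ``term`` (the term included)."""
        return self._ancestors[term]


def information_content(go: GOResource, term: str) -> float:
    """IC(t) = −ln(n(t)/n(root)) over propagated annotation counts.

    Raises
    ------
    KeyError
        If the term has zero propagated annotations (IC undefined; such
        terms are excluded from scoring).
    """
    if term not in go.terms:
        raise KeyError(f"unknown term {term!r}")
    if term not in go.ic:
        raise KeyError(f"term {term!r} has no propagated annotations; IC undefined")
    return go.ic[term]


def resnik_similarity(go: GOResource, t1: str, t2: str) -> float:
    """IC of the most-informative common ancestor (terms are their own
    ancestors); 0 when the only shared ancestor is the root."""
    common = go.ancestors(t1) & go.ancestors(t2)
    scored = [go.ic[t] for t in common if t in go.ic]
    return max(scored, default=0.0)


def protein_goss(go: GOResource, p: str, q: str) -> float:
    """Highest Resnik similarity over the direct term sets of two proteins.

    Unannotated proteins score 0, as do term pairs whose only common
    ancestor is the root.
    """
    tp = go.annotations.get(p, set())
    tq = go.annotations.get(q, set())
    if not tp or not tq:
        return 0.0
    return max(resnik_similarity(go, a, b) for a in tp for b in tq)


def weight_edges(net: WeightedNetwork, go: GOResource) -> WeightedNetwork:
    """Set every edge weight to 1 + GOSS(endpoints); topology unchanged.

    Idempotent: weights are recomputed from the same similarity each time.
    """
    out = net.copy()
    for a, b in out.edges():
        out.set_weight(a, b, 1.0 + protein_goss(go, a, b))
    return out


def filter_annotations(
    gaf_rows: Iterable[tuple[str, str, str, str]], include_iea: bool = False
) -> dict[str, set[str]]:
    """Filter (protein, term, evidence, aspect) rows to usable annotations.

    ND (no biological data) is always dropped; IEA is dropped unless
    ``include_iea``; only the biological-process aspect (``P``) is kept.
    Malformed evidence codes skip the row with a warning.
    """
    out: dict[str, set[str]] = {}
    for protein, term, evidence, aspect in gaf_rows:
        ev = evidence.strip().upper()
        if not ev.isalpha() or not (2 <= len(ev) <= 3):
            logger.warning("skipping row with malformed evidence code %r", evidence)
            continue
        if aspect.strip().upper() != "P":
            continue
        if ev == "ND":
            continue
        if ev == "IEA" and not include_iea:
            continue
        out.setdefault(protein, set()).add(term)
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_obo(
    path: str | Path,
    namespace: str | None = "biological_process",
    include_part_of: bool = False,
) -> dict[str, set[str]]:
    """Read an OBO 1.2 file into a child → parent-set mapping.

    Only ``is_a`` edges are traversed by default (``part_of`` optionally);
    obsolete terms are dropped by obonet.  ``namespace=None`` keeps all
    namespaces (single-root check happens at :class:`GOResource` build).
    """
    g = obonet.read_obo(path)
    keys = {"is_a"} | ({"part_of"} if include_part_of else set())
    parents: dict[str, set[str]] = {}
    for term, data in g.nodes(data=True):
        if namespace is not None and data.get("namespace", namespace) != namespace:
            continue
        parents.setdefault(term, set())
    for child, parent, key in g.edges(keys=True):
        if key in keys and child in parents and parent in parents:
            parents[child].add(parent)
    return parents


def read_gaf_tsv(path: str | Path) -> list[tuple[str, str, str, str]]:
    """Read a GAF-like TSV: protein, term, evidence, aspect; header line."""
    rows: list[tuple[str, str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) >= 4 and row[0]:
                rows.append((row[0], row[1], row[2], row[3]))
    return rows


def build_go(
    parents: dict[str, set[str]], annotations: dict[str, set[str]]
) -> GOResource:
    """Convenience constructor restricting annotations to known terms."""
    known = {
        p: {t for t in ts if t in parents} for p, ts in annotations.items()
    }
    return GOResource(parents=parents, annotations=known)
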