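"""Phylogenetic age profiling from bidirectional-best-hit orthologues.

Orthologues are called as mutual best hits between two species'
similarity tables (E ≤ 0.01 by default); each protein's orthologue
presence pattern across clades maps to an ordered age group
(species-specific → Universal), and age distributions of protein classes
are compared with a chi-square test of homogeneity.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologyProfile",
    "AgeGroupRules",
    "bbh_orthologues",
    "assign_age_group",
    "age_distribution",
    "age_chisq",
    "ecoli_age_rules",
    "yeast_age_rules",
    "read_similarity_tsv",
    "read_orthology_tsv",
    "write_orthology_tsv",
]


@dataclass
class OrthologyProfile:
    """Per-protein orthologue presence and assigned age group.

    ``group_order`` runs youngest → oldest; ``presence`` maps each protein
    to the set of non-focal species with an orthologue.
    """

    presence: dict[str, set[str]]
    age_group: dict[str, str]
    group_order: list[str]
    clade_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g for g in self.age_group.values() if g not in self.group_order}
        if bad:
            raise ValueError(f"age groups not in group_order: {sorted(bad)}")


def bbh_orthologues(
    sim: pd.DataFrame,
    species_x: str,
    species_y: str,
    e_max: float = 0.01,
    strict_unique: bool = False,
) -> set[tuple[str, str]]:
    """Bidirectional best hits between two species.

    ``sim`` has columns query, query_species, target, target_species,
    e_value.  A pair (x, y) qualifies when y is x's minimum-E target in
    species_y, x is y's minimum-E target in species_x, and both E-values
    are ≤ ``e_max``.  By default any tied best hit satisfies the
    condition; ``strict_unique`` requires the best hit to be unique.
    """
    def best_hits(qs: str, ts: str) -> dict[str, set[str]]:
        sub = sim[
            (sim["query_species"] == qs)
            & (sim["target_species"] == ts)
            & (sim["e_value"] <= e_max)
        ]
        out: dict[str, set[str]] = {}
        for query, grp in sub.groupby("query"):
            emin = grp["e_value"].min()
            best = set(grp.loc[grp["e_value"] == emin, "target"])
            if strict_unique and len(best) > 1:
                continue
            out[query] = best
        return out

    fwd = best_hits(species_x, species_y)
    rev = best_hits(species_y, species_x)
    pairs: set[tuple[str, str]] = set()
    for x, ys in fwd.items():
        for y in ys:
            if x in rev.get(y, set()):
                pairs.add((x, y))
    return pairs


@dataclass
class AgeGroupRules:
    """Clade-presence pattern → age-group label, as configuration data.

    ``patterns`` maps frozensets of clade labels to group labels and must
    include the empty pattern (the species-specific group).  Patterns with
    no exact rule fall back to the first matching entry of ``precedence``:
    (required subset, label) pairs tried in order; such assignments are
    logged as flagged.
    """

    patterns: dict[frozenset[str], str]
    precedence: list[tuple[frozenset[str], str]] = field(default_factory=list)
    group_order: list[str] = field(default_factory=list)

    def label(self, clade_pattern: frozenset[str]) -> str:
        if clade_pattern in self.patterns:
            return self.patterns[clade_pattern]
        for required, lab in self.precedence:
            if required <= clade_pattern:
                logger.info(
                    "pattern %s has no exact rule; mapped to %r by precedence",
                    sorted(clade_pattern), lab,
                )
                return lab
        raise KeyError(
            f"no age-group rule for clade pattern {sorted(clade_pattern)}"
        )


def assign_age_group(
    presence: set[str], clade_map: dict[str, str], rules: AgeGroupRules
) -> str:
    """Collapse species presence to a clade pattern and map it to a label.

    A clade is present when at least one of its species holds an
    orthologue; the count per species never matters.
    """
    unknown = {s for s in presence if s not in clade_map}
    if unknown:
        raise KeyError(f"species without clade assignment: {sorted(unknown)}")
    pattern = frozenset(clade_map[s] for s in presence)
    return rules.label(pattern)


def build_profile(
    presence: dict[str, set[str]],
    clade_map: dict[str, str],
    rules: AgeGroupRules,
) -> OrthologyProfile:
    """Assign every protein an age group from its presence set."""
    groups = {
        p: assign_age_group(sp, clade_map, rules) for p, sp in presence.items()
    }
    return OrthologyProfile(
        presence=presence,
        age_group=groups,
        group_order=list(rules.group_order),
        clade_map=dict(clade_map),
    )


def age_distribution(
    proteins: set[str], profile: OrthologyProfile
) -> pd.DataFrame:
    """Histogram of a protein set over the ordered age groups.

    Proteins without an assigned group land in an explicit ``unassigned``
    bucket; percentages are over all counted proteins.
    """
    counts = {g: 0 for g in profile.group_order}
    counts["unassigned"] = 0
    for p in sorted(proteins):
        counts[profile.age_group.get(p, "unassigned")] += 1
    total = sum(counts.values())
    frame = pd.DataFrame(
        {
            "group": list(counts),
            "count": list(counts.values()),
        }
    )
    frame["percent"] = 100.0 * frame["count"] / total if total else 0.0
    return frame


def age_chisq(
    class_counts: "list[int] | np.ndarray | pd.DataFrame",
    background_counts: "list[int] | np.ndarray | pd.DataFrame",
    pool_small: bool = True,
) -> tuple[float, int, float]:
    """Chi-square test of homogeneity between two age histograms.

    Accepts raw count vectors (aligned over the same ordered groups) or
    frames from :func:`age_distribution`.  No continuity correction.  With
    ``pool_small`` (default), groups whose expected count falls below 5
    are pooled into the neighbouring older group, preserving group order;
    pooling is logged.
    """
    def as_vector(c) -> np.ndarray:
        if isinstance(c, pd.DataFrame):
            return c["count"].to_numpy(dtype=float)
        return np.asarray(c, dtype=float)

    a = as_vector(class_counts)
    b = as_vector(background_counts)
    if a.shape != b.shape:
        raise ValueError("count vectors must align over the same groups")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("all counts are zero in one class")

    if pool_small:
        a, b = _pool_small_expected(a, b)
    if len(a) < 2:
        raise ValueError("fewer than 2 groups remain after pooling")
    table = np.vstack([a, b])
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def _pool_small_expected(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool adjacent groups (towards older) until all expected counts >= 5."""
    a, b = a.copy(), b.copy()
    while len(a) > 2:
        table = np.vstack([a, b])
        expected = (
            table.sum(axis=1, keepdims=True)
            @ table.sum(axis=0, keepdims=True)
            / table.sum()
        )
        small = np.nonzero(expected.min(axis=0) < 5)[0]
        if len(small) == 0:
            break
        i = int(small[0])
        j = i + 1 if i + 1 < len(a) else i - 1  # pool into next (older) group
        logger.info("pooling age group %d into %d (expected count < 5)", i, j)
        a[j] += a[i]
        b[j] += b[i]
        a = np.delete(a, i)
        b = np.delete(b, i)
    return a, b


# ---------------------------------------------------------------------------
# shipped age-group vocabularies
# ---------------------------------------------------------------------------


def ecoli_age_rules() -> tuple[AgeGroupRules, dict[str, str]]:
    """Age groups for an E. coli focal species over five clade labels.

    Clades: ``Proteobacteria``, ``Firmicutes``, ``OtherBacteria``,
    ``Archaea``, ``Eukaryota``.  The returned clade map is empty — supply
    your own species → clade mapping alongside these rules.
    """
    P, F, O, A, E = (
        "Proteobacteria",
        "Firmicutes",
        "OtherBacteria",
        "Archaea",
        "Eukaryota",
    )
    groups = [
        "E. coli K12-specific",
        "Proteobacteria",
        "Proteobacteria Firmicutes",
        "Bacteria",
        "Eukaryota+Bacteria",
        "Bacteria+Archaea",
        "Universal",
    ]
    patterns: dict[frozenset[str], str] = {
        frozenset(): groups[0],
        frozenset({P}): groups[1],
        frozenset({P, F}): groups[2],
        frozenset({P, O}): groups[3],
        frozenset({F, O}): groups[3],
        frozenset({P, F, O}): groups[3],
        frozenset({F}): groups[3],
        frozenset({O}): groups[3],
    }
    bacteria_subsets = [
        frozenset(s)
        for s in ([P], [F], [O], [P, F], [P, O], [F, O], [P, F, O])
    ]
    for bs in bacteria_subsets:
        patterns[bs | {E}] = groups[4]
        patterns[bs | {A}] = groups[5]
        patterns[bs | {A, E}] = groups[6]
    precedence = [
        (frozenset({A, E}), groups[6]),
        (frozenset({E}), groups[4]),
        (frozenset({A}), groups[5]),
    ]
    rules = AgeGroupRules(
        patterns=patterns, precedence=precedence, group_order=groups
    )
    return rules, {}


def yeast_age_rules() -> tuple[AgeGroupRules, dict[str, str]]:
    """Age groups for a yeast focal species over five clade labels.

    Clades: ``Fungi``, ``Metazoa``, ``OtherEukaryota``, ``Archaea``,
    ``Bacteria``.
    """
    F, M, O, A, B = "Fungi", "Metazoa", "OtherEukaryota", "Archaea", "Bacteria"
    groups = [
        "S. cerevisiae-specific",
        "Fungi",
        "Fungi Metazoa",
        "Eukaryota",
        "Eukaryota+Archaea",
        "Eukaryota+Bacteria",
        "Universal",
    ]
    patterns: dict[frozenset[str], str] = {
        frozenset(): groups[0],
        frozenset({F}): groups[1],
        frozenset({F, M}): groups[2],
        frozenset({F, O}): groups[3],
        frozenset({M, O}): groups[3],
        frozenset({F, M, O}): groups[3],
        frozenset({M}): groups[3],
        frozenset({O}): groups[3],
    }
    euk_subsets = [
        frozenset(s)
        for s in ([F], [M], [O], [F, M], [F, O], [M, O], [F, M, O])
    ]
    for es in euk_subsets:
        patterns[es | {A}] = groups[4]
        patterns[es | {B}] = groups[5]
        patterns[es | {A, B}] = groups[6]
    precedence = [
        (frozenset({A, B}), groups[6]),
        (frozenset({B}), groups[5]),
        (frozenset({A}), groups[4]),
    ]
    rules = AgeGroupRules(
        patterns=patterns, precedence=precedence, group_order=groups
    )
    return rules, {}


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------


def read_similarity_tsv(path: str | Path) -> pd.DataFrame:
    """Read query, query_species, target, target_species, e_value TSV."""
    frame = pd.read_csv(path, sep="\t")
    expected = ["query", "query_species", "target", "target_species", "e_value"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"similarity table missing columns: {missing}")
    return frame


def read_orthology_tsv(
    path: str | Path, group_order: list[str]
) -> OrthologyProfile:
    """Read ``protein<TAB>age_group<TAB>species1,species2,...``; header line."""
    presence: dict[str, set[str]] = {}
    age_group: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if not row or not row[0]:
                continue
            presence[row[0]] = (
                {s for s in row[2].split(",") if s} if len(row) > 2 else set()
            )
            age_group[row[0]] = row[1]
    return OrthologyProfile(
        presence=presence, age_group=age_group, group_order=group_order
    )


def write_orthology_tsv(profile: OrthologyProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "age_group", "species"])
        for p in sorted(profile.age_group):
            writer.writerow(
                [p, profile.age_group[p], ",".join(sorted(profile.presence.get(p, set())))]
            )
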