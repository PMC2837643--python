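"""Domain-superfamily homology statistics over complex datasets.

Two proteins are *domain homologues* when they share at least one domain
superfamily, and *protein homologues* when their entire multi-domain
architectures (MDAs, the N→C order of superfamilies with tandem repeats
collapsed) are identical.  Every statistic here asks whether an observed
co-complex count exceeds what size-preserving membership shuffles of the
complex dataset produce: superfamily-wise co-occurrence (with BH-FDR
across superfamilies), complex-wise homologous-pair content, interaction
enrichment of homologous pairs, the member-count vs complex-count spread,
and functional coherence of superfamily members.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from ._permutation import MembershipShuffler, empirical_p
from .complexes import ComplexDataset, cocomplex_pairs, shuffle_complexes
from .network import WeightedNetwork
from .ontology import GOResource, protein_goss

logger = logging.getLogger(__name__)

__all__ = [
    "DomainAnnotation",
    "PermutationResult",
    "shuffle_complexes",
    "cocomplex_pair_count",
    "superfamily_distribution_test",
    "bh_fdr",
    "complexes_with_homolog_pairs",
    "pair_interaction_enrichment",
    "spread_regression",
    "superfamily_function_coherence",
    "read_domains_tsv",
    "write_domains_tsv",
]


def _collapse_repeats(sfams: list[str]) -> tuple[str, ...]:
    out: list[str] = []
    for s in sfams:
        if not out or out[-1] != s:
            out.append(s)
    return tuple(out)


@dataclass
class DomainAnnotation:
    """Per-protein ordered superfamily lists (multi-domain architectures).

    Consecutive repeats of a superfamily are collapsed on construction
    (tandem repeats are ignored for architecture comparison), and the set
    view used for domain homology keeps each superfamily at most once per
    protein.
    """

    mda: dict[str, tuple[str, ...]]
    superfamily_index: dict[str, set[str]] = field(init=False)

    def __init__(self, mda: dict[str, list[str] | tuple[str, ...]]):
        self.mda = {p: _collapse_repeats(list(sf)) for p, sf in mda.items() if sf}
        index: dict[str, set[str]] = {}
        for p, sfams in self.mda.items():
            for s in set(sfams):
                index.setdefault(s, set()).add(p)
        self.superfamily_index = index

    def superfamilies_of(self, protein: str) -> frozenset[str]:
        return frozenset(self.mda.get(protein, ()))

    @property
    def superfamilies(self) -> set[str]:
        return set(self.superfamily_index)

    def share_domain(self, p: str, q: str) -> bool:
        return bool(self.superfamilies_of(p) & self.superfamilies_of(q))

    def share_architecture(self, p: str, q: str) -> bool:
        a, b = self.mda.get(p), self.mda.get(q)
        return a is not None and a == b


@dataclass
class PermutationResult:
    observed: float
    null_counts: np.ndarray
    p_value: float
    n_rand: int


# ---------------------------------------------------------------------------
# superfamily-wise co-occurrence
# ---------------------------------------------------------------------------


def cocomplex_pair_count(
    sfam: str, ds: ComplexDataset, da: DomainAnnotation
) -> int:
    """Unordered protein pairs both carrying ``sfam`` that share a complex."""
    carriers = da.superfamily_index.get(sfam, set())
    total = 0
    for c in ds:
        k = len(c & carriers)
        total += k * (k - 1) // 2
    return total


def bh_fdr(p_values: list[float], alpha: float) -> set[int]:
    """Benjamini-Hochberg step-up: indices significant at level ``alpha``."""
    m = len(p_values)
    if m == 0:
        return set()
    order = np.argsort(p_values)
    sorted_p = np.asarray(p_values)[order]
    below = np.nonzero(sorted_p <= alpha * (np.arange(m) + 1) / m)[0]
    if len(below) == 0:
        return set()
    k = below[-1]
    return set(int(i) for i in order[: k + 1])


def superfamily_distribution_test(
    ds: ComplexDataset,
    da: DomainAnnotation,
    min_members: int = 5,
    n_rand: int = 10000,
    alpha: float = 0.01,
    seed: int = 0,
    strict: bool = False,
) -> tuple[dict[str, PermutationResult], set[str]]:
    """Per-superfamily co-complex pair counts against the membership-shuffle
    null, BH-FDR corrected across superfamilies.

    Only superfamilies with at least ``min_members`` members among the
    dataset's proteins are tested.  All superfamilies share one shuffle
    stream: each randomised dataset is scored for every superfamily at
    once (dataset-level randomisation).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    shuffler = MembershipShuffler.from_dataset(ds)
    member_pool = set(shuffler.proteins)
    members_in_ds = {
        s: carriers & member_pool
        for s, carriers in da.superfamily_index.items()
    }
    sfams = sorted(s for s, m in members_in_ds.items() if len(m) >= min_members)
    if not sfams:
        return {}, set()

    features = np.zeros((len(shuffler.proteins), len(sfams)))
    pindex = {p: i for i, p in enumerate(shuffler.proteins)}
    for j, s in enumerate(sfams):
        for p in members_in_ds[s]:
            features[pindex[p], j] = 1.0

    def pair_counts(counts: np.ndarray) -> np.ndarray:
        return (counts * (counts - 1) / 2).sum(axis=0)

    observed = pair_counts(shuffler.feature_counts(features))
    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, len(sfams)))
    for r, counts in enumerate(
        shuffler.null_feature_counts(features, n_rand, rng)
    ):
        null[r] = pair_counts(counts)

    results: dict[str, PermutationResult] = {}
    p_list: list[float] = []
    for j, s in enumerate(sfams):
        p = empirical_p(observed[j], null[:, j], strict=strict)
        results[s] = PermutationResult(
            observed=float(observed[j]),
            null_counts=null[:, j],
            p_value=p,
            n_rand=n_rand,
        )
        p_list.append(p)
    significant = {sfams[i] for i in bh_fdr(p_list, alpha)}
    return results, significant


# ---------------------------------------------------------------------------
# complex-wise homologous pairs
# ---------------------------------------------------------------------------


@dataclass
class HomologPairResult:
    count: int
    fraction: float
    fold_vs_null: float
    permutation: PermutationResult
    pairs: list[tuple[str, str]]


def _homolog_feature_matrix(
    shuffler: MembershipShuffler, da: DomainAnnotation, mode: str
) -> np.ndarray:
    """One-hot matrix whose columns witness homology when a complex count
    reaches 2: superfamilies (domain mode) or whole MDAs (architecture)."""
    proteins = shuffler.proteins
    pindex = {p: i for i, p in enumerate(proteins)}
    if mode == "domain":
        keys = sorted({s for p in proteins for s in da.superfamilies_of(p)})
        kindex = {k: j for j, k in enumerate(keys)}
        features = np.zeros((len(proteins), len(keys)))
        for p in proteins:
            for s in da.superfamilies_of(p):
                features[pindex[p], kindex[s]] = 1.0
    elif mode == "architecture":
        keys = sorted({da.mda[p] for p in proteins if p in da.mda})
        kindex = {k: j for j, k in enumerate(keys)}
        features = np.zeros((len(proteins), len(keys)))
        for p in proteins:
            if p in da.mda:
                features[pindex[p], kindex[da.mda[p]]] = 1.0
    else:
        raise ValueError(f"unknown homology mode {mode!r}")
    return features


def complexes_with_homolog_pairs(
    ds: ComplexDataset,
    da: DomainAnnotation,
    mode: str = "domain",
    n_rand: int = 10000,
    seed: int = 0,
    strict: bool = False,
) -> HomologPairResult:
    """Count complexes containing at least one homologous protein pair.

    ``mode='domain'``: a pair shares ≥1 superfamily; ``mode='architecture'``:
    identical MDAs.  Proteins without domain annotation occupy shuffle
    slots but can never form homologous pairs.
    """
    shuffler = MembershipShuffler.from_dataset(ds)
    features = _homolog_feature_matrix(shuffler, da, mode)

    def n_with_pair(counts: np.ndarray) -> int:
        if counts.shape[1] == 0:
            return 0
        return int((counts >= 2).any(axis=1).sum())

    observed = n_with_pair(shuffler.feature_counts(features))
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            n_with_pair(c)
            for c in shuffler.null_feature_counts(features, n_rand, rng)
        ]
    )
    p = empirical_p(observed, null, strict=strict)

    related = (
        da.share_domain if mode == "domain" else da.share_architecture
    )
    pairs: list[tuple[str, str]] = []
    for c in ds:
        members = sorted(c)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if related(members[i], members[j]):
                    pairs.append((members[i], members[j]))

    null_mean = float(null.mean())
    return HomologPairResult(
        count=observed,
        fraction=observed / len(ds) if len(ds) else 0.0,
        fold_vs_null=observed / null_mean if null_mean > 0 else float("inf"),
        permutation=PermutationResult(
            observed=observed, null_counts=null, p_value=p, n_rand=n_rand
        ),
        pairs=pairs,
    )


def pair_interaction_enrichment(
    pairs: list[tuple[str, str]],
    ds: ComplexDataset,
    net: WeightedNetwork,
    n_rand: int = 10000,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """Empirical p that the given co-complex pairs interact more often than
    equally many random co-complex pairs."""
    if not pairs:
        raise ValueError("no pairs to test")
    all_pairs = sorted(tuple(sorted(p)) for p in cocomplex_pairs(ds))
    k = len(pairs)
    if len(all_pairs) < k:
        raise ValueError(
            f"only {len(all_pairs)} co-complex pairs available, need {k}"
        )
    is_edge = np.array([net.has_edge(a, b) for a, b in all_pairs], dtype=float)
    observed = float(np.mean([net.has_edge(a, b) for a, b in pairs]))
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            is_edge[rng.choice(len(all_pairs), size=k, replace=False)].mean()
            for _ in range(n_rand)
        ]
    )
    return empirical_p(observed, null, strict=strict)


# ---------------------------------------------------------------------------
# superfamily spread and functional coherence
# ---------------------------------------------------------------------------


def spread_regression(
    da: DomainAnnotation, ds: ComplexDataset
) -> tuple[list[tuple[int, int]], float | None]:
    """Superfamily member count vs number of complexes containing members.

    Least-squares line through one point per superfamily (counted over the
    dataset's proteins); returns the points and the r² of the fit, or
    ``None`` when the member counts are degenerate (no x-variance).
    """
    proteins = ds.proteins
    points: list[tuple[int, int]] = []
    for s in sorted(da.superfamilies):
        members = da.superfamily_index[s] & proteins
        if not members:
            continue
        n_complexes = sum(1 for c in ds if c & members)
        points.append((len(members), n_complexes))
    if len(points) < 2:
        raise ValueError("need at least 2 superfamilies with members")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return points, None
    fit = stats.linregress(x, y)
    return points, float(fit.rvalue**2)


def _mean_pairwise_goss(go: GOResource, proteins: list[str]) -> float:
    vals = [
        protein_goss(go, proteins[i], proteins[j])
        for i in range(len(proteins))
        for j in range(i + 1, len(proteins))
    ]
    return float(np.mean(vals))


def superfamily_function_coherence(
    sfam: str,
    da: DomainAnnotation,
    go: GOResource,
    n_rand: int = 10000,
    seed: int = 0,
    mode: str = "members",
    net: WeightedNetwork | None = None,
    strict: bool = False,
) -> float | None:
    """Are a superfamily's members (or their interactors) functionally more
    similar than random annotated proteins?

    ``members`` mode compares the mean pairwise GOSS among annotated
    members against equal-size random sets drawn from the annotated
    background.  ``interactors`` mode compares the mean GOSS between the
    network neighbourhoods of distinct members against those of random
    annotated proteins.  Returns ``None`` (skipped) when fewer than two
    members qualify.
    """
    rng = np.random.default_rng(seed)
    annotated = sorted(p for p, ts in go.annotations.items() if ts)
    if mode == "members":
        members = sorted(
            p for p in da.superfamily_index.get(sfam, set()) if go.annotations.get(p)
        )
        if len(members) < 2:
            logger.info("superfamily %s: <2 annotated members, skipped", sfam)
            return None
        background = annotated
        observed = _mean_pairwise_goss(go, members)

        def stat(sample: list[str]) -> float:
            return _mean_pairwise_goss(go, sample)

    elif mode == "interactors":
        if net is None:
            raise ValueError("interactors mode requires a network")
        neighbours = {
            p: sorted(net.graph.neighbors(p)) for p in net.graph.nodes
        }
        members = sorted(
            p
            for p in da.superfamily_index.get(sfam, set())
            if neighbours.get(p)
        )
        if len(members) < 2:
            logger.info("superfamily %s: <2 members with interactors, skipped", sfam)
            return None
        background = sorted(p for p in annotated if neighbours.get(p))
        if len(background) < len(members):
            raise ValueError("background smaller than member set")

        def cross_goss(u: str, v: str) -> float:
            vals = [
                protein_goss(go, x, y)
                for x in neighbours[u]
                for y in neighbours[v]
                if x != y
            ]
            return float(np.mean(vals)) if vals else 0.0

        def stat(sample: list[str]) -> float:
            vals = [
                cross_goss(sample[i], sample[j])
                for i in range(len(sample))
                for j in range(i + 1, len(sample))
            ]
            return float(np.mean(vals))

        observed = stat(members)
    else:
        raise ValueError(f"unknown coherence mode {mode!r}")

    k = len(members)
    null = np.array(
        [
            stat(list(np.asarray(background)[rng.choice(len(background), size=k, replace=False)]))
            for _ in range(n_rand)
        ]
    )
    return empirical_p(observed, null, strict=strict)


# ---------------------------------------------------------------------------
# io
# ---------------------------------------------------------------------------


def read_domains_tsv(path: str | Path) -> DomainAnnotation:
    """Read ``protein<TAB>sfam1,sfam2,...`` (ordered N→C); header line."""
    mda: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if len(row) >= 2 and row[0] and row[1]:
                mda[row[0]] = [s for s in row[1].split(",") if s]
    return DomainAnnotation(mda)


def write_domains_tsv(da: DomainAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "superfamilies"])
        for p in sorted(da.mda):
            writer.writerow([p, ",".join(da.mda[p])])
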