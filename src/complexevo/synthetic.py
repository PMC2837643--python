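"""Synthetic worlds with planted structure for every pipeline stage.

The generator emulates the statistical structure the analysis assumes —
modular interaction networks with planted complexes (dense within, sparse
between), TAP purifications with false positives and negatives, domain
annotations with a controllable fraction of co-complex homologous pairs
and planted correlated superfamily pairs, a small rooted GO DAG with
propagated annotations, and orthologue age profiles with an old-shifted
planted core.  It makes no attempt to match the degree distribution of
real interactome resources; only the modularity structure matters here.

One global integer seed fans out to per-stage child seeds through
``numpy.random.SeedSequence([seed, crc32(stage_name)])``, so each stage is
independently reproducible and regenerating a world with the same seed
and parameters is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .complexes import ComplexDataset
from .homology import DomainAnnotation, write_domains_tsv
from .interactions import TAPRecord, write_edges_tsv
from .io import (
    write_complexes_tsv,
    write_funcat_tsv,
    write_gaf_tsv,
    write_obo,
    write_tap_tsv,
)
from .network import WeightedNetwork
from .ontology import GOResource
from .phylo import OrthologyProfile, write_orthology_tsv

__all__ = [
    "TruncatedGeometric",
    "PlantedWorld",
    "stage_seed",
    "generate_planted_pin",
    "generate_tap_records",
    "generate_domain_annotations",
    "generate_go",
    "generate_orthology",
    "generate_world",
    "write_world",
]


def stage_seed(seed: int, stage: str) -> np.random.Generator:
    """Child RNG for a named stage, derived from the global seed.

    The derivation is ``SeedSequence([seed, crc32(stage)])`` — fixed, so
    every stage can be regenerated on its own.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


@dataclass
class TruncatedGeometric:
    """Right-skewed complex-size distribution on [lo, hi].

    P(k) ∝ (1 − p)^(k − lo): most complexes are small, a few are large,
    echoing the size distribution of clustered interactomes.
    """

    p: float = 0.25
    lo: int = 2
    hi: int = 30

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        ks = np.arange(self.lo, self.hi + 1)
        weights = (1 - self.p) ** (ks - self.lo)
        weights /= weights.sum()
        return rng.choice(ks, size=size, p=weights)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# planted interaction network
# ---------------------------------------------------------------------------


def generate_planted_pin(
    n_complexes: int,
    size_sampler: TruncatedGeometric | None = None,
    p_within: float = 0.9,
    p_between: float = 0.01,
    seed: int = 0,
) -> tuple[WeightedNetwork, ComplexDataset]:
    """Erdős–Rényi-style modular network with planted complexes.

    Every intra-complex pair is an edge with probability ``p_within`` and
    every inter-complex pair with ``p_between``; all weights are 1.
    Requires ``0 ≤ p_between < p_within ≤ 1`` — otherwise the planted
    structure is undetectable by design.
    """
    if not (0 <= p_between < p_within <= 1):
        raise ValueError(
            "need 0 <= p_between < p_within <= 1; got "
            f"p_within={p_within}, p_between={p_between}"
        )
    rng = stage_seed(seed, "pin")
    sampler = size_sampler or TruncatedGeometric()
    sizes = sampler.sample(rng, size=n_complexes)
    if np.any(sizes < 2):
        raise ValueError("complex sizes must be >= 2")
    n = int(sizes.sum())
    proteins = _protein_ids(n)
    complexes: list[frozenset[str]] = []
    label = np.empty(n, dtype=int)
    off = 0
    for ci, size in enumerate(sizes):
        complexes.append(frozenset(proteins[off : off + size]))
        label[off : off + size] = ci
        off += size

    iu, ju = np.triu_indices(n, k=1)
    same = label[iu] == label[ju]
    prob = np.where(same, p_within, p_between)
    mask = rng.random(len(iu)) < prob
    net = WeightedNetwork()
    for p in proteins:
        net.add_node(p)
    for a, b in zip(iu[mask], ju[mask]):
        net.add_edge(proteins[a], proteins[b])
    return net, ComplexDataset(complexes, provenance="gold")


# ---------------------------------------------------------------------------
# TAP purifications
# ---------------------------------------------------------------------------


def generate_tap_records(
    true_complexes: ComplexDataset,
    bait_fraction: float = 1.0,
    fn_rate: float = 0.0,
    fp_preys: int = 0,
    seed: int = 0,
) -> list[TAPRecord]:
    """Bait-prey records derived from planted complexes.

    Each complex member becomes a bait with probability ``bait_fraction``;
    its preys are its co-members with each dropped at ``fn_rate``, plus
    ``fp_preys`` random non-members (false positives).
    """
    if len(true_complexes) == 0:
        raise ValueError("cannot derive TAP records from an empty complex set")
    for rate in (bait_fraction, fn_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    rng = stage_seed(seed, "tap")
    universe = sorted(true_complexes.proteins)
    records: list[TAPRecord] = []
    for c in true_complexes:
        members = sorted(c)
        non_members = [p for p in universe if p not in c]
        for bait in members:
            if rng.random() >= bait_fraction:
                continue
            preys = [
                p for p in members if p != bait and rng.random() >= fn_rate
            ]
            if fp_preys and non_members:
                extra = rng.choice(
                    non_members, size=min(fp_preys, len(non_members)), replace=False
                )
                preys.extend(sorted(extra))
            records.append(TAPRecord(bait=bait, preys=preys, source_tag="synthetic"))
    return records


# ---------------------------------------------------------------------------
# domain annotations
# ---------------------------------------------------------------------------


def generate_domain_annotations(
    proteins: list[str],
    true_complexes: ComplexDataset,
    n_superfamilies: int = 40,
    planted_homolog_complex_fraction: float = 0.0,
    planted_correlated_pairs: int = 0,
    complexes_per_correlated_pair: int = 3,
    mda_length_sampler: TruncatedGeometric | None = None,
    seed: int = 0,
) -> DomainAnnotation:
    """Domain annotations with planted homologous and correlated structure.

    Background: every protein receives an MDA of background superfamilies
    drawn uniformly at random.  A ``planted_homolog_complex_fraction`` of
    the true complexes receives a protein pair sharing a dedicated
    superfamily (and, for every second such complex, an identical full
    MDA, i.e. protein homologues).  Each of ``planted_correlated_pairs``
    (A, B) superfamily pairs is planted into
    ``complexes_per_correlated_pair`` complexes via two distinct proteins
    per complex.
    """
    rng = stage_seed(seed, "domains")
    sampler = mda_length_sampler or TruncatedGeometric(p=0.5, lo=1, hi=4)
    background = [f"SF{i + 1:04d}" for i in range(n_superfamilies)]
    mda: dict[str, list[str]] = {}
    for p in proteins:
        length = int(sampler.sample(rng)[0])
        mda[p] = list(rng.choice(background, size=length, replace=True))

    n_complexes = len(true_complexes)
    n_homolog = int(round(planted_homolog_complex_fraction * n_complexes))
    if n_homolog > n_complexes:
        raise ValueError("planted homolog fraction exceeds complex count")
    chosen = rng.choice(n_complexes, size=n_homolog, replace=False) if n_homolog else []
    for k, ci in enumerate(sorted(chosen)):
        members = sorted(true_complexes[ci])
        if len(members) < 2:
            raise ValueError("planted complex too small to host a homolog pair")
        p, q = [members[i] for i in rng.choice(len(members), size=2, replace=False)]
        if k % 2 == 0:
            shared = f"HOM{k + 1:04d}"
            mda[p] = mda[p] + [shared]
            mda[q] = mda[q] + [shared]
        else:
            mda[q] = list(mda[p])  # identical architecture: protein homologues

    eligible = [ci for ci in range(n_complexes) if len(true_complexes[ci]) >= 2]
    if planted_correlated_pairs and len(eligible) < complexes_per_correlated_pair:
        raise ValueError("not enough complexes to host planted correlated pairs")
    for k in range(planted_correlated_pairs):
        sfam_a, sfam_b = f"COR{k + 1:04d}A", f"COR{k + 1:04d}B"
        hosts = rng.choice(
            eligible, size=complexes_per_correlated_pair, replace=False
        )
        for ci in sorted(hosts):
            members = sorted(true_complexes[ci])
            p, q = [
                members[i]
                for i in rng.choice(len(members), size=2, replace=False)
            ]
            mda[p] = mda[p] + [sfam_a]
            mda[q] = mda[q] + [sfam_b]
    return DomainAnnotation(mda)


# ---------------------------------------------------------------------------
# GO DAG
# ---------------------------------------------------------------------------


def generate_go(
    proteins: list[str],
    depth: int = 3,
    branching: int = 3,
    n_annotations: int = 0,
    seed: int = 0,
) -> GOResource:
    """Rooted ``is_a`` tree of the given depth/branching with random
    annotations propagated to ancestors and an IC table.

    Annotations are (protein, term) draws, term-uniform over non-root
    terms (depth 1 leaves only a root, giving every similarity score 0).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = stage_seed(seed, "go")
    parents: dict[str, set[str]] = {"GO:0000001": set()}
    frontier = ["GO:0000001"]
    counter = 1
    for _level in range(depth - 1):
        nxt: list[str] = []
        for node in frontier:
            for _ in range(branching):
                counter += 1
                term = f"GO:{counter:07d}"
                parents[term] = {node}
                nxt.append(term)
        frontier = nxt
    non_root = sorted(t for t in parents if parents[t])
    annotations: dict[str, set[str]] = {p: set() for p in proteins}
    if n_annotations and non_root:
        ps = rng.choice(proteins, size=n_annotations, replace=True)
        ts = rng.choice(non_root, size=n_annotations, replace=True)
        for p, t in zip(ps, ts):
            annotations[p].add(t)
    elif n_annotations:
        # root-only DAG: annotate at the root (all similarity scores are 0)
        ps = rng.choice(proteins, size=n_annotations, replace=True)
        for p in ps:
            annotations[p].add("GO:0000001")
    return GOResource(parents=parents, annotations=annotations)


# ---------------------------------------------------------------------------
# orthologue age profiles
# ---------------------------------------------------------------------------


def generate_orthology(
    proteins: list[str],
    age_groups: list[str],
    planted_core: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    core_decay: float = 0.45,
    background_decay: float = 0.45,
) -> OrthologyProfile:
    """Assign age groups: background young-shifted, planted core old-shifted.

    Group probabilities decay geometrically from the youngest group for
    background proteins (P(group i) ∝ decay^i) and from the oldest group
    for the planted core.  ``planted_core`` must be a subset of
    ``proteins``.
    """
    extra = set(planted_core) - set(proteins)
    if extra:
        raise ValueError(f"planted core not a subset of proteins: {sorted(extra)[:5]}")
    rng = stage_seed(seed, "orthology")
    k = len(age_groups)
    if k < 2:
        raise ValueError("need at least two age groups")
    idx = np.arange(k)
    bg = background_decay**idx
    bg /= bg.sum()
    core = core_decay ** idx[::-1]
    core /= core.sum()
    age_group: dict[str, str] = {}
    for p in proteins:
        probs = core if p in planted_core else bg
        age_group[p] = age_groups[int(rng.choice(k, p=probs))]
    return OrthologyProfile(
        presence={p: set() for p in proteins},
        age_group=age_group,
        group_order=list(age_groups),
    )


# ---------------------------------------------------------------------------
# whole worlds
# ---------------------------------------------------------------------------

DEFAULT_AGE_GROUPS = [
    "species-specific",
    "genus",
    "family",
    "kingdom",
    "superkingdom",
    "two-superkingdoms",
    "Universal",
]

DEFAULT_FUNCAT_TERMS = [f"F{i:02d}" for i in range(1, 11)]


@dataclass
class PlantedWorld:
    """Everything one pipeline run consumes, with the planted truth."""

    proteins: list[str]
    true_complexes: ComplexDataset
    pin: WeightedNetwork
    domain_annotation: DomainAnnotation
    go: GOResource
    funcat: dict[str, set[str]]
    orthology: OrthologyProfile
    seed: int
    planted_core: frozenset[str] = frozenset()
    tap_records: list[TAPRecord] = field(default_factory=list)


def generate_world(
    seed: int = 0,
    n_complexes: int = 20,
    size_sampler: TruncatedGeometric | None = None,
    p_within: float = 0.9,
    p_between: float = 0.01,
    planted_homolog_complex_fraction: float = 0.0,
    planted_correlated_pairs: int = 0,
    complexes_per_correlated_pair: int = 3,
    n_superfamilies: int = 40,
    go_depth: int = 4,
    go_branching: int = 3,
    annotations_per_protein: float = 1.5,
    core_fraction: float = 0.0,
    funcat_coherence: float = 0.7,
    funcat_coverage: float = 0.8,
    bait_fraction: float = 1.0,
    fn_rate: float = 0.1,
    fp_preys: int = 1,
) -> PlantedWorld:
    """Generate a complete planted world from a single seed.

    Defaults describe the standard study condition used throughout the
    test-suite: 20 complexes of truncated-geometric size on [2, 30],
    dense-within/sparse-between wiring (0.9 / 0.01), and — when planted
    structure is requested — homologous pairs, correlated superfamily
    pairs and an old-shifted orthologue core drawn as documented in each
    stage generator.
    """
    pin, truth = generate_planted_pin(
        n_complexes,
        size_sampler=size_sampler,
        p_within=p_within,
        p_between=p_between,
        seed=seed,
    )
    proteins = sorted(truth.proteins)
    da = generate_domain_annotations(
        proteins,
        truth,
        n_superfamilies=n_superfamilies,
        planted_homolog_complex_fraction=planted_homolog_complex_fraction,
        planted_correlated_pairs=planted_correlated_pairs,
        complexes_per_correlated_pair=complexes_per_correlated_pair,
        seed=seed,
    )
    go = generate_go(
        proteins,
        depth=go_depth,
        branching=go_branching,
        n_annotations=int(round(annotations_per_protein * len(proteins))),
        seed=seed,
    )
    rng = stage_seed(seed, "funcat")
    terms = DEFAULT_FUNCAT_TERMS
    funcat: dict[str, set[str]] = {}
    for ci, c in enumerate(truth):
        complex_term = terms[ci % len(terms)]
        for p in sorted(c):
            if rng.random() >= funcat_coverage:
                continue
            term = (
                complex_term
                if rng.random() < funcat_coherence
                else terms[int(rng.integers(len(terms)))]
            )
            funcat.setdefault(p, set()).add(term)
    n_core = int(round(core_fraction * len(proteins)))
    core = frozenset(
        np.asarray(proteins)[rng.choice(len(proteins), size=n_core, replace=False)]
    ) if n_core else frozenset()
    orthology = generate_orthology(
        proteins, DEFAULT_AGE_GROUPS, planted_core=core, seed=seed
    )
    tap = generate_tap_records(
        truth,
        bait_fraction=bait_fraction,
        fn_rate=fn_rate,
        fp_preys=fp_preys,
        seed=seed,
    )
    return PlantedWorld(
        proteins=proteins,
        true_complexes=truth,
        pin=pin,
        domain_annotation=da,
        go=go,
        funcat=funcat,
        orthology=orthology,
        seed=seed,
        planted_core=core,
        tap_records=tap,
    )


def write_world(world: PlantedWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write every artefact in the formats the ingest modules read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "complexes": out / "true_complexes.tsv",
        "domains": out / "domains.tsv",
        "obo": out / "go.obo",
        "gaf": out / "annotations.tsv",
        "funcat": out / "funcat.tsv",
        "orthology": out / "orthology.tsv",
        "tap": out / "tap.tsv",
    }
    write_edges_tsv(world.pin, paths["edges"])
    write_complexes_tsv(world.true_complexes, paths["complexes"])
    write_domains_tsv(world.domain_annotation, paths["domains"])
    write_obo(world.go.parents, paths["obo"])
    write_gaf_tsv(world.go.annotations, paths["gaf"])
    write_funcat_tsv(world.funcat, paths["funcat"])
    write_orthology_tsv(world.orthology, paths["orthology"])
    write_tap_tsv(world.tap_records, paths["tap"])
    return paths
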