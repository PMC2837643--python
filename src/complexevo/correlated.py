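"""Correlated pairs of non-homologous domain superfamilies.

A superfamily pair (A, B), A ≠ B, is *correlated* when distinct proteins
p (carrying A) and q (carrying B) co-occur in more complexes than
size-preserving membership shuffles produce.  Candidate pairs are those
observed in at least two complexes of the real dataset; pairs with
empirical p above the cutoff are excluded (a raw cutoff, not FDR — an
optional Benjamini-Hochberg switch is provided).  Witness pairs feed the
interaction and functional-similarity enrichment tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._permutation import MembershipShuffler, empirical_p
from .complexes import ComplexDataset, cocomplex_pairs
from .homology import DomainAnnotation, bh_fdr
from .network import WeightedNetwork
from .ontology import GOResource, protein_goss

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelatedPair",
    "pair_complex_count",
    "find_correlated_pairs",
    "correlated_pair_enrichment",
    "cross_species_overlap",
]


@dataclass
class CorrelatedPair:
    sfam_a: str
    sfam_b: str
    n_complexes: int
    p_value: float
    supporting: list[tuple[int, str, str]]  # (complex index, protein p, protein q)

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.sfam_a, self.sfam_b))


def _complex_has_pair(
    members: frozenset[str], sfam_a: str, sfam_b: str, da: DomainAnnotation
) -> bool:
    a_carriers = members & da.superfamily_index.get(sfam_a, set())
    b_carriers = members & da.superfamily_index.get(sfam_b, set())
    if not a_carriers or not b_carriers:
        return False
    # distinct proteins required: fails only when the single A-carrier is
    # also the single B-carrier
    if len(a_carriers) == 1 and a_carriers == b_carriers:
        return False
    return True


def pair_complex_count(
    sfam_a: str, sfam_b: str, ds: ComplexDataset, da: DomainAnnotation
) -> int:
    """Number of complexes with distinct proteins carrying A and B.

    A complex counts once no matter how many witness pairs it holds.
    """
    if sfam_a == sfam_b:
        raise ValueError("correlated pairs are non-homologous: A must differ from B")
    return sum(1 for c in ds if _complex_has_pair(c, sfam_a, sfam_b, da))


def _witnesses(
    ds: ComplexDataset, sfam_a: str, sfam_b: str, da: DomainAnnotation
) -> list[tuple[int, str, str]]:
    out: list[tuple[int, str, str]] = []
    for ci, c in enumerate(ds):
        for p in sorted(c & da.superfamily_index.get(sfam_a, set())):
            for q in sorted(c & da.superfamily_index.get(sfam_b, set())):
                if p != q:
                    out.append((ci, p, q))
    return out


def find_correlated_pairs(
    ds: ComplexDataset,
    da: DomainAnnotation,
    n_rand: int = 10000,
    p_max: float = 0.01,
    min_complexes: int = 2,
    seed: int = 0,
    strict: bool = False,
    fdr: bool = False,
) -> list[CorrelatedPair]:
    """Screen all observed superfamily pairs for correlated co-occurrence.

    The candidate universe is the set of unordered pairs witnessed in at
    least ``min_complexes`` complexes of the real dataset; each candidate's
    complex count is compared against one shared stream of membership
    shuffles.  ``fdr=True`` replaces the raw ``p_max`` cutoff with
    Benjamini-Hochberg at the same level.
    """
    shuffler = MembershipShuffler.from_dataset(ds)
    pindex = {p: i for i, p in enumerate(shuffler.proteins)}

    # candidate pairs from the observed dataset
    counts: dict[frozenset[str], set[int]] = {}
    for ci, c in enumerate(ds):
        sfams_present: dict[str, set[str]] = {}
        for p in c:
            for s in da.superfamilies_of(p):
                sfams_present.setdefault(s, set()).add(p)
        for s_a, s_b in combinations(sorted(sfams_present), 2):
            if _complex_has_pair(c, s_a, s_b, da):
                counts.setdefault(frozenset((s_a, s_b)), set()).add(ci)
    candidates = sorted(
        (tuple(sorted(k)) for k, v in counts.items() if len(v) >= min_complexes)
    )
    if not candidates:
        return []

    sfams = sorted({s for pair in candidates for s in pair})
    sindex = {s: j for j, s in enumerate(sfams)}
    carrier = np.zeros((len(shuffler.proteins), len(sfams)))
    for s in sfams:
        for p in da.superfamily_index.get(s, set()):
            if p in pindex:
                carrier[pindex[p], sindex[s]] = 1.0
    both = np.zeros((len(shuffler.proteins), len(candidates)))
    for k, (s_a, s_b) in enumerate(candidates):
        both[:, k] = carrier[:, sindex[s_a]] * carrier[:, sindex[s_b]]

    a_idx = np.array([sindex[a] for a, _ in candidates])
    b_idx = np.array([sindex[b] for _, b in candidates])

    def pair_counts(perm: np.ndarray | None) -> np.ndarray:
        sf_counts = shuffler.feature_counts(carrier, perm=perm)
        ab_counts = shuffler.feature_counts(both, perm=perm)
        n_a = sf_counts[:, a_idx]
        n_b = sf_counts[:, b_idx]
        has = (n_a >= 1) & (n_b >= 1) & ~(
            (n_a == 1) & (n_b == 1) & (ab_counts == 1)
        )
        return has.sum(axis=0)

    observed = pair_counts(None)
    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, len(candidates)))
    n_slots = len(shuffler.slots)
    for r in range(n_rand):
        null[r] = pair_counts(rng.permutation(n_slots))

    p_values = [
        empirical_p(observed[k], null[:, k], strict=strict)
        for k in range(len(candidates))
    ]
    if fdr:
        keep = bh_fdr(p_values, p_max)
    else:
        keep = {k for k, p in enumerate(p_values) if p <= p_max}

    out: list[CorrelatedPair] = []
    for k in sorted(keep):
        s_a, s_b = candidates[k]
        out.append(
            CorrelatedPair(
                sfam_a=s_a,
                sfam_b=s_b,
                n_complexes=int(observed[k]),
                p_value=p_values[k],
                supporting=_witnesses(ds, s_a, s_b, da),
            )
        )
    return out


def correlated_pair_enrichment(
    pairs: list[CorrelatedPair],
    ds: ComplexDataset,
    net: WeightedNetwork,
    go: GOResource,
    n_rand: int = 10000,
    seed: int = 0,
    strict: bool = False,
) -> tuple[float, float]:
    """Interaction and functional-similarity enrichment of witness pairs.

    The pooled witness protein pairs are compared against ``n_rand``
    equal-size samples of random co-complex protein pairs, once on the
    fraction that interact and once on the mean GOSS score.  Returns
    (interaction p, GOSS p).
    """
    if not pairs:
        raise ValueError("no correlated pairs to test")
    witness_pairs = sorted(
        {tuple(sorted((p, q))) for cp in pairs for _, p, q in cp.supporting}
    )
    pool = sorted(tuple(sorted(p)) for p in cocomplex_pairs(ds))
    if not pool:
        raise ValueError("dataset has no co-complex pairs to sample")
    k = len(witness_pairs)
    if len(pool) < k:
        raise ValueError(f"only {len(pool)} co-complex pairs available, need {k}")

    is_edge = np.array([net.has_edge(a, b) for a, b in pool], dtype=float)
    goss = np.array([protein_goss(go, a, b) for a, b in pool], dtype=float)
    obs_edge = float(np.mean([net.has_edge(a, b) for a, b in witness_pairs]))
    obs_goss = float(np.mean([protein_goss(go, a, b) for a, b in witness_pairs]))

    rng = np.random.default_rng(seed)
    draws = np.stack(
        [rng.choice(len(pool), size=k, replace=False) for _ in range(n_rand)]
    )
    null_edge = is_edge[draws].mean(axis=1)
    null_goss = goss[draws].mean(axis=1)
    return (
        empirical_p(obs_edge, null_edge, strict=strict),
        empirical_p(obs_goss, null_goss, strict=strict),
    )


def cross_species_overlap(
    pairs_a: list[CorrelatedPair], pairs_b: list[CorrelatedPair]
) -> tuple[set[str], set[frozenset[str]]]:
    """Overlap of two species' correlated-pair lists at the superfamily
    level and at the unordered-pair level."""
    sf_a = {s for cp in pairs_a for s in (cp.sfam_a, cp.sfam_b)}
    sf_b = {s for cp in pairs_b for s in (cp.sfam_a, cp.sfam_b)}
    keys_a = {cp.key for cp in pairs_a}
    keys_b = {cp.key for cp in pairs_b}
    return sf_a & sf_b, keys_a & keys_b
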