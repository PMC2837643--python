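"""Cluster-vs-gold-standard benchmarking: sensitivity, PPV, accuracy.

Predicted clusters are scored against curated complexes through a
contingency table T, where T[i, j] is the number of members of gold
complex i found in cluster j.  Sensitivity is the size-weighted average
over gold complexes of the best-covered fraction; PPV is the
marginal-weighted average over clusters of their purest column fraction;
accuracy is the geometric mean of the two.  A size-preserving membership
shuffle of the clusters provides the random baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import ComplexDataset

__all__ = [
    "ContingencyTable",
    "BenchmarkScores",
    "contingency",
    "sensitivity",
    "ppv",
    "accuracy",
    "benchmark_scores",
    "randomized_baseline",
]


@dataclass
class ContingencyTable:
    """Shared-member counts between gold complexes (rows) and clusters
    (columns).

    Gold complexes of size one are excluded; so are clusters sharing no
    member with any gold complex.  ``tdot`` is the column marginal
    Σ_i T[i, j] by default; with ``literal_tj`` it is instead the number of
    distinct gold-annotated proteins in the cluster (these differ only when
    gold complexes overlap).
    """

    t: np.ndarray  # (n_gold, n_clusters) shared-member counts
    n: np.ndarray  # gold complex sizes N_i
    tdot: np.ndarray  # per-cluster weights T_j

    def __post_init__(self) -> None:
        if self.t.ndim != 2:
            raise ValueError("contingency table must be 2-d")


def contingency(
    predicted: ComplexDataset, gold: ComplexDataset, literal_tj: bool = False
) -> ContingencyTable:
    """Build the gold × cluster shared-member table."""
    gold_sets = [c for c in gold.complexes if len(c) >= 2]
    if not gold_sets:
        raise ValueError("gold standard has no complexes with >1 protein")
    gold_proteins = set().union(*gold_sets)
    clusters = [c for c in predicted.complexes if c & gold_proteins]
    t = np.array(
        [[len(gi & cj) for cj in clusters] for gi in gold_sets], dtype=float
    )
    if t.size == 0:
        t = t.reshape(len(gold_sets), 0)
    n = np.array([len(gi) for gi in gold_sets], dtype=float)
    if literal_tj:
        tdot = np.array([len(cj & gold_proteins) for cj in clusters], dtype=float)
    else:
        tdot = t.sum(axis=0)
    return ContingencyTable(t=t, n=n, tdot=tdot)


def sensitivity(ct: ContingencyTable) -> float:
    """Sn = Σ_i N_i · max_j(T[i,j]/N_i) / Σ_i N_i."""
    if ct.t.shape[1] == 0:
        return 0.0
    best = ct.t.max(axis=1)  # N_i * max_j T_ij / N_i = max_j T_ij
    return float(best.sum() / ct.n.sum())


def ppv(ct: ContingencyTable) -> float:
    """PPV = Σ_j T_j · max_i(T[i,j]/T_j) / Σ_j T_j."""
    keep = ct.tdot > 0
    if not keep.any():
        raise ValueError("no cluster shares a member with the gold standard")
    t = ct.t[:, keep]
    tdot = ct.tdot[keep]
    # T_j * max_i T_ij / T_j = max_i T_ij under the marginal definition;
    # keep the explicit ratio so the literal T_j variant also works.
    best_frac = t.max(axis=0) / tdot
    return float((tdot * best_frac).sum() / tdot.sum())


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric mean of sensitivity and PPV."""
    if not (0 <= sn <= 1 and 0 <= ppv_value <= 1):
        raise ValueError("sensitivity and PPV must lie in [0, 1]")
    return float(np.sqrt(sn * ppv_value))


@dataclass
class BenchmarkScores:
    sensitivity: float
    ppv: float
    accuracy: float


def benchmark_scores(
    predicted: ComplexDataset, gold: ComplexDataset, literal_tj: bool = False
) -> BenchmarkScores:
    """Sensitivity, PPV and accuracy of a clustering against a gold set."""
    ct = contingency(predicted, gold, literal_tj=literal_tj)
    sn = sensitivity(ct)
    pv = ppv(ct)
    return BenchmarkScores(sensitivity=sn, ppv=pv, accuracy=accuracy(sn, pv))


def randomized_baseline(
    predicted: ComplexDataset,
    gold: ComplexDataset,
    n: int = 10000,
    seed: int = 0,
    literal_tj: bool = False,
) -> tuple[float, float]:
    """Mean and population SD of accuracy over membership-shuffled clusters.

    Each replicate permutes the pooled cluster members across the fixed
    cluster-size skeleton and re-benchmarks against the (fixed) gold set.
    """
    if n < 1:
        raise ValueError("need at least one randomisation")
    rng = np.random.default_rng(seed)
    flat, offsets = predicted.membership_slots()
    offsets_arr = np.array(offsets, dtype=np.intp)

    gold_sets = [c for c in gold.complexes if len(c) >= 2]
    if not gold_sets:
        raise ValueError("gold standard has no complexes with >1 protein")
    gold_list = sorted(set().union(*gold_sets))
    gold_index = {p: i for i, p in enumerate(gold_list)}
    # per-slot one-hot gold membership (a protein may sit in several gold
    # complexes when the gold standard overlaps)
    onehot = np.zeros((len(flat), len(gold_sets)), dtype=float)
    in_gold = np.zeros(len(flat), dtype=float)
    for s, p in enumerate(flat):
        for gi, gset in enumerate(gold_sets):
            if p in gset:
                onehot[s, gi] = 1.0
        if p in gold_index:
            in_gold[s] = 1.0
    n_i = np.array([len(g) for g in gold_sets], dtype=float)
    n_slots = len(flat)

    accs = np.empty(n)
    for r in range(n):
        perm = rng.permutation(n_slots)
        t = np.add.reduceat(onehot[perm], offsets_arr, axis=0).T  # gold x cluster
        if literal_tj:
            tdot = np.add.reduceat(in_gold[perm], offsets_arr)
        else:
            tdot = t.sum(axis=0)
        keep = tdot > 0
        sn = float(t.max(axis=1).sum() / n_i.sum())
        if keep.any():
            # T_j * max_i(T_ij/T_j) = max_i T_ij for either T_j definition
            pv = float(t[:, keep].max(axis=0).sum() / tdot[keep].sum())
            accs[r] = np.sqrt(sn * pv)
        else:
            accs[r] = 0.0
    return float(accs.mean()), float(accs.std())
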