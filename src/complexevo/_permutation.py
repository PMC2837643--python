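"""Shared machinery for membership-shuffle permutation tests.

Every evolutionary statistic in the package compares an observed count
against the same null model: complex members shuffled over the fixed
complex-size skeleton.  To make 10^3-10^4 shuffles cheap, proteins are
mapped to integer rows of a feature matrix and per-complex feature counts
are computed with a single ``np.add.reduceat`` per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import ComplexDataset

__all__ = ["MembershipShuffler", "empirical_p"]


def empirical_p(
    observed: float, null_values: np.ndarray, strict: bool = False
) -> float:
    """Empirical p-value of ``observed`` against permutation ``null_values``.

    Default estimator is (1 + #{null >= observed}) / (1 + n): the add-one
    form never returns zero and counts ties against the hypothesis, which
    is conservative.  ``strict=True`` gives the literal
    #{null > observed} / n variant (proportion of trials in which the
    observed count was exceeded).
    """
    null_values = np.asarray(null_values)
    n = len(null_values)
    if n == 0:
        raise ValueError("empirical p-value needs at least one permutation")
    if strict:
        return float(np.sum(null_values > observed)) / n
    return float(1 + np.sum(null_values >= observed)) / (1 + n)


@dataclass
class MembershipShuffler:
    """Vectorised view of a complex dataset for repeated shuffling.

    Attributes
    ----------
    proteins
        Sorted list of member proteins; row order of feature matrices.
    slots
        Integer protein index per membership slot (flattened complexes).
    offsets
        Start offset of each complex in ``slots`` (for ``reduceat``).
    sizes
        Complex sizes, aligned with ``offsets``.
    """

    proteins: list[str]
    slots: np.ndarray
    offsets: np.ndarray
    sizes: np.ndarray

    @classmethod
    def from_dataset(cls, ds: ComplexDataset) -> "MembershipShuffler":
        flat, offsets = ds.membership_slots()
        proteins = sorted(set(flat))
        index = {p: i for i, p in enumerate(proteins)}
        return cls(
            proteins=proteins,
            slots=np.array([index[p] for p in flat], dtype=np.intp),
            offsets=np.array(offsets, dtype=np.intp),
            sizes=np.diff(
                np.append(np.array(offsets, dtype=np.intp), len(flat))
            ),
        )

    @property
    def n_complexes(self) -> int:
        return len(self.offsets)

    def protein_index(self, protein: str) -> int | None:
        import bisect

        i = bisect.bisect_left(self.proteins, protein)
        if i < len(self.proteins) and self.proteins[i] == protein:
            return i
        return None

    def feature_counts(
        self, features: np.ndarray, perm: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-complex column sums of ``features`` (proteins x k).

        ``perm`` permutes the membership slots (a shuffled dataset); omit it
        for the observed assignment.  Returns an (n_complexes x k) array.
        """
        slot_rows = self.slots if perm is None else self.slots[perm]
        return np.add.reduceat(features[slot_rows], self.offsets, axis=0)

    def null_feature_counts(
        self, features: np.ndarray, n_rand: int, rng: np.random.Generator
    ):
        """Yield per-complex count matrices for ``n_rand`` shuffles."""
        n = len(self.slots)
        for _ in range(n_rand):
            yield self.feature_counts(features, perm=rng.permutation(n))
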