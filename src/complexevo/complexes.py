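"""Protein-complex datasets and the size-preserving membership shuffle.

A :class:`ComplexDataset` is an ordered list of protein sets with a
provenance tag.  Predicted datasets (MCL clusters) are disjoint by
construction; curated gold standards may overlap.  The membership shuffle
is the shared null model for every permutation statistic in the package:
proteins are permuted over a fixed complex-size skeleton, so the complex
size distribution and the protein multiset are both preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

__all__ = ["ComplexDataset", "shuffle_complexes"]

Provenance = Literal["predicted", "gold", "randomised"]


@dataclass
class ComplexDataset:
    complexes: list[frozenset[str]]
    provenance: Provenance = "predicted"
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if self.provenance in ("predicted", "randomised"):
            seen: set[str] = set()
            for c in self.complexes:
                if seen & c:
                    raise ValueError(
                        f"{self.provenance} complexes must be disjoint; "
                        f"duplicated member(s): {sorted(seen & c)[:5]}"
                    )
                seen |= c

    @classmethod
    def from_lists(
        cls, members: Iterable[Iterable[str]], provenance: Provenance = "predicted"
    ) -> "ComplexDataset":
        return cls([frozenset(m) for m in members], provenance=provenance)

    # -- inspection -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> frozenset[str]:
        return self.complexes[i]

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]

    def filter_min_size(self, min_size: int = 2) -> "ComplexDataset":
        """Drop complexes below ``min_size`` members, preserving order."""
        return ComplexDataset(
            [c for c in self.complexes if len(c) >= min_size],
            provenance=self.provenance,
        )

    def membership_slots(self) -> tuple[list[str], list[int]]:
        """Flattened member list plus per-complex offsets (skeleton view).

        Members within each complex are emitted in sorted order so the
        flattening is deterministic.
        """
        flat: list[str] = []
        offsets: list[int] = []
        for c in self.complexes:
            offsets.append(len(flat))
            flat.extend(sorted(c))
        return flat, offsets


def shuffle_complexes(
    ds: ComplexDataset, seed: int | np.random.Generator
) -> ComplexDataset:
    """Randomise complex membership while retaining the size skeleton.

    Members are shuffled between complexes: a single random permutation of
    the pooled membership multiset is re-sliced into the original complex
    sizes.  Both the size multiset and the protein multiset are invariant.
    """
    rng = np.random.default_rng(seed)
    flat, offsets = ds.membership_slots()
    perm = rng.permutation(len(flat))
    shuffled = [flat[i] for i in perm]
    out: list[frozenset[str]] = []
    sizes = ds.sizes
    for off, size in zip(offsets, sizes):
        out.append(frozenset(shuffled[off : off + size]))
    return ComplexDataset(out, provenance="randomised")


def cocomplex_pairs(ds: ComplexDataset) -> set[frozenset[str]]:
    """All unordered protein pairs sharing at least one complex."""
    pairs: set[frozenset[str]] = set()
    for c in ds:
        members: Sequence[str] = sorted(c)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(frozenset((members[i], members[j])))
    return pairs
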