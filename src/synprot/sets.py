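"""Set logic over altered-protein lists.

Derives per-comparison UP/DOWN/altered accession sets from a classified
ratio table, group-specific subsets (altered in a target comparison and
in none of a stated contrast group), Venn region counts, and top-k
rankings by normalized ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .transform import DOWN, UP

__all__ = [
    "AlteredSets",
    "SpecificityResult",
    "altered_sets",
    "specific_set",
    "venn_counts",
    "top_k",
]


@dataclass(frozen=True)
class AlteredSets:
    """Per-comparison UP and DOWN accession sets."""

    up: Mapping[str, frozenset]
    down: Mapping[str, frozenset]

    @property
    def comparisons(self) -> tuple[str, ...]:
        return tuple(self.up)

    def altered(self, comparison: str) -> frozenset:
        """UP union DOWN for one comparison."""
        if comparison not in self.up:
            raise KeyError(f"unknown comparison {comparison!r}")
        return self.up[comparison] | self.down[comparison]

    def counts(self) -> pd.DataFrame:
        """Summary table: n_up / n_down / n_altered per comparison."""
        return pd.DataFrame(
            {
                "comparison": list(self.up),
                "n_up": [len(self.up[c]) for c in self.up],
                "n_down": [len(self.down[c]) for c in self.up],
                "n_altered": [len(self.altered(c)) for c in self.up],
            }
        )


@dataclass(frozen=True)
class SpecificityResult:
    """Partition of a target comparison's altered set.

    ``specific`` holds proteins altered only in the target comparison;
    ``shared`` holds those also altered in at least one contrast
    comparison.  Together they partition the target's altered set.
    """

    target: str
    specific: frozenset
    shared: frozenset

    def __post_init__(self) -> None:
        assert not (self.specific & self.shared)


def altered_sets(ratios: pd.DataFrame) -> AlteredSets:
    """Extract UP/DOWN accession sets per comparison from a ratio table."""
    up: dict[str, frozenset] = {}
    down: dict[str, frozenset] = {}
    for comp, grp in ratios.groupby("comparison", sort=False):
        up[comp] = frozenset(grp.loc[grp["change_class"] == UP, "accession"])
        down[comp] = frozenset(grp.loc[grp["change_class"] == DOWN, "accession"])
    return AlteredSets(up=up, down=down)


def specific_set(
    target: str, others: Sequence[str], sets: AlteredSets
) -> SpecificityResult:
    """Proteins altered in ``target`` and in none of ``others``.

    Raises
    ------
    ConfigError
        If the target appears among the contrast comparisons.
    KeyError
        For unknown comparison names.
    """
    if target in others:
        raise ConfigError(f"target {target!r} listed among contrast comparisons")
    target_altered = sets.altered(target)
    other_union: frozenset = frozenset()
    for name in others:
        other_union |= sets.altered(name)
    specific = target_altered - other_union
    return SpecificityResult(
        target=target, specific=specific, shared=target_altered & other_union
    )


def venn_counts(named_sets: Mapping[str, Iterable]) -> dict[tuple[bool, ...], int]:
    """Counts of every non-empty Venn membership region of 2-4 sets.

    Keys are membership tuples aligned with the input order: for sets
    (A, B) the key ``(True, False)`` counts elements in A only.  Counts
    over all regions sum to the size of the union.
    """
    if not 2 <= len(named_sets) <= 4:
        raise ConfigError(f"venn_counts supports 2-4 sets, got {len(named_sets)}")
    sets = [frozenset(s) for s in named_sets.values()]
    counts: dict[tuple[bool, ...], int] = {}
    for mask in product([True, False], repeat=len(sets)):
        if not any(mask):
            continue
        inc = [s for s, m in zip(sets, mask) if m]
        exc = [s for s, m in zip(sets, mask) if not m]
        members = frozenset.intersection(*inc)
        for s in exc:
            members -= s
        counts[mask] = len(members)
    return counts


def top_k(
    ratios: pd.DataFrame, comparison: str, k: int = 10, direction: str = UP
) -> list[str]:
    """Top-k accessions by normalized ratio, descending for UP and
    ascending for DOWN; ties broken by accession lexicographic order.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if direction not in (UP, DOWN):
        raise ConfigError(f"direction must be {UP!r} or {DOWN!r}")
    grp = ratios.loc[ratios["comparison"] == comparison]
    if grp.empty:
        raise KeyError(f"unknown comparison {comparison!r}")
    ascending = direction == DOWN
    ranked = grp.sort_values(
        ["norm_ratio", "accession"], ascending=[ascending, True], kind="mergesort"
    )
    return ranked["accession"].head(k).tolist()
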