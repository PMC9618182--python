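"""Comparison designs for pooled ratiometric experiments.

A pooled TMT experiment quantifies one master sample ("pool") per
experimental group; every contrast of interest is a named case-pool /
control-pool pair tagged with a brain region and a stratification label
(disease, cognitive status, repeat-expansion status).  The ten-pool,
two-region layout of the study this package models is available as
:func:`default_study_design`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError

__all__ = ["Comparison", "ComparisonDesign", "default_study_design"]


@dataclass(frozen=True)
class Comparison:
    """One case-vs-control contrast between two pools.

    Parameters
    ----------
    name
        Unique identifier for the contrast (e.g. ``"ALS_BA4"``).
    case_pool, control_pool
        Column identifiers of the numerator and denominator pools.
    region
        Brain region label (e.g. ``"BA4"`` primary motor cortex,
        ``"BA9"`` dorsolateral prefrontal cortex).
    stratum
        Stratification label (e.g. ``"ALS"``, ``"ALSci"``, ``"C9pos"``).
    """

    name: str
    case_pool: str
    control_pool: str
    region: str = ""
    stratum: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("comparison name must be non-empty")
        if self.case_pool == self.control_pool:
            raise ConfigError(
                f"comparison {self.name!r}: case and control pool are identical "
                f"({self.case_pool!r})"
            )


@dataclass(frozen=True)
class ComparisonDesign:
    """An ordered collection of uniquely named comparisons."""

    comparisons: tuple[Comparison, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(self.comparisons))
        if not self.comparisons:
            raise ConfigError("design must contain at least one comparison")
        names = [c.name for c in self.comparisons]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate comparison names: {sorted(dupes)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.comparisons)

    @property
    def pool_ids(self) -> tuple[str, ...]:
        """All pool ids referenced by the design, in first-use order."""
        seen: dict[str, None] = {}
        for c in self.comparisons:
            seen.setdefault(c.control_pool)
            seen.setdefault(c.case_pool)
        return tuple(seen)

    def __iter__(self):
        return iter(self.comparisons)

    def __len__(self) -> int:
        return len(self.comparisons)

    def __getitem__(self, name: str) -> Comparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "ComparisonDesign":
        """Build a design from dicts with keys matching :class:`Comparison`."""
        comps = []
        for rec in records:
            try:
                comps.append(
                    Comparison(
                        name=rec["name"],
                        case_pool=rec["case_pool"],
                        control_pool=rec["control_pool"],
                        region=rec.get("region", ""),
                        stratum=rec.get("stratum", ""),
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"comparison record missing key {exc}") from exc
        return cls(tuple(comps))

    def to_records(self) -> list[dict[str, str]]:
        return [
            {
                "name": c.name,
                "case_pool": c.case_pool,
                "control_pool": c.control_pool,
                "region": c.region,
                "stratum": c.stratum,
            }
            for c in self.comparisons
        ]


def default_study_design() -> ComparisonDesign:
    """The ten-pool cohort layout: two regions, strata by disease,
    cognitive status and C9ORF72 repeat-expansion status.

    Pools 1-10 follow the published pooling scheme: per region one control
    and one all-ALS pool, per region ALSnoci/ALSci pools, and (BA9 only)
    C9ORF72-RE negative/positive pools.  Every case pool is contrasted
    against its region's control pool.
    """
    return ComparisonDesign(
        (
            Comparison("ALS_BA9", "pool_ALS_BA9", "pool_Control_BA9", "BA9", "ALS"),
            Comparison("ALS_BA4", "pool_ALS_BA4", "pool_Control_BA4", "BA4", "ALS"),
            Comparison("ALSnoci_BA9", "pool_ALSnoci_BA9", "pool_Control_BA9", "BA9", "ALSnoci"),
            Comparison("ALSnoci_BA4", "pool_ALSnoci_BA4", "pool_Control_BA4", "BA4", "ALSnoci"),
            Comparison("ALSci_BA9", "pool_ALSci_BA9", "pool_Control_BA9", "BA9", "ALSci"),
            Comparison("ALSci_BA4", "pool_ALSci_BA4", "pool_Control_BA4", "BA4", "ALSci"),
            Comparison("C9neg_BA9", "pool_C9neg_BA9", "pool_Control_BA9", "BA9", "C9neg"),
            Comparison("C9pos_BA9", "pool_C9pos_BA9", "pool_Control_BA9", "BA9", "C9pos"),
        )
    )
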