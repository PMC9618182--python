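"""Overlap with reference proteomes and subsynaptic compartment maps.

Synaptoneurosome datasets are routinely benchmarked against published
brain/synapse proteome lists (overlap fraction of the dataset found in
the reference) and altered proteins are assigned to pre-/postsynaptic
compartments using curated synapse databases.  Identifier conventions
differ between resources, so matching is case-insensitive for gene
symbols and isoform suffixes ("P12345-2") are stripped from accessions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ConfigError

__all__ = [
    "ReferenceList",
    "CompartmentMap",
    "COMPARTMENTS",
    "normalize_id",
    "overlap_fraction",
    "compartment_distribution",
]

COMPARTMENTS = ("presynaptic", "postsynaptic", "both", "unknown")


def normalize_id(identifier: str, id_type: str = "accession") -> str:
    """Canonicalize an identifier for matching across resources.

    Accessions are upper-cased with any isoform suffix removed; symbols
    are upper-cased and stripped.
    """
    ident = identifier.strip().upper()
    if id_type == "accession" and "-" in ident:
        ident = ident.split("-", 1)[0]
    return ident


@dataclass(frozen=True)
class ReferenceList:
    """A named reference identifier set (accession- or symbol-keyed)."""

    name: str
    ids: frozenset
    id_type: str = "accession"

    def __post_init__(self) -> None:
        if self.id_type not in ("accession", "symbol"):
            raise ConfigError(f"id_type must be accession or symbol, got {self.id_type!r}")
        normalized = frozenset(normalize_id(i, self.id_type) for i in self.ids)
        if not normalized:
            raise ConfigError(f"reference list {self.name!r} is empty")
        object.__setattr__(self, "ids", normalized)


@dataclass(frozen=True)
class CompartmentMap:
    """Identifier -> coarse synaptic compartment assignment.

    Each identifier maps to exactly one of ``presynaptic``,
    ``postsynaptic`` or ``both``; identifiers absent from the map are
    reported as ``unknown``.  An optional fine-grained term (e.g.
    "postsynaptic density", "synaptic vesicle") may accompany each id.
    """

    mapping: Mapping[str, str]
    id_type: str = "accession"
    fine_terms: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for ident, comp in self.mapping.items():
            comp = comp.strip().lower()
            if comp not in ("presynaptic", "postsynaptic", "both"):
                raise ConfigError(
                    f"compartment for {ident!r} must be presynaptic/postsynaptic/both, "
                    f"got {comp!r}"
                )
            clean[normalize_id(ident, self.id_type)] = comp
        object.__setattr__(self, "mapping", clean)

    def lookup(self, identifier: str) -> str:
        return self.mapping.get(normalize_id(identifier, self.id_type), "unknown")


def overlap_fraction(
    dataset_ids: Iterable, reference: ReferenceList
) -> tuple[int, float]:
    """Count and fraction of the dataset found in the reference list.

    The dataset size is the denominator (the directionality used when
    reporting "X% of our dataset matched published data").
    """
    ids = {normalize_id(i, reference.id_type) for i in dataset_ids}
    if not ids:
        raise ConfigError("dataset id list is empty")
    hits = len(ids & reference.ids)
    return hits, hits / len(ids)


def compartment_distribution(
    ids: Iterable, compartment_map: CompartmentMap
) -> dict[str, dict[str, float]]:
    """Per-compartment counts and fractions for a protein list.

    Unmapped identifiers fall into ``unknown``; counts always sum to the
    number of input identifiers.  An empty input yields all zeros.
    """
    id_list = list(ids)
    tally = Counter(compartment_map.lookup(i) for i in id_list)
    n = len(id_list)
    return {
        comp: {
            "count": tally.get(comp, 0),
            "fraction": (tally.get(comp, 0) / n) if n else 0.0,
        }
        for comp in COMPARTMENTS
    }
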