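"""Model/results interface for the pooled ratiometric analysis.

:class:`SynapticProteomeModel` is constructed from a protein
quantification table and a comparison design, holding the analysis
parameters (peptide filter, fold-change thresholds).  ``fit()`` runs the
clean-up filters, the per-comparison ratiometric normalization and the
+/-20% classification, and returns a :class:`SynapticProteomeResults`
carrying the analysis-ready table, the tidy ratio table, the altered
sets and the derived set operations, with a ``summary()`` table in the
style of statistical modelling packages.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .design import ComparisonDesign
from .errors import ConfigError
from .filters import FilterReport, filter_analysis_ready
from .io import read_protein_table, validate_protein_table
from .sets import AlteredSets, SpecificityResult, altered_sets, specific_set, top_k
from .transform import hierarchical_order, ratiometric_normalize, zscore_rows

__all__ = ["SynapticProteomeModel", "SynapticProteomeResults"]


class SynapticProteomeModel:
    """Pooled-cohort differential-abundance model.

    Parameters
    ----------
    table
        Protein quantification table (accession index, ``symbol``,
        ``unique_peptides`` and one intensity column per pool); validated
        on construction.
    design
        Case/control comparisons over the pools.
    min_unique_peptides
        Identification stringency for the analysis-ready filter.
    up_threshold, down_threshold
        Normalized-ratio thresholds for the UP/DOWN calls (inclusive).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        design: ComparisonDesign,
        min_unique_peptides: int = 2,
        up_threshold: float = 1.2,
        down_threshold: float = 0.8,
    ) -> None:
        if min_unique_peptides < 0:
            raise ConfigError("min_unique_peptides must be >= 0")
        if not 0 < down_threshold < 1 <= up_threshold:
            raise ConfigError(
                "thresholds must satisfy 0 < down < 1 <= up, got "
                f"{down_threshold}/{up_threshold}"
            )
        self.design = design
        self.table = validate_protein_table(table, design.pool_ids)
        self.min_unique_peptides = min_unique_peptides
        self.up_threshold = up_threshold
        self.down_threshold = down_threshold

    @classmethod
    def from_tsv(
        cls,
        path: str,
        design: ComparisonDesign,
        column_map: dict[str, str] | None = None,
        **kwargs,
    ) -> "SynapticProteomeModel":
        """Build a model straight from a TSV/CSV quantification export."""
        table = read_protein_table(path, design.pool_ids, column_map=column_map)
        return cls(table, design, **kwargs)

    def fit(self) -> "SynapticProteomeResults":
        """Run filtering, normalization and classification."""
        retained, report = filter_analysis_ready(
            self.table, self.design.pool_ids, self.min_unique_peptides
        )
        ratios = ratiometric_normalize(
            retained, self.design, self.up_threshold, self.down_threshold
        )
        return SynapticProteomeResults(self, retained, report, ratios)


class SynapticProteomeResults:
    """Fitted results: analysis-ready table, ratios and altered sets."""

    def __init__(
        self,
        model: SynapticProteomeModel,
        analysis_ready: pd.DataFrame,
        filter_report: FilterReport,
        ratios: pd.DataFrame,
    ) -> None:
        self.model = model
        self.analysis_ready = analysis_ready
        self.filter_report = filter_report
        self.ratios = ratios
        self._sets: AlteredSets | None = None

    @property
    def sets(self) -> AlteredSets:
        """Per-comparison UP/DOWN accession sets (lazily derived)."""
        if self._sets is None:
            self._sets = altered_sets(self.ratios)
        return self._sets

    def specific_set(self, target: str, others: Sequence[str]) -> SpecificityResult:
        """Proteins altered in ``target`` but in none of ``others``."""
        return specific_set(target, others, self.sets)

    def top_k(self, comparison: str, k: int = 10, direction: str = "UP") -> list[str]:
        """Top-k proteins by normalized ratio in one comparison."""
        return top_k(self.ratios, comparison, k=k, direction=direction)

    def log2_matrix(self) -> pd.DataFrame:
        """Proteins x comparisons matrix of log2 normalized ratios."""
        return self.ratios.pivot(
            index="accession", columns="comparison", values="log2_ratio"
        )[list(self.model.design.names)]

    def zscores(self) -> tuple[pd.DataFrame, pd.Series]:
        """Row z-scores of the log2 ratio matrix (heatmap input)."""
        return zscore_rows(self.log2_matrix())

    def heatmap_order(self, method: str = "complete") -> tuple[list, np.ndarray]:
        """Hierarchical (Euclidean) leaf order of z-scored proteins."""
        z, _ = self.zscores()
        return hierarchical_order(z, method=method)

    def summary(self) -> pd.DataFrame:
        """Per-comparison summary: UP/DOWN/altered counts and the median
        normalized ratio (1 by construction)."""
        counts = self.sets.counts().set_index("comparison")
        medians = self.ratios.groupby("comparison", sort=False)["norm_ratio"].median()
        counts["median_norm_ratio"] = medians
        counts.attrs["filter_report"] = self.filter_report.to_dict()
        return counts.loc[list(self.model.design.names)].reset_index()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SynapticProteomeResults: {self.filter_report.n_retained} proteins, "
            f"{len(self.model.design)} comparisons>"
        )
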