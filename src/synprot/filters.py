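"""Clean-up filters producing the analysis-ready protein table.

Two filters are applied, in either order (the result is identical):

1. identification stringency — keep proteins assigned >= 2 unique
   peptides (configurable);
2. complete detection — keep proteins quantified in every experimental
   pool (any missing intensity excludes the protein).

A protein failing both filters is counted in both failure tallies; the
retained count reconciles against the union of the failing sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["FilterReport", "filter_analysis_ready"]


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for the analysis-ready filter.

    ``n_retained == n_input - |union of failing sets|``; because a row can
    fail both criteria, ``n_fail_peptides + n_fail_missing`` may exceed
    the number of rows removed.
    """

    n_input: int
    n_fail_peptides: int
    n_fail_missing: int
    n_retained: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_fail_peptides": self.n_fail_peptides,
            "n_fail_missing": self.n_fail_missing,
            "n_retained": self.n_retained,
        }


def filter_analysis_ready(
    table: pd.DataFrame,
    pool_ids: Sequence[str],
    min_unique_peptides: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the peptide-count and complete-detection filters.

    Parameters
    ----------
    table
        Validated quantification table (see :mod:`synprot.io`).
    pool_ids
        Pool columns over which complete detection is required.
    min_unique_peptides
        Minimum unique-peptide count to retain a protein (default 2).

    Returns
    -------
    (retained_table, report)
        The retained rows (original order preserved) and a
        :class:`FilterReport`.
    """
    fail_pept = table["unique_peptides"] < min_unique_peptides
    fail_miss = table[list(pool_ids)].isna().any(axis=1)
    keep = ~(fail_pept | fail_miss)
    report = FilterReport(
        n_input=len(table),
        n_fail_peptides=int(fail_pept.sum()),
        n_fail_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
    )
    return table.loc[keep].copy(), report
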