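"""Prevalence filtering, normalization, sparsity accounting, taxon collapse.

Prevalence of a feature is the fraction of samples in which it is detected
(value strictly greater than zero).  Following the convention of keeping
features "shared by more than" a fraction of samples, the filter boundary is
strict by default: a feature present in exactly 20% of samples is removed at
a 0.2 threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import UNCLASSIFIED, FeatureTable, TaxonomyMap

logger = logging.getLogger("guildflow")

__all__ = [
    "FilterReport",
    "prevalence_filter",
    "to_relative",
    "sparsity",
    "collapse_taxa",
]


@dataclass
class FilterReport:
    """Bookkeeping for a filtering/collapsing step."""

    n_features_in: int
    n_features_out: int
    min_prevalence: float | None
    retained_fraction_of_signal: float

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "min_prevalence": self.min_prevalence,
            "retained_fraction_of_signal": self.retained_fraction_of_signal,
        }
        return pd.DataFrame({"value": rows})


def prevalence_filter(
    ft: FeatureTable, min_prevalence: float = 0.2, strict: bool = True
) -> tuple[FeatureTable, FilterReport]:
    """Keep features present in more than ``min_prevalence`` of the samples.

    With ``strict=True`` (default) the inequality is strict: prevalence must
    exceed the threshold.  Returns the filtered table and a report with the
    fraction of total abundance retained.
    """
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    values = ft.values
    prevalence = (values > 0).mean(axis=1)
    keep = prevalence > min_prevalence if strict else prevalence >= min_prevalence
    if not keep.any():
        raise ValueError(
            f"prevalence filter at {min_prevalence} removed every feature; "
            "lower the threshold"
        )
    total = values.sum()
    retained = values[keep].sum() / total if total > 0 else 1.0
    out = FeatureTable(ft.data.loc[keep], unit=ft.unit)
    report = FilterReport(
        n_features_in=ft.n_features,
        n_features_out=out.n_features,
        min_prevalence=min_prevalence,
        retained_fraction_of_signal=float(retained),
    )
    return out, report


def to_relative(ft: FeatureTable) -> FeatureTable:
    """Divide each sample column by its sum (counts -> relative)."""
    if ft.unit == "relative":
        raise ValueError("table is already relative; refusing to renormalize")
    values = ft.values
    sums = values.sum(axis=0)
    zero = sums <= 0
    if zero.any():
        sid = ft.sample_ids[int(np.argmax(zero))]
        raise ValueError(f"sample {sid!r} has zero total abundance")
    return FeatureTable(ft.data / sums, unit="relative")


def sparsity(table) -> float:
    """Fraction of zero cells in an abundance matrix."""
    if isinstance(table, FeatureTable):
        values = table.values
    else:
        values = np.asarray(pd.DataFrame(table), dtype=float)
    if values.size == 0:
        raise ValueError("empty table has no sparsity")
    return float((values == 0).sum() / values.size)


def collapse_taxa(
    ft: FeatureTable,
    tax: TaxonomyMap,
    rank: str = "genus",
    drop_unclassified: bool = True,
) -> tuple[FeatureTable, FilterReport]:
    """Sum features sharing the same taxon label at ``rank``.

    Features unclassified at ``rank`` (including features absent from the
    taxonomy) are dropped when ``drop_unclassified`` is set; the report
    records the fraction of total abundance retained.  Per-sample mass is
    conserved exactly for every retained taxon.
    """
    labels = []
    for fid in ft.feature_ids:
        if fid not in tax:
            logger.warning("feature %r missing from taxonomy; treated as unclassified", fid)
        labels.append(tax.rank_of(fid, rank))
    labels = pd.Series(labels, index=ft.data.index, name=rank)
    classified = labels != UNCLASSIFIED
    if not classified.any():
        raise ValueError(f"no feature is classified at rank {rank!r}")

    data = ft.data
    if drop_unclassified:
        data = data.loc[classified]
        labels = labels.loc[classified]
    else:
        labels = labels.copy()
    collapsed = data.groupby(labels, sort=False).sum()
    collapsed.index = collapsed.index.astype(str)
    total = ft.values.sum()
    retained = data.to_numpy(dtype=float).sum() / total if total > 0 else 1.0
    unit = ft.unit
    if unit == "relative" and retained < 1.0 - 1e-9:
        # mass conservation takes priority over column closure: keep the
        # summed proportions exact and drop the "relative" tag
        logger.warning(
            "collapse dropped %.1f%% of abundance from a relative table; "
            "output columns no longer sum to 1",
            100 * (1 - retained),
        )
        unit = "counts"
    out = FeatureTable(collapsed, unit=unit)
    report = FilterReport(
        n_features_in=ft.n_features,
        n_features_out=out.n_features,
        min_prevalence=None,
        retained_fraction_of_signal=float(retained),
    )
    return out, report
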