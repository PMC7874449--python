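"""Core data containers shared across the pipeline.

The unit of analysis is a *feature*: a draft genome in shotgun metagenomics,
or an OTU/ASV in 16S rRNA gene data.  A :class:`FeatureTable` holds the
feature-by-sample abundance matrix; :class:`TaxonomyMap` holds ranked
lineages; sample metadata (host phenotypes) travels as a plain
:class:`pandas.DataFrame` indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "FeatureTable",
    "TaxonomyMap",
    "validate_metadata",
]

#: Canonical lineage ranks, highest to lowest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Sentinel for a rank with no annotation.
UNCLASSIFIED = "unclassified"

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Nonnegative feature-by-sample abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features, columns are samples.
    unit : {"counts", "relative"}
        ``relative`` requires every sample column to sum to 1 (within 1e-9).
    """

    data: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value {values[i, j]} at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        if self.unit not in ("counts", "relative"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit == "relative" and df.size:
            sums = values.sum(axis=0)
            bad = np.abs(sums - 1.0) > _REL_TOL
            if bad.any():
                j = int(np.argmax(bad))
                raise ValueError(
                    f"relative table: sample {df.columns[j]!r} sums to "
                    f"{sums[j]!r}, expected 1"
                )

    # ------------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Matrix of shape (n_features, n_samples), float."""
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), unit=self.unit)

    def select_features(self, ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)], unit=self.unit)

    def select_samples(self, ids) -> "FeatureTable":
        ids = list(ids)
        sub = self.data.loc[:, ids]
        ft = FeatureTable.__new__(FeatureTable)
        ft.data = sub
        # subsetting samples of a relative table breaks per-column closure
        # only if columns are removed, not reordered; keep tag either way
        ft.unit = self.unit
        if self.unit == "relative":
            ft.validate()
        return ft

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.unit == other.unit
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


@dataclass
class TaxonomyMap:
    """Feature id -> ordered lineage (kingdom..species).

    Every rank is always present; unannotated ranks hold the sentinel
    ``"unclassified"``.
    """

    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, str]] = {}
        for fid, lineage in self.lineages.items():
            entry = {rank: UNCLASSIFIED for rank in RANKS}
            for rank, name in lineage.items():
                if rank not in RANKS:
                    raise ValueError(f"unknown rank {rank!r} for {fid!r}")
                name = (name or "").strip()
                entry[rank] = name if name else UNCLASSIFIED
            clean[str(fid)] = entry
        self.lineages = clean

    def rank_of(self, feature_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.lineages.get(feature_id, {}).get(rank, UNCLASSIFIED)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata frame (samples x phenotypes)."""
    if md.shape[1] < 1:
        raise ValueError("metadata must have at least one phenotype column")
    if md.index.duplicated().any():
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    md.index = md.index.astype(str)
    return md
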