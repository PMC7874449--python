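"""Readers and writers for the tables the pipeline touches.

TSV (tab-separated, UTF-8, header row) is the canonical interchange format;
BIOM v2.1 (HDF5) feature tables are supported read-only.  All writers use a
fixed float format (6 significant digits) so that repeated write/read/write
cycles are byte-stable.
"""

from __future__ import annotations

import json
import logging
import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .containers import RANKS, UNCLASSIFIED, FeatureTable, TaxonomyMap, validate_metadata

if TYPE_CHECKING:  # pragma: no cover
    from .guilds import GuildPartition

logger = logging.getLogger("guildflow")

_FLOAT_FMT = "%.6g"

__all__ = [
    "read_feature_table",
    "read_taxonomy",
    "read_metadata",
    "write_table",
    "read_table",
    "write_partition",
    "read_partition",
    "write_correlation",
    "read_correlation",
]

_RANK_PREFIXES = {
    "k": "kingdom",
    "d": "kingdom",  # 'd__' (domain) treated as the top rank
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


# ----------------------------------------------------------------------
# feature tables
# ----------------------------------------------------------------------
def read_feature_table(path: str, format: str | None = None) -> FeatureTable:
    """Read a feature-by-sample abundance table.

    TSV dialect: first column feature id, header row sample ids.  The unit
    is inferred as ``counts`` unless every sample column sums to ~1, in
    which case it is ``relative`` (columns are re-closed exactly to absorb
    formatting round-off).
    """
    if format is None:
        format = "biom" if str(path).endswith(".biom") else "tsv"
    if format == "tsv":
        df = _read_tsv_matrix(path)
    elif format == "biom":
        df = _read_biom(path)
    else:
        raise ValueError(f"unknown feature-table format {format!r}")

    values = df.to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"empty feature table: {path}")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative value {values[i, j]} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    sums = values.sum(axis=0)
    if np.all(np.abs(sums - 1.0) < 1e-4) and (sums > 0).all():
        df = df / sums  # absorb 6-sig-digit round-off exactly
        return FeatureTable(df, unit="relative")
    return FeatureTable(df, unit="counts")


def _read_tsv_matrix(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    ncols = df.shape[1]
    for i, row in enumerate(df.itertuples(index=False)):
        if sum(pd.isna(v) for v in row) and len(row) == ncols:
            bad = [j for j, v in enumerate(row) if pd.isna(v)]
            raise ValueError(
                f"{path}: ragged/missing cell at row {df.index[i]!r}, "
                f"column {df.columns[bad[0]]!r}"
            )
    try:
        out = df.astype(float)
    except ValueError as exc:
        for fid in df.index:
            for sid in df.columns:
                try:
                    float(df.at[fid, sid])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {df.at[fid, sid]!r} at "
                        f"feature {fid!r}, sample {sid!r}"
                    ) from exc
        raise
    return out


def _read_biom(path: str) -> pd.DataFrame:
    """Minimal BIOM v2.1 (HDF5) reader: observation-major CSR layout."""
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        obs_ids = [_as_str(x) for x in fh["observation/ids"][:]]
        sample_ids = [_as_str(x) for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    return pd.DataFrame(mat.toarray(), index=obs_ids, columns=sample_ids)


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ----------------------------------------------------------------------
# taxonomy
# ----------------------------------------------------------------------
def read_taxonomy(path: str) -> TaxonomyMap:
    """Read a two-column (feature id, lineage string) taxonomy TSV.

    Lineage strings follow the ``k__...;p__...;...;s__...`` dialect;
    un-prefixed tokens are assigned to ranks by position.  Empty or
    unparseable tokens become ``"unclassified"``.
    """
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")
    lineages: dict[str, dict[str, str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            fid = parts[0].strip()
            if lineno == 1 and fid.lower() in ("feature_id", "#otu id", "otu_id", "id"):
                continue
            lineage_str = parts[1] if len(parts) > 1 else ""
            lineage = _parse_lineage(lineage_str)
            if fid in lineages and lineages[fid] != lineage:
                raise ValueError(
                    f"{path}: duplicate feature {fid!r} with conflicting lineages"
                )
            lineages[fid] = lineage
    return TaxonomyMap(lineages)


def _parse_lineage(s: str) -> dict[str, str]:
    lineage = {rank: UNCLASSIFIED for rank in RANKS}
    tokens = [t.strip() for t in s.split(";")] if s.strip() else []
    pos = 0
    for token in tokens:
        if len(token) >= 3 and token[1:3] == "__" and token[0].lower() in _RANK_PREFIXES:
            rank = _RANK_PREFIXES[token[0].lower()]
            name = token[3:].strip()
        else:
            if pos >= len(RANKS):
                continue
            rank = RANKS[pos]
            name = token
        lineage[rank] = name if name else UNCLASSIFIED
        pos = RANKS.index(rank) + 1
    return lineage


# ----------------------------------------------------------------------
# metadata
# ----------------------------------------------------------------------
def read_metadata(path: str) -> pd.DataFrame:
    """Read sample metadata (first column sample id, one column per phenotype).

    Columns with at least one numeric value are parsed as phenotypes;
    non-numeric cells in them become missing (with a logged warning).
    Entirely non-numeric columns are kept as categorical and skipped by the
    association stage.
    """
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: metadata needs at least one phenotype column")
    out = {}
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.notna().any():
            bad = raw[col].notna() & numeric.isna()
            if bad.any():
                logger.warning(
                    "metadata column %r: %d non-numeric cell(s) set to missing",
                    col, int(bad.sum()),
                )
            out[col] = numeric
        else:
            out[col] = raw[col]
    md = pd.DataFrame(out, index=raw.index.astype(str))
    return validate_metadata(md)


# ----------------------------------------------------------------------
# generic tables
# ----------------------------------------------------------------------
def write_table(table, path: str) -> None:
    """Write a FeatureTable or DataFrame as TSV (6 significant digits)."""
    if isinstance(table, FeatureTable):
        df = table.data
        index_label = "feature_id"
    else:
        df = table
        index_label = df.index.name or "id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def read_table(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")
    return pd.read_csv(path, sep="\t", index_col=0, header=0)


# ----------------------------------------------------------------------
# guild partitions
# ----------------------------------------------------------------------
def write_partition(partition: "GuildPartition", path: str) -> None:
    """Write a partition (assignments TSV + trail TSV + params JSON).

    ``path`` names the assignment table; the test trail and parameters are
    written next to it as ``<path>.trail.tsv`` and ``<path>.params.json``.
    Floats in the trail use shortest round-trip repr so that
    ``read_partition(write_partition(p))`` reproduces ``p`` exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tguild\n")
        for fid, label in partition.assignments.items():
            fh.write(f"{fid}\t{label}\n")
    with open(_trail_path(path), "w", encoding="utf-8") as fh:
        fh.write(
            "node\tn_left\tn_right\tpseudo_F\tp_value\tp_selection\t"
            "n_perm\tdecision\n"
        )
        for t in partition.trail:
            fh.write(
                f"{t.node_id}\t{t.n_left}\t{t.n_right}\t{t.pseudo_F!r}\t"
                f"{t.p_value!r}\t{t.p_selection!r}\t{t.n_perm}\t{t.decision}\n"
            )
    with open(_params_path(path), "w", encoding="utf-8") as fh:
        json.dump(partition.params, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_partition(path: str) -> "GuildPartition":
    from .guilds import GuildPartition, SplitTest

    assignments: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("feature_id"):
            raise ValueError(f"{path}: not a partition table")
        for line in fh:
            if not line.strip():
                continue
            fid, label = line.rstrip("\n").split("\t")
            assignments[fid] = label
    trail = []
    tpath = _trail_path(path)
    if os.path.exists(tpath):
        with open(tpath, "r", encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                node, nl, nr, F, p, psel, nperm, decision = (
                    line.rstrip("\n").split("\t")
                )
                trail.append(
                    SplitTest(
                        node_id=int(node),
                        pseudo_F=float(F),
                        p_value=float(p),
                        n_perm=int(nperm),
                        n_left=int(nl),
                        n_right=int(nr),
                        decision=decision,
                        p_selection=float(psel),
                    )
                )
    params = {}
    ppath = _params_path(path)
    if os.path.exists(ppath):
        with open(ppath, "r", encoding="utf-8") as fh:
            params = json.load(fh)
    return GuildPartition(assignments=assignments, trail=trail, params=params)


def _trail_path(path: str) -> str:
    return f"{path}.trail.tsv"


def _params_path(path: str) -> str:
    return f"{path}.params.json"


# ----------------------------------------------------------------------
# correlation matrices
# ----------------------------------------------------------------------
def write_correlation(cm, path: str) -> None:
    """Square correlation TSV + JSON sidecar with estimation params."""
    df = pd.DataFrame(cm.r, index=cm.feature_ids, columns=cm.feature_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="feature_id")
    sidecar = {"method": cm.method, "params": cm.params}
    with open(_params_path(path), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def read_correlation(path: str):
    from .correlation import CorrelationMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    method, params = "unknown", {}
    ppath = _params_path(path)
    if os.path.exists(ppath):
        with open(ppath, "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        method = sidecar.get("method", "unknown")
        params = sidecar.get("params", {})
    r = df.to_numpy(dtype=float)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)  # absorb formatting round-off
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        feature_ids=[str(i) for i in df.index], r=r, method=method, params=params
    )
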