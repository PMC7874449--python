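"""Guild partitioning: 1−r distances, Ward tree, recursive PERMANOVA cuts.

The algorithm clusters features (genomes/OTUs/ASVs) by co-abundance:

1. pairwise correlations are converted to distances ``d = 1 − r``;
2. the features are clustered with Ward's minimum-variance criterion
   (Lance–Williams recurrence on the supplied distances);
3. from the top of the tree, a two-group PERMANOVA asks at each node
   whether its two child clades differ significantly; significant nodes are
   split recursively, non-significant nodes become guilds.

This yields a data-driven number of guilds without presetting it.  Note
that the per-node tests are run on clades selected by the same distance
matrix, i.e. they are post-selection tests; the pure-noise behaviour is
characterised empirically in the test suite rather than corrected for.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import FeatureTable
from .correlation import (
    BootstrapSpearman,
    CorrelationMatrix,
    SparCC,
    SpearmanCorrelation,
)

logger = logging.getLogger("guildflow")

__all__ = [
    "DistanceMatrix",
    "GuildTree",
    "SplitTest",
    "GuildPartition",
    "PermanovaResult",
    "corr_to_dist",
    "ward_tree",
    "permanova",
    "selection_pvalue",
    "partition_guilds",
    "guild_abundance",
    "GuildPartitioner",
]


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    """Symmetric 1−r distance matrix over features (entries in [0, 2])."""

    feature_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.feature_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match feature ids")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < -1e-12).any() or (self.d > 2 + 1e-9).any():
            raise ValueError("1−r distances must lie in [0, 2]")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance diagonal must be 0")


@dataclass
class GuildTree:
    """Binary merge tree over features (scipy linkage encoding).

    Leaves are numbered ``0..n-1`` in ``feature_ids`` order; internal node
    ``n+i`` is created by linkage row ``i`` at height ``Z[i, 2]``.
    """

    feature_ids: list[str]
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.feature_ids)
        if n >= 2 and self.Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape mismatch")
        self._members = self._compute_members()

    @property
    def n_leaves(self) -> int:
        return len(self.feature_ids)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2 if self.n_leaves > 1 else 0

    def children(self, node: int) -> tuple[int, int]:
        n = self.n_leaves
        if node < n:
            raise ValueError(f"leaf node {node} has no children")
        row = self.Z[node - n]
        return int(row[0]), int(row[1])

    def members(self, node: int) -> list[int]:
        """Leaf indices under ``node``."""
        return self._members[node]

    def height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else float(self.Z[node - n, 2])

    def _compute_members(self) -> list[list[int]]:
        n = self.n_leaves
        members: list[list[int]] = [[i] for i in range(n)]
        for i in range(self.Z.shape[0]):
            a, b = int(self.Z[i, 0]), int(self.Z[i, 1])
            members.append(members[a] + members[b])
        return members

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        def rec(node: int, parent_height: float) -> str:
            bl = parent_height - self.height(node)
            if node < self.n_leaves:
                return f"{self.feature_ids[node]}:{bl:.6g}"
            a, b = self.children(node)
            h = self.height(node)
            return f"({rec(a, h)},{rec(b, h)}):{bl:.6g}"

        if self.n_leaves == 1:
            return f"{self.feature_ids[0]}:0;"
        root = self.root
        h = self.height(root)
        a, b = self.children(root)
        return f"({rec(a, h)},{rec(b, h)});"


@dataclass
class SplitTest:
    """Record of one PERMANOVA clade-vs-clade test.

    ``p_value`` is the classical label-permutation p; ``p_selection`` is the
    selection-calibrated p (NaN when the classical test already stopped the
    recursion, so the calibrated test was not needed).
    """

    node_id: int
    pseudo_F: float
    p_value: float
    n_perm: int
    n_left: int
    n_right: int
    decision: str  # "split" | "stop"
    p_selection: float = float("nan")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SplitTest):
            return NotImplemented
        same_sel = (
            self.p_selection == other.p_selection
            or (math.isnan(self.p_selection) and math.isnan(other.p_selection))
        )
        return same_sel and (
            (self.node_id, self.pseudo_F, self.p_value, self.n_perm,
             self.n_left, self.n_right, self.decision)
            == (other.node_id, other.pseudo_F, other.p_value, other.n_perm,
                other.n_left, other.n_right, other.decision)
        )


@dataclass
class GuildPartition:
    """Feature -> guild assignment plus the test trail that produced it."""

    assignments: dict[str, str]
    trail: list[SplitTest] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    @property
    def guild_ids(self) -> list[str]:
        seen: list[str] = []
        for label in self.assignments.values():
            if label not in seen:
                seen.append(label)
        return seen

    @property
    def n_guilds(self) -> int:
        return len(set(self.assignments.values()))

    def members(self, guild: str) -> list[str]:
        return [f for f, g in self.assignments.items() if g == guild]

    def __eq__(self, other) -> bool:
        if not isinstance(other, GuildPartition):
            return NotImplemented
        return self.assignments == other.assignments and self.trail == other.trail


# ----------------------------------------------------------------------
# distance + tree
# ----------------------------------------------------------------------
def corr_to_dist(cm: CorrelationMatrix) -> DistanceMatrix:
    """Convert correlations to distances, ``d_ij = 1 − r_ij`` (diagonal 0)."""
    d = 1.0 - cm.r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DistanceMatrix(feature_ids=list(cm.feature_ids), d=d)


def ward_tree(dm: DistanceMatrix) -> GuildTree:
    """Ward minimum-variance tree on the supplied (precomputed) distances.

    The Lance–Williams recurrence is applied directly to the 1−r
    dissimilarities; no embedding into Euclidean coordinates is attempted.
    """
    n = len(dm.feature_ids)
    if n < 2:
        raise ValueError("need at least 2 features to build a tree")
    condensed = squareform(dm.d, checks=False)
    Z = linkage(condensed, method="ward")
    return GuildTree(feature_ids=list(dm.feature_ids), Z=Z)


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------
@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_perm: int
    exhaustive: bool


def _pseudo_f(D2: np.ndarray, masks: np.ndarray, n1: int) -> np.ndarray:
    """Pseudo-F for each boolean group-A mask (masks: (P, N))."""
    N = D2.shape[0]
    n2 = N - n1
    B = masks.astype(float)
    C = 1.0 - B
    ss_a = np.einsum("pi,ij,pj->p", B, D2, B) / (2.0 * n1)
    ss_b = np.einsum("pi,ij,pj->p", C, D2, C) / (2.0 * n2)
    ss_within = ss_a + ss_b
    ss_total = D2.sum() / (2.0 * N)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ss_between / (ss_within / (N - 2))
    tol = 1e-12 * max(ss_total, 1.0)
    F = np.where(ss_within <= tol, np.where(ss_between > tol, np.inf, 0.0), F)
    return F


def permanova(
    dm, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """Two-group PERMANOVA on a distance matrix.

    ``pseudo_F = [SS_between/(a−1)] / [SS_within/(N−a)]`` with ``a = 2``,
    where ``SS_total = (1/N) Σ_{i<j} d_ij²`` and ``SS_within`` sums the
    within-group squared distances scaled by group size.  The p-value uses
    the add-one permutation estimator; when the number of distinct
    relabelings C(N, n1) does not exceed ``n_perm`` they are enumerated
    exhaustively and the exact p is reported.  Ties in F count as ≥.
    """
    d = dm.d if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    groups = np.asarray(groups)
    N = d.shape[0]
    if groups.shape[0] != N:
        raise ValueError("group labels do not match distance matrix size")
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("exactly two non-empty groups are required")
    mask = groups == uniq[0]
    n1 = int(mask.sum())
    if n1 == 0 or n1 == N:
        raise ValueError("both groups must be non-empty")
    if N < 3:
        raise ValueError("need at least 3 items for PERMANOVA")
    D2 = d**2
    F_obs = float(_pseudo_f(D2, mask[None, :], n1)[0])

    n_distinct = math.comb(N, n1)
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, N), dtype=bool)
        for k, idx in enumerate(combinations(range(N), n1)):
            masks[k, list(idx)] = True
        F_perm = _pseudo_f(D2, masks, n1)
        p = float((F_perm >= F_obs).sum()) / n_distinct
        return PermanovaResult(F_obs, p, n_distinct, True)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, N), dtype=bool)
    for k in range(n_perm):
        idx = rng.permutation(N)[:n1]
        masks[k, idx] = True
    F_perm = _pseudo_f(D2, masks, n1)
    p = (1.0 + float((F_perm >= F_obs).sum())) / (1.0 + n_perm)
    return PermanovaResult(F_obs, p, n_perm, False)


# ----------------------------------------------------------------------
# selection-calibrated split test
# ----------------------------------------------------------------------
def selection_pvalue(
    d_sub: np.ndarray, n_left: int, n_perm: int = 999, seed: int | None = None
) -> float:
    """Calibrated p-value for a split that was *chosen* by the tree.

    A clade's top split is selected by Ward to maximise separation, so the
    classical label-permutation PERMANOVA is anti-conservative there: on
    exchangeable (structureless) distances the selected split of a clade of
    8+ items rejects at alpha = 0.05 almost always.  This test builds the
    proper reference distribution: shuffle the off-diagonal entries of the
    clade's distance matrix (destroying any group structure while keeping
    the entry distribution), re-run Ward on each shuffled matrix, and score
    the pseudo-F of the split Ward then selects.  The observed F of the
    actual selected split is compared against that null with the add-one
    estimator.
    """
    N = d_sub.shape[0]
    mask = np.zeros(N, dtype=bool)
    mask[:n_left] = True
    D2 = d_sub**2
    F_obs = float(_pseudo_f(D2, mask[None, :], n_left)[0])
    if not np.isfinite(F_obs):
        return 1.0 / (1.0 + n_perm)
    rng = np.random.default_rng(seed)
    condensed = squareform(d_sub, checks=False)
    count = 0
    for _ in range(n_perm):
        shuffled = rng.permutation(condensed)
        ds = squareform(shuffled)
        Z = linkage(shuffled, method="ward")
        left = _root_split_members(Z, N)
        m = np.zeros(N, dtype=bool)
        m[left] = True
        n1 = len(left)
        if n1 == 0 or n1 == N:  # pragma: no cover - degenerate linkage
            continue
        F_null = float(_pseudo_f(ds**2, m[None, :], n1)[0])
        if F_null >= F_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def _root_split_members(Z: np.ndarray, n: int) -> list[int]:
    """Leaf indices of the first child of the linkage root."""
    members: list[list[int]] = [[i] for i in range(n)]
    for i in range(Z.shape[0]):
        members.append(members[int(Z[i, 0])] + members[int(Z[i, 1])])
    return members[int(Z[-1, 0])]


# ----------------------------------------------------------------------
# recursive partition
# ----------------------------------------------------------------------
def partition_guilds(
    tree: GuildTree,
    dm: DistanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    min_clade_size: int = 2,
    seed: int | None = None,
    bonferroni_depth: bool = False,
    selection_adjusted: bool = True,
) -> GuildPartition:
    """Top-down dichotomic PERMANOVA partition of a Ward tree.

    At each node the two child clades are compared on the restricted 1−r
    distance matrix; the recursion descends into both children when the
    split is significant and both clades have at least ``min_clade_size``
    members, otherwise the node's member set becomes one guild.  Guild
    labels are assigned in tree (pre-order) order.  Per-node random streams
    are derived from ``(seed, node_id)`` so that p-values do not depend on
    the traversal outcome elsewhere in the tree.

    With ``selection_adjusted`` (default) a split must pass *both* the
    classical label-permutation PERMANOVA and the selection-calibrated test
    of :func:`selection_pvalue` at ``alpha``; the classical test alone is
    anti-conservative on tree-selected splits and over-partitions
    homogeneous clades (see :func:`selection_pvalue`).

    ``bonferroni_depth`` divides alpha by 2**depth (root depth 0).
    """
    if tree.feature_ids != dm.feature_ids:
        raise ValueError("tree and distance matrix cover different feature sets")
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    trail: list[SplitTest] = []
    guilds: list[list[int]] = []

    def visit(node: int, depth: int) -> None:
        if node < tree.n_leaves:
            guilds.append([node])
            return
        left, right = tree.children(node)
        mem_l, mem_r = tree.members(left), tree.members(right)
        members = mem_l + mem_r
        N = len(members)
        alpha_eff = alpha / (2**depth) if bonferroni_depth else alpha
        if N >= 3:
            sub = dm.d[np.ix_(members, members)]
            labels = np.array([0] * len(mem_l) + [1] * len(mem_r))
            node_seed = int(
                np.random.SeedSequence([int(seed), int(node)]).generate_state(1)[0]
                % (2**31)
            )
            res = permanova(sub, labels, n_perm=n_perm, seed=node_seed)
            split = (
                res.p_value < alpha_eff
                and len(mem_l) >= min_clade_size
                and len(mem_r) >= min_clade_size
            )
            p_sel = float("nan")
            if split and selection_adjusted:
                sel_seed = int(
                    np.random.SeedSequence([int(seed), int(node), 1])
                    .generate_state(1)[0] % (2**31)
                )
                p_sel = selection_pvalue(
                    sub, len(mem_l), n_perm=n_perm, seed=sel_seed
                )
                split = p_sel < alpha_eff
            trail.append(
                SplitTest(
                    node_id=int(node),
                    pseudo_F=res.pseudo_F,
                    p_value=res.p_value,
                    n_perm=res.n_perm,
                    n_left=len(mem_l),
                    n_right=len(mem_r),
                    decision="split" if split else "stop",
                    p_selection=p_sel,
                )
            )
            if split:
                visit(left, depth + 1)
                visit(right, depth + 1)
                return
        guilds.append(members)

    visit(tree.root, 0)

    assignments: dict[str, str] = {}
    for k, members in enumerate(guilds, start=1):
        label = f"guild_{k}"
        for idx in sorted(members):
            assignments[tree.feature_ids[idx]] = label
    # stable feature order in the mapping
    assignments = {fid: assignments[fid] for fid in tree.feature_ids}
    params = {
        "alpha": alpha,
        "n_perm": n_perm,
        "min_clade_size": min_clade_size,
        "seed": int(seed),
        "bonferroni_depth": bonferroni_depth,
        "selection_adjusted": selection_adjusted,
    }
    return GuildPartition(assignments=assignments, trail=trail, params=params)


# ----------------------------------------------------------------------
# guild abundance
# ----------------------------------------------------------------------
def guild_abundance(ft: FeatureTable, partition: GuildPartition) -> FeatureTable:
    """Guild-by-sample table: each guild row sums its members' abundances."""
    part_feats = set(partition.assignments)
    table_feats = set(ft.feature_ids)
    missing = part_feats - table_feats
    if missing:
        raise ValueError(f"partition features absent from table: {sorted(missing)[:5]}")
    extra = table_feats - part_feats
    if extra:
        raise ValueError(f"table features not covered by partition: {sorted(extra)[:5]}")
    rows = {}
    for guild in partition.guild_ids:
        members = partition.members(guild)
        rows[guild] = ft.data.loc[members].sum(axis=0)
    import pandas as pd

    gt = pd.DataFrame(rows).T
    gt.columns = ft.data.columns
    return FeatureTable(gt, unit=ft.unit)


# ----------------------------------------------------------------------
# scikit-learn estimator
# ----------------------------------------------------------------------
class GuildPartitioner(TransformerMixin, BaseEstimator):
    """Cluster features into co-abundance guilds and aggregate them.

    Parameters
    ----------
    correlation : {"spearman", "bootstrap", "sparcc", "precomputed"} or estimator
        How to obtain the feature-feature correlation matrix from
        ``X`` (shape ``(n_samples, n_features)``).  ``"precomputed"``
        expects ``X`` to be the square correlation matrix itself.  Any
        estimator with a ``fit_transform`` returning a square correlation
        matrix may be passed.
    alpha, n_perm, min_clade_size : recursion-stop parameters (see
        :func:`partition_guilds`).
    random_state : master seed for the bootstrap and the permutation tests.

    Attributes
    ----------
    correlation_ : ndarray, square feature correlations
    tree_ : GuildTree
    labels_ : ndarray of int, guild index per feature (0-based)
    n_guilds_ : int
    trail_ : list of SplitTest
    """

    def __init__(
        self,
        correlation="spearman",
        alpha: float = 0.05,
        n_perm: int = 999,
        min_clade_size: int = 2,
        n_boot: int = 1000,
        ci_level: float = 0.95,
        filter_nonrobust: bool = True,
        bonferroni_depth: bool = False,
        selection_adjusted: bool = True,
        random_state: int | None = None,
    ):
        self.correlation = correlation
        self.alpha = alpha
        self.n_perm = n_perm
        self.min_clade_size = min_clade_size
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.filter_nonrobust = filter_nonrobust
        self.bonferroni_depth = bonferroni_depth
        self.selection_adjusted = selection_adjusted
        self.random_state = random_state

    def _correlation_estimator(self):
        if self.correlation == "spearman":
            return SpearmanCorrelation()
        if self.correlation == "bootstrap":
            return BootstrapSpearman(
                n_boot=self.n_boot,
                ci_level=self.ci_level,
                filter_nonrobust=self.filter_nonrobust,
                random_state=self.random_state,
            )
        if self.correlation == "sparcc":
            return SparCC(random_state=self.random_state)
        if hasattr(self.correlation, "fit_transform"):
            return self.correlation
        raise ValueError(f"unknown correlation method {self.correlation!r}")

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.correlation == "precomputed":
            r = X
            if r.shape[0] != r.shape[1]:
                raise ValueError("precomputed correlation must be square")
        else:
            r = self._correlation_estimator().fit_transform(X)
        n_features = r.shape[0]
        ids = [f"f{i}" for i in range(n_features)]
        cm = CorrelationMatrix(feature_ids=ids, r=r, method=str(self.correlation))
        dmat = corr_to_dist(cm)
        self.tree_ = ward_tree(dmat)
        part = partition_guilds(
            self.tree_,
            dmat,
            alpha=self.alpha,
            n_perm=self.n_perm,
            min_clade_size=self.min_clade_size,
            seed=self.random_state,
            bonferroni_depth=self.bonferroni_depth,
            selection_adjusted=self.selection_adjusted,
        )
        guild_index = {g: k for k, g in enumerate(part.guild_ids)}
        self.labels_ = np.array(
            [guild_index[part.assignments[f]] for f in ids], dtype=int
        )
        self.correlation_ = r
        self.distance_ = dmat.d
        self.trail_ = part.trail
        self.partition_ = part
        self.n_guilds_ = part.n_guilds
        self.n_features_in_ = n_features
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def transform(self, X):
        """Aggregate samples-by-features ``X`` into samples-by-guilds sums."""
        check_is_fitted(self, "labels_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of features than fit")
        membership = np.zeros((self.n_features_in_, self.n_guilds_))
        membership[np.arange(self.n_features_in_), self.labels_] = 1.0
        return X @ membership
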