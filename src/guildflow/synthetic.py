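"""Synthetic compositional microbiome data with planted guild structure.

The generator emulates the data regimes the pipeline is designed for:
log-normal strain abundances organised into co-abundant blocks (guilds),
zero inflation via dropout, compositional closure, multinomial sequencing
counts, and host phenotypes driven linearly by designated guild abundances.
Every stage of the pipeline can therefore be benchmarked against known
ground truth.

Generative model for the default table:

* guild ``g`` has one latent trajectory ``z_g(s) ~ N(0, 1)`` per sample;
* member ``i`` of guild ``g``: ``log a_is = mu_i + lam * z_g(s) + eps_is``
  with ``mu_i ~ N(0, base_log_sd^2)`` and ``eps_is ~ N(0, sigma^2)``;
* noise features follow the same law with private latents;
* zeros emulate a per-feature detection limit: within each feature the
  lowest ``dropout_prob`` fraction of abundances falls below detection and
  is set to zero (applied before closure, so sparsity is controlled
  independently of depth).  Detection-limit zeros co-vary with abundance,
  as they do in real sequencing data; zeros placed independently at random
  would destroy the very co-abundance signal the planted guilds are meant
  to carry;
* columns are closed to proportions and multinomial counts are drawn at
  ``sequencing_depth`` reads per sample.

Phenotypes are linear in standardised true guild abundance:
``y_s = sum_g beta_g * z-score(A_g(s)) + N(0, sd^2)``; standardising makes
the slopes comparable across guilds of different mean abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import FeatureTable, TaxonomyMap
from .guilds import DistanceMatrix, GuildPartition

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_guild_data",
    "simulate_phenotypes",
    "simulate_cancellation",
    "sparcc_benchmark",
    "planted_two_clade_distance",
    "evaluate_partition",
]

NOISE_LABEL = "none"


@dataclass
class SimulationParams:
    """Knobs of the planted-guild generator (defaults = study conditions)."""

    n_samples: int = 60
    n_guilds: int = 5
    guild_sizes: tuple[int, ...] | int = 8
    n_noise_features: int = 20
    within_guild_loading: float = 1.0   # lam
    feature_noise_sd: float = 0.3       # sigma
    base_log_sd: float = 1.0            # spread of per-feature means mu_i
    dropout_prob: float = 0.3
    sequencing_depth: int = 50_000
    #: list of (guild index, slope beta, noise sd); one phenotype per entry
    phenotype_effects: tuple = ((0, 2.0, 0.1), (1, -2.0, 0.1))
    seed: int | None = None

    def sizes(self) -> list[int]:
        if isinstance(self.guild_sizes, int):
            return [self.guild_sizes] * self.n_guilds
        sizes = list(self.guild_sizes)
        if len(sizes) != self.n_guilds:
            raise ValueError("guild_sizes length must equal n_guilds")
        return sizes

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_guilds < 1 or self.n_noise_features < 0:
            raise ValueError("all sizes must be positive")
        if any(s < 1 for s in self.sizes()):
            raise ValueError("guild sizes must be positive")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.sequencing_depth < 1000:
            raise ValueError("sequencing_depth must be at least 1000")
        for g, beta, sd in self.phenotype_effects:
            if not 0 <= g < self.n_guilds:
                raise ValueError(f"phenotype effect references guild {g} out of range")
            if sd < 0:
                raise ValueError("phenotype noise sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    feature_guilds: dict[str, str]
    latent: pd.DataFrame                 # guild x sample latent trajectories
    guild_relative_abundance: pd.DataFrame  # true guild sums of proportions
    phenotype_effects: tuple
    seed: int | None
    extras: dict = field(default_factory=dict)

    @property
    def planted_features(self) -> list[str]:
        return [f for f, g in self.feature_guilds.items() if g != NOISE_LABEL]


def simulate_guild_data(
    params: SimulationParams | None = None, seed: int | None = None
) -> tuple[FeatureTable, SyntheticTruth]:
    """Generate a counts FeatureTable with planted co-abundance guilds."""
    params = params or SimulationParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    sizes = params.sizes()
    n_planted = sum(sizes)
    n_features = n_planted + params.n_noise_features
    n = params.n_samples

    feature_ids, labels = [], []
    for g, size in enumerate(sizes, start=1):
        for j in range(size):
            feature_ids.append(f"g{g}_f{j + 1}")
            labels.append(f"guild_{g}")
    for j in range(params.n_noise_features):
        feature_ids.append(f"noise_{j + 1}")
        labels.append(NOISE_LABEL)
    sample_ids = [f"s{k + 1}" for k in range(n)]

    z = rng.standard_normal((params.n_guilds, n))
    mu = rng.normal(0.0, params.base_log_sd, size=n_features)
    eps = rng.normal(0.0, params.feature_noise_sd, size=(n_features, n))
    log_a = np.empty((n_features, n))
    row = 0
    for g, size in enumerate(sizes):
        log_a[row:row + size] = (
            mu[row:row + size, None]
            + params.within_guild_loading * z[g][None, :]
            + eps[row:row + size]
        )
        row += size
    if params.n_noise_features:
        z_noise = rng.standard_normal((params.n_noise_features, n))
        log_a[row:] = (
            mu[row:, None]
            + params.within_guild_loading * z_noise
            + eps[row:]
        )
    abundance = np.exp(log_a)
    if params.dropout_prob > 0:
        # detection limit: each feature's lowest dropout_prob fraction of
        # abundances is below detection
        thresholds = np.quantile(
            abundance, params.dropout_prob, axis=1, keepdims=True
        )
        abundance = np.where(abundance <= thresholds, 0.0, abundance)
    col_sums = abundance.sum(axis=0)
    dead = col_sums <= 0
    if dead.any():  # vanishingly rare; keep columns valid
        abundance[0, dead] = 1.0
        col_sums = abundance.sum(axis=0)
    proportions = abundance / col_sums

    counts = np.empty_like(proportions)
    for s in range(n):
        counts[:, s] = rng.multinomial(params.sequencing_depth, proportions[:, s])
    ft = FeatureTable(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids), unit="counts"
    )

    guild_names = [f"guild_{g + 1}" for g in range(params.n_guilds)]
    latent = pd.DataFrame(z, index=guild_names, columns=sample_ids)
    lab = np.array(labels)
    true_sums = {
        gname: proportions[lab == gname].sum(axis=0) for gname in guild_names
    }
    truth = SyntheticTruth(
        feature_guilds=dict(zip(feature_ids, labels)),
        latent=latent,
        guild_relative_abundance=pd.DataFrame(true_sums, index=sample_ids).T,
        phenotype_effects=params.phenotype_effects,
        seed=seed,
    )
    return ft, truth


def simulate_phenotypes(
    truth: SyntheticTruth,
    guild_table: FeatureTable | None = None,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Host phenotypes linearly driven by designated guild abundances.

    One phenotype per ``(guild index, beta, noise sd)`` entry:
    ``y = beta * z-score(A_g) + noise``.  ``A_g`` is taken from
    ``guild_table`` when given, otherwise from the true guild sums in
    ``truth``.
    """
    effects = params.phenotype_effects if params else truth.phenotype_effects
    if not effects:
        raise ValueError("phenotype_effects must be non-empty")
    if guild_table is not None:
        abundance = guild_table.data
    else:
        abundance = truth.guild_relative_abundance
    guild_names = list(abundance.index)
    if seed is None:
        seed = None if truth.seed is None else truth.seed + 10_000
    rng = np.random.default_rng(seed)
    sample_ids = list(abundance.columns)
    out = {}
    for k, (g, beta, sd) in enumerate(effects, start=1):
        if not 0 <= g < len(guild_names):
            raise ValueError(f"phenotype effect references guild index {g} out of range")
        a = abundance.loc[guild_names[g]].to_numpy(dtype=float)
        z = (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
        out[f"phen_{k}"] = beta * z + rng.normal(0.0, sd, size=len(sample_ids))
    return pd.DataFrame(out, index=sample_ids)


# ----------------------------------------------------------------------
# strain-vs-species cancellation fixture
# ----------------------------------------------------------------------
def simulate_cancellation(
    n_samples: int = 60,
    effect: float = 1.0,
    seed: int | None = None,
    depth: int = 20_000,
) -> tuple[FeatureTable, TaxonomyMap, pd.DataFrame, SyntheticTruth]:
    """Two anti-correlated strains of one species, opposite phenotype links.

    Strain 1 rises and strain 2 falls along the same latent gradient ``u``
    with comparable magnitude, so their species-level sum is nearly flat.
    The phenotype is ``y = effect * u + noise``: strain 1's guild associates
    positively, strain 2's negatively, and the collapsed species row shows
    an attenuated, non-significant association.  Each strain gets three
    co-abundant partner features (other taxa) so both guilds are real
    clades; two background guilds of four features are added.
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    rng = np.random.default_rng(seed)
    n = n_samples
    u = rng.standard_normal(n)

    def traj(direction: float, base: float) -> np.ndarray:
        t = np.clip(1.0 + 0.4 * direction * u, 0.05, None)
        noise = np.exp(rng.normal(0.0, 0.1, size=n))
        return base * t * noise

    rows: dict[str, np.ndarray] = {}
    rows["EE_strain_1"] = traj(+1.0, 1.0)
    rows["EE_strain_2"] = traj(-1.0, 1.0)
    # balanced partner magnitudes keep the sample totals flat along u, so
    # closure does not leak the gradient into unrelated proportions
    partner_bases = rng.uniform(0.5, 1.5, size=3)
    for j in range(3):
        rows[f"partner_up_{j + 1}"] = traj(+1.0, float(partner_bases[j]))
    for j in range(3):
        rows[f"partner_down_{j + 1}"] = traj(-1.0, float(partner_bases[j]))
    for b, zb in enumerate((rng.standard_normal(n), rng.standard_normal(n)), start=1):
        for j in range(4):
            base = float(rng.uniform(0.5, 1.5))
            noise = np.exp(rng.normal(0.0, 0.1, size=n))
            rows[f"bg{b}_f{j + 1}"] = base * np.exp(0.5 * zb) * noise

    feature_ids = list(rows)
    abundance = np.vstack([rows[f] for f in feature_ids])
    proportions = abundance / abundance.sum(axis=0)
    sample_ids = [f"s{k + 1}" for k in range(n)]
    counts = np.empty_like(proportions)
    for s in range(n):
        counts[:, s] = rng.multinomial(depth, proportions[:, s])
    ft = FeatureTable(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids), unit="counts"
    )

    lineages = {
        "EE_strain_1": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                        "genus": "Eubacterium", "species": "Eubacterium_eligens"},
        "EE_strain_2": {"kingdom": "Bacteria", "phylum": "Firmicutes",
                        "genus": "Eubacterium", "species": "Eubacterium_eligens"},
    }
    for fid in feature_ids[2:]:
        lineages[fid] = {
            "kingdom": "Bacteria",
            "genus": f"Genus_{fid}",
            "species": f"Species_{fid}",
        }
    tax = TaxonomyMap(lineages)

    y = effect * u + rng.normal(0.0, 0.3, size=n)
    md = pd.DataFrame({"phenotype": y}, index=sample_ids)

    labels = {}
    for fid in feature_ids:
        if fid == "EE_strain_1" or fid.startswith("partner_up"):
            labels[fid] = "guild_1"
        elif fid == "EE_strain_2" or fid.startswith("partner_down"):
            labels[fid] = "guild_2"
        elif fid.startswith("bg1"):
            labels[fid] = "guild_3"
        else:
            labels[fid] = "guild_4"
    truth = SyntheticTruth(
        feature_guilds=labels,
        latent=pd.DataFrame({"u": u}, index=sample_ids).T,
        guild_relative_abundance=pd.DataFrame(
            {
                g: proportions[[i for i, f in enumerate(feature_ids) if labels[f] == g]].sum(axis=0)
                for g in ("guild_1", "guild_2", "guild_3", "guild_4")
            },
            index=sample_ids,
        ).T,
        phenotype_effects=((0, effect, 0.3), (1, -effect, 0.3)),
        seed=seed,
        extras={
            "expected_categories": {
                "strain_1_guild": "positive" if effect > 0 else "neutral",
                "strain_2_guild": "negative" if effect > 0 else "neutral",
                "species": "neutral",
            },
            "species_name": "Eubacterium_eligens",
            "strain_ids": ("EE_strain_1", "EE_strain_2"),
        },
    )
    return ft, tax, md, truth


# ----------------------------------------------------------------------
# SparCC benchmark and worked-example distance matrix
# ----------------------------------------------------------------------
def sparcc_benchmark(
    n_features: int = 50,
    n_samples: int = 200,
    depth: int = 10_000,
    planted_corr: float = 0.0,
    seed: int | None = None,
) -> tuple[FeatureTable, tuple[str, str] | None]:
    """Log-normal basis + multinomial counts, with one optional planted pair.

    All basis log-abundances are independent N(mu_i, 1) except features 0
    and 1, whose log-abundances are bivariate normal with correlation
    ``planted_corr``.  Returns the counts table and the planted pair ids
    (or None when ``planted_corr == 0``).
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 1.0, size=n_features)
    log_basis = rng.standard_normal((n_features, n_samples))
    if planted_corr != 0.0:
        rho = planted_corr
        shared = rng.standard_normal(n_samples)
        e1 = rng.standard_normal(n_samples)
        e2 = rng.standard_normal(n_samples)
        log_basis[0] = np.sqrt(abs(rho)) * shared + np.sqrt(1 - abs(rho)) * e1
        log_basis[1] = np.sign(rho) * np.sqrt(abs(rho)) * shared + np.sqrt(1 - abs(rho)) * e2
    basis = np.exp(mu[:, None] + log_basis)
    proportions = basis / basis.sum(axis=0)
    counts = np.empty_like(proportions)
    for s in range(n_samples):
        counts[:, s] = rng.multinomial(depth, proportions[:, s])
    ids = [f"f{i + 1}" for i in range(n_features)]
    ft = FeatureTable(
        pd.DataFrame(counts, index=ids, columns=[f"s{j + 1}" for j in range(n_samples)]),
        unit="counts",
    )
    pair = (ids[0], ids[1]) if planted_corr != 0.0 else None
    return ft, pair


def planted_two_clade_distance(
    n_per_clade: int = 6, seed: int | None = 0
) -> tuple[DistanceMatrix, dict[str, list[str]]]:
    """Distance matrix realising the textbook two-clade stopping narrative.

    Two clades A and B of ``n_per_clade`` features each: within-clade
    distances ~0.2, between-clade ~1.8, with a small symmetric jitter so
    Ward has no exact ties.  The A-vs-B comparison is overwhelmingly
    significant while any sub-split within A or B is homogeneous noise, so
    the recursive partition should stop after one split, yielding exactly
    the two guilds A and B.
    """
    rng = np.random.default_rng(seed)
    ids = [f"A{i + 1}" for i in range(n_per_clade)] + [
        f"B{i + 1}" for i in range(n_per_clade)
    ]
    n = 2 * n_per_clade
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_per_clade) == (j < n_per_clade)
            base = 0.2 if same else 1.8
            d[i, j] = d[j, i] = base + rng.uniform(-0.02, 0.02)
    dm = DistanceMatrix(feature_ids=ids, d=d)
    clades = {"A": ids[:n_per_clade], "B": ids[n_per_clade:]}
    return dm, clades


# ----------------------------------------------------------------------
# recovery metrics
# ----------------------------------------------------------------------
def evaluate_partition(
    partition: GuildPartition,
    truth: SyntheticTruth,
    exclude_noise: bool = True,
) -> dict:
    """Compare a recovered partition against planted truth.

    Returns adjusted Rand index, guild-count error, and per-feature-weighted
    purity.  With ``exclude_noise`` (default) features planted without guild
    membership are left out: they have no ground-truth co-abundance class.
    """
    truth_labels = truth.feature_guilds
    features = [f for f in partition.assignments if f in truth_labels]
    if not features:
        raise ValueError("partition and truth share no features")
    if exclude_noise:
        features = [f for f in features if truth_labels[f] != NOISE_LABEL]
        if not features:
            raise ValueError("no planted (non-noise) features to evaluate")
    y_true = [truth_labels[f] for f in features]
    y_pred = [partition.assignments[f] for f in features]
    ari = float(adjusted_rand_score(y_true, y_pred))

    pred_series = pd.Series(y_pred, index=features)
    true_series = pd.Series(y_true, index=features)
    per_guild_purity = {}
    weighted = 0.0
    for guild, members in pred_series.groupby(pred_series):
        counts = true_series.loc[members.index].value_counts()
        purity = float(counts.iloc[0] / counts.sum())
        per_guild_purity[guild] = purity
        weighted += purity * len(members)
    n_true = len(set(y_true))
    n_pred = len(set(y_pred))
    return {
        "ari": ari,
        "n_guilds_true": n_true,
        "n_guilds_recovered": n_pred,
        "guild_count_error": n_pred - n_true,
        "purity": weighted / len(features),
        "per_guild_purity": per_guild_purity,
    }
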