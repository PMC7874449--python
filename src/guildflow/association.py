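"""Guild-phenotype association, FDR control, and guild categorisation.

Guild abundances are correlated with host phenotypes by Spearman rank
correlation; p-values are Benjamini–Hochberg corrected across all
guild-by-phenotype pairs as one family (per-phenotype families available
via a flag).  Each guild is then categorised:

* ``positive``  — at least one phenotype with q < alpha and rho > 0, and no
  significant negative association (potentially detrimental);
* ``negative``  — symmetric (potentially beneficial);
* ``mixed``     — significant associations of both signs (flagged, counted
  as neither);
* ``neutral``   — no significant association (potentially commensal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, TaxonomyMap
from .guilds import GuildPartition
from .preprocess import collapse_taxa

logger = logging.getLogger("guildflow")

__all__ = [
    "associate",
    "classify_guilds",
    "compare_guild_vs_taxon",
    "ComparisonReport",
]

MIN_OVERLAP = 5


def associate(
    gt: FeatureTable,
    md: pd.DataFrame,
    alpha_fdr: float = 0.05,
    per_phenotype_family: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of every guild with every numeric phenotype.

    Returns a frame with columns ``guild, phenotype, rho, p_value, q_value,
    n_used``.  Pairs with fewer than 5 overlapping samples, or a constant
    side, are reported with missing statistics and excluded from the BH
    family.
    """
    md = md.copy()
    md.index = md.index.astype(str)
    shared = [s for s in gt.sample_ids if s in md.index]
    if not shared:
        raise ValueError("no overlapping samples between guild table and metadata")
    numeric_cols = [c for c in md.columns if pd.api.types.is_numeric_dtype(md[c])]
    skipped = [c for c in md.columns if c not in numeric_cols]
    if skipped:
        logger.warning("skipping non-numeric phenotype column(s): %s", skipped)
    if not numeric_cols:
        raise ValueError("metadata has no numeric phenotype columns")

    abund = gt.data.loc[:, shared]
    rows = []
    for guild in gt.feature_ids:
        x_full = abund.loc[guild].to_numpy(dtype=float)
        for phen in numeric_cols:
            y_full = md.loc[shared, phen].to_numpy(dtype=float)
            ok = ~np.isnan(x_full) & ~np.isnan(y_full)
            n_used = int(ok.sum())
            rho = p = np.nan
            if n_used >= MIN_OVERLAP:
                x, y = x_full[ok], y_full[ok]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    logger.warning(
                        "constant series for pair (%s, %s); statistics missing",
                        guild, phen,
                    )
                else:
                    rho, p = stats.spearmanr(x, y)
            rows.append(
                {"guild": guild, "phenotype": phen, "rho": rho,
                 "p_value": p, "n_used": n_used}
            )
    at = pd.DataFrame(rows)
    at["q_value"] = np.nan
    if per_phenotype_family:
        for phen in numeric_cols:
            sel = (at["phenotype"] == phen) & at["p_value"].notna()
            if sel.any():
                at.loc[sel, "q_value"] = multipletests(
                    at.loc[sel, "p_value"], method="fdr_bh"
                )[1]
    else:
        sel = at["p_value"].notna()
        if sel.any():
            at.loc[sel, "q_value"] = multipletests(
                at.loc[sel, "p_value"], method="fdr_bh"
            )[1]
    at.attrs["alpha_fdr"] = alpha_fdr
    return at[["guild", "phenotype", "rho", "p_value", "q_value", "n_used"]]


def classify_guilds(at: pd.DataFrame, alpha_fdr: float = 0.05) -> pd.Series:
    """Categorise each guild as positive / negative / neutral / mixed."""
    categories = {}
    for guild, sub in at.groupby("guild", sort=False):
        sig = sub[(sub["q_value"] < alpha_fdr) & sub["rho"].notna()]
        has_pos = bool((sig["rho"] > 0).any())
        has_neg = bool((sig["rho"] < 0).any())
        if has_pos and has_neg:
            logger.warning(
                "guild %r has significant associations of both signs; "
                "flagged as mixed", guild,
            )
            categories[guild] = "mixed"
        elif has_pos:
            categories[guild] = "positive"
        elif has_neg:
            categories[guild] = "negative"
        else:
            categories[guild] = "neutral"
    return pd.Series(categories, name="category")


@dataclass
class ComparisonReport:
    """Side-by-side guild-based vs taxon-based association results."""

    guild_associations: pd.DataFrame
    guild_categories: pd.Series
    taxon_associations: pd.DataFrame
    taxon_categories: pd.Series
    per_taxon: pd.DataFrame  # taxon, members, member guilds, disagreement kind
    dropped_abundance_fraction: float

    def summary(self) -> str:
        n_dis = int((self.per_taxon["disagreement"] != "none").sum())
        n_cancel = int((self.per_taxon["disagreement"] == "cancellation").sum())
        lines = [
            f"taxa compared: {len(self.per_taxon)}",
            f"taxa with guild/taxon category disagreement: {n_dis}",
            f"  of which cancellation (taxon neutral, member guilds in "
            f"opposite directions): {n_cancel}",
            f"abundance fraction excluded as unclassified: "
            f"{self.dropped_abundance_fraction:.4f}",
        ]
        return "\n".join(lines)


def compare_guild_vs_taxon(
    ft: FeatureTable,
    tax: TaxonomyMap,
    partition: GuildPartition,
    md: pd.DataFrame,
    rank: str = "genus",
    alpha_fdr: float = 0.05,
) -> ComparisonReport:
    """Contrast guild-level and taxon-level phenotype associations.

    Runs the association stage on (a) the guild abundance table from
    ``partition`` and (b) the taxon table collapsed at ``rank`` (dropping
    unclassified features, as taxon-based analyses do).  For every taxon the
    report lists its members' guilds and flags category disagreements:
    ``cancellation`` when the taxon is neutral but its members sit in both a
    positive and a negative guild, ``split`` when member guilds disagree
    with the taxon's category in any other way.
    """
    from .guilds import guild_abundance

    gt = guild_abundance(ft, partition)
    guild_at = associate(gt, md, alpha_fdr=alpha_fdr)
    guild_cat = classify_guilds(guild_at, alpha_fdr=alpha_fdr)

    taxon_ft, taxon_report = collapse_taxa(ft, tax, rank=rank, drop_unclassified=True)
    taxon_at = associate(taxon_ft, md, alpha_fdr=alpha_fdr)
    taxon_cat = classify_guilds(taxon_at, alpha_fdr=alpha_fdr)

    rows = []
    for taxon in taxon_ft.feature_ids:
        members = [
            fid for fid in ft.feature_ids if tax.rank_of(fid, rank) == taxon
        ]
        member_guilds = sorted({partition.assignments[m] for m in members})
        member_cats = sorted({str(guild_cat.get(g, "neutral")) for g in member_guilds})
        t_cat = str(taxon_cat.get(taxon, "neutral"))
        if member_cats in ([t_cat],):
            disagreement = "none"
        elif t_cat == "neutral" and "positive" in member_cats and "negative" in member_cats:
            disagreement = "cancellation"
        elif set(member_cats) == {t_cat} | {"neutral"} or set(member_cats) == {t_cat}:
            disagreement = "none" if member_cats == [t_cat] else "split"
        else:
            disagreement = "split"
        rows.append(
            {
                "taxon": taxon,
                "n_members": len(members),
                "members": ",".join(members),
                "member_guilds": ",".join(member_guilds),
                "taxon_category": t_cat,
                "member_guild_categories": ",".join(member_cats),
                "disagreement": disagreement,
            }
        )
    per_taxon = pd.DataFrame(rows)
    return ComparisonReport(
        guild_associations=guild_at,
        guild_categories=guild_cat,
        taxon_associations=taxon_at,
        taxon_categories=taxon_cat,
        per_taxon=per_taxon,
        dropped_abundance_fraction=1.0 - taxon_report.retained_fraction_of_signal,
    )
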