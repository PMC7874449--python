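"""One-command pipeline with config file, logging, and a run manifest.

Stages: (simulate) → filter → correlate → partition → abundance →
associate → compare-taxon.  The config is a flat ``key = value`` text file
and is the single source of truth; every stochastic stage receives a seed
derived deterministically from the master seed, and the manifest records
input checksums, parameters, and outputs per stage for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import io as gio
from .association import associate, classify_guilds, compare_guild_vs_taxon
from .correlation import bootstrap_spearman, sparcc, spearman_matrix
from .guilds import corr_to_dist, guild_abundance, partition_guilds, ward_tree
from .preprocess import prevalence_filter, sparsity
from .synthetic import SimulationParams, simulate_cancellation, simulate_guild_data, simulate_phenotypes

logger = logging.getLogger("guildflow")

__all__ = ["RunConfig", "run_pipeline"]

_DEFAULTS = {
    "input_table": "",
    "taxonomy": "",
    "metadata": "",
    "simulate": "",            # "default" | "cancellation" | "" (use input files)
    "correlation_method": "bootstrap",   # bootstrap | spearman | sparcc
    "min_prevalence": 0.2,
    "alpha": 0.05,
    "n_perm": 999,
    "n_boot": 1000,
    "alpha_fdr": 0.05,
    "rank": "genus",
    "seed": 0,
}


@dataclass
class RunConfig:
    """Flat pipeline configuration; see ``_DEFAULTS`` for keys."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cfg = dict(_DEFAULTS)
        for key, val in self.values.items():
            if key not in _DEFAULTS:
                raise ValueError(f"unknown config key {key!r}")
            cfg[key] = type(_DEFAULTS[key])(val)
        self.values = cfg

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        values = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"config line without '=': {line!r}")
                key, val = line.split("=", 1)
                values[key.strip()] = val.strip()
        return cls(values)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in self.values.items():
                fh.write(f"{key} = {val}\n")

    def stage_seed(self, stage_index: int) -> int:
        import numpy as np

        return int(
            np.random.SeedSequence([int(self["seed"]), stage_index])
            .generate_state(1)[0] % (2**31)
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage error aborts the run with the stage name and cause; partial
    outputs are retained next to a ``FAILED`` marker.
    """
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"config": dict(config.values), "stages": []}
    config.to_file(os.path.join(out_dir, "config.txt"))
    current_stage = "setup"

    def record(name, params, inputs, outputs):
        manifest["stages"].append(
            {
                "stage": name,
                "params": params,
                "inputs": {p: _sha256(p) for p in inputs if p and os.path.exists(p)},
                "outputs": [os.path.relpath(p, out_dir) for p in outputs],
            }
        )

    try:
        # ---------------- simulate / load -------------------------------
        current_stage = "simulate" if config["simulate"] else "load"
        tax = None
        md = None
        if config["simulate"]:
            seed = config.stage_seed(0)
            if config["simulate"] == "default":
                params = SimulationParams()
                ft, truth = simulate_guild_data(params, seed=seed)
                md = simulate_phenotypes(truth, params=params, seed=seed + 1)
            elif config["simulate"] == "cancellation":
                ft, tax, md, truth = simulate_cancellation(seed=seed)
            else:
                raise ValueError(f"unknown simulate preset {config['simulate']!r}")
            ft_path = os.path.join(out_dir, "feature_table.tsv")
            md_path = os.path.join(out_dir, "metadata.tsv")
            gio.write_table(ft, ft_path)
            md.to_csv(md_path, sep="\t", index_label="sample_id")
            truth_path = os.path.join(out_dir, "truth.tsv")
            with open(truth_path, "w", encoding="utf-8") as fh:
                fh.write("feature_id\ttrue_guild\n")
                for fid, lab in truth.feature_guilds.items():
                    fh.write(f"{fid}\t{lab}\n")
            outputs = [ft_path, md_path, truth_path]
            if tax is not None:
                tax_path = os.path.join(out_dir, "taxonomy.tsv")
                with open(tax_path, "w", encoding="utf-8") as fh:
                    for fid, lin in tax.lineages.items():
                        s = ";".join(
                            f"{r[0]}__{'' if v == 'unclassified' else v}"
                            for r, v in lin.items()
                        )
                        fh.write(f"{fid}\t{s}\n")
                outputs.append(tax_path)
            record("simulate", {"preset": config["simulate"], "seed": seed}, [], outputs)
        else:
            if not config["input_table"]:
                raise ValueError("config needs input_table or a simulate preset")
            ft = gio.read_feature_table(config["input_table"])
            if config["taxonomy"]:
                tax = gio.read_taxonomy(config["taxonomy"])
            if config["metadata"]:
                md = gio.read_metadata(config["metadata"])
            record(
                "load",
                {},
                [config["input_table"], config["taxonomy"], config["metadata"]],
                [],
            )

        if ft.n_samples < 25:
            logger.warning(
                "only %d samples: a minimum of 25 samples is recommended for "
                "robust co-abundance analysis", ft.n_samples,
            )

        # ---------------- filter ----------------------------------------
        current_stage = "filter"
        ft_f, report = prevalence_filter(ft, float(config["min_prevalence"]))
        filt_path = os.path.join(out_dir, "filtered_table.tsv")
        rep_path = os.path.join(out_dir, "filter_report.tsv")
        gio.write_table(ft_f, filt_path)
        report.to_frame().to_csv(rep_path, sep="\t")
        record(
            "filter",
            {"min_prevalence": config["min_prevalence"]},
            [],
            [filt_path, rep_path],
        )

        # ---------------- correlate -------------------------------------
        current_stage = "correlate"
        seed_c = config.stage_seed(2)
        method = config["correlation_method"]
        if method == "bootstrap":
            cm = bootstrap_spearman(ft_f, n_boot=int(config["n_boot"]), seed=seed_c)
        elif method == "spearman":
            cm = spearman_matrix(ft_f)
        elif method == "sparcc":
            cm = sparcc(ft_f, seed=seed_c)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        corr_path = os.path.join(out_dir, "correlation.tsv")
        gio.write_correlation(cm, corr_path)
        record("correlate", {"method": method, "seed": seed_c}, [], [corr_path])

        # ---------------- partition -------------------------------------
        current_stage = "partition"
        seed_p = config.stage_seed(3)
        dm = corr_to_dist(cm)
        tree = ward_tree(dm)
        part = partition_guilds(
            tree, dm,
            alpha=float(config["alpha"]),
            n_perm=int(config["n_perm"]),
            seed=seed_p,
        )
        part_path = os.path.join(out_dir, "partition.tsv")
        tree_path = os.path.join(out_dir, "tree.nwk")
        gio.write_partition(part, part_path)
        with open(tree_path, "w", encoding="utf-8") as fh:
            fh.write(tree.to_newick() + "\n")
        record(
            "partition",
            {"alpha": config["alpha"], "n_perm": config["n_perm"], "seed": seed_p},
            [],
            [part_path, tree_path],
        )

        # ---------------- abundance -------------------------------------
        current_stage = "abundance"
        gt = guild_abundance(ft_f, part)
        gt_path = os.path.join(out_dir, "guild_table.tsv")
        gio.write_table(gt, gt_path)
        spars = {
            "feature_level_sparsity": sparsity(ft_f),
            "guild_level_sparsity": sparsity(gt),
        }
        spars_path = os.path.join(out_dir, "sparsity.tsv")
        with open(spars_path, "w", encoding="utf-8") as fh:
            for key, val in spars.items():
                fh.write(f"{key}\t{val:.6g}\n")
        record("abundance", spars, [], [gt_path, spars_path])

        # ---------------- associate -------------------------------------
        if md is not None:
            current_stage = "associate"
            at = associate(gt, md, alpha_fdr=float(config["alpha_fdr"]))
            cat = classify_guilds(at, alpha_fdr=float(config["alpha_fdr"]))
            at_path = os.path.join(out_dir, "associations.tsv")
            cat_path = os.path.join(out_dir, "guild_categories.tsv")
            at.to_csv(at_path, sep="\t", index=False, float_format="%.6g")
            cat.to_frame().to_csv(cat_path, sep="\t", index_label="guild")
            record(
                "associate", {"alpha_fdr": config["alpha_fdr"]}, [], [at_path, cat_path]
            )

        # ---------------- compare-taxon ---------------------------------
        if md is not None and tax is not None:
            current_stage = "compare-taxon"
            cmp_report = compare_guild_vs_taxon(
                ft_f, tax, part, md,
                rank=config["rank"], alpha_fdr=float(config["alpha_fdr"]),
            )
            cmp_path = os.path.join(out_dir, "taxon_comparison.tsv")
            cmp_txt = os.path.join(out_dir, "taxon_comparison.txt")
            cmp_report.per_taxon.to_csv(cmp_path, sep="\t", index=False)
            with open(cmp_txt, "w", encoding="utf-8") as fh:
                fh.write(cmp_report.summary() + "\n")
            record("compare-taxon", {"rank": config["rank"]}, [], [cmp_path, cmp_txt])

        manifest["status"] = "success"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        with open(os.path.join(out_dir, "FAILED"), "w", encoding="utf-8") as fh:
            fh.write(f"stage: {current_stage}\nerror: {exc}\n")
        _write_manifest(manifest, out_dir)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    _write_manifest(manifest, out_dir)
    logger.removeHandler(handler)
    handler.close()
    return manifest


def _write_manifest(manifest: dict, out_dir: str) -> None:
    from . import __version__

    manifest["version"] = __version__
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
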