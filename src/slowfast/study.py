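"""End-to-end experiment runners.

``run_simulation_study`` reproduces the simulation audit at a configurable
scale: simulate alignments on known trees, bin sites into rate categories,
build rate-specific alignment partitions (RSAPs), bootstrap each partition,
and measure how bipartition recovery depends on site rate and branch
length. ``run_audit`` applies the same machinery to user-supplied data.

Seeds: a single master seed fans out deterministically through
``numpy.random.SeedSequence([master, replicate, stage, ...])`` with a fixed
stage numbering (0 topology, 1 branch lengths, 2 sequence evolution,
3 bootstrap per category, 4 subsampling), so any sub-experiment can be
re-run independently and bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import Alignment
from .compare import (
    mask_support,
    pooled_rate_branchlength_spearman,
    recovery_statistics,
    bh_qvalues,
    rf_slope,
    rf_matrix,
    mds_embedding,
)
from .composition import aa_frequencies, composition_table
from .infer import bootstrap_trees, nj_tree, pairwise_distance_matrix
from .models import discretize_gamma, load_model
from .partition import TrimScheme, apply_trim, bin_sites, build_rsap, remove_invariant_sites
from .phylo import Phylogeny
from .simulate import (
    BranchLengthPrior,
    assign_branch_lengths,
    evolve_alignment,
    random_topology,
)
from .siterates import assign_site_categories

logger = logging.getLogger("slowfast")


def stage_seed(master: int, *path: int) -> np.random.SeedSequence:
    """Deterministic per-stage seed derived from the master seed and a
    counter path (replicate, stage, category...)."""
    return np.random.SeedSequence([int(master), *[int(p) for p in path]])


@dataclass
class ExperimentConfig:
    """Scaled simulation-study settings (the full-scale design is 1000
    leaves, 100 replicates and 1000 bootstrap trees per partition)."""

    n_leaves: int = 100
    n_sites: int = 2596
    n_replicates: int = 3
    n_bootstrap: int = 100
    alpha: float = 0.803
    k: int = 12
    model: str = "LG"
    internal_shape: float = 0.7581720
    terminal_shape: float = 1.509421
    internal_median: float = 0.05
    terminal_median: float = 0.20
    recovery_threshold: float = 0.8
    max_distance: float = 10.0
    use_true_tree: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("n_leaves", "n_sites", "n_replicates", "n_bootstrap", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.recovery_threshold <= 1:
            raise ValueError("recovery_threshold must lie in (0, 1]")

    def prior(self) -> BranchLengthPrior:
        return BranchLengthPrior.calibrated(
            internal_median=self.internal_median,
            terminal_median=self.terminal_median,
            internal_shape=self.internal_shape,
            terminal_shape=self.terminal_shape,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_simulation_study(config: ExperimentConfig, outdir=None) -> dict:
    """Run the full simulation audit; returns a report dict and optionally
    writes TSV/JSON artifacts under ``outdir``.

    Per replicate: simulate -> flag invariant sites -> assign rate
    categories (against the true tree by default) -> build one RSAP per
    category -> bootstrap each RSAP -> score true-bipartition support, RF
    distances to the true tree, and the rate/branch-length statistics.
    """
    model = load_model(config.model)
    cats = discretize_gamma(config.alpha, config.k)
    prior = config.prior()
    recovery_rows = []
    per_category_rows = []
    replicate_rows = []
    failures = []
    for rep in range(config.n_replicates):
        try:
            rep_result = _run_replicate(rep, config, model, cats, prior)
        except Exception as exc:
            logger.exception("replicate %d aborted: %s", rep, exc)
            failures.append({"replicate": rep, "error": str(exc)})
            continue
        recovery_rows.append(rep_result["table"])
        per_category_rows.extend(rep_result["per_category"])
        replicate_rows.append(rep_result["stats"])
    if not replicate_rows:
        raise RuntimeError(f"every replicate failed: {failures}")
    table = pd.concat(recovery_rows, ignore_index=True)
    per_category = pd.DataFrame(per_category_rows)
    replicate_stats = pd.DataFrame(replicate_rows)
    replicate_stats["pooled_q"] = bh_qvalues(replicate_stats["pooled_p"].fillna(1.0))

    by_cat = per_category.groupby("category", sort=True)
    summary = {
        "config": config.to_dict(),
        "category_rates": [float(r) for r in cats.rates],
        "n_replicates_completed": int(len(replicate_rows)),
        "failures": failures,
        "below_median_recovery_by_category": _as_dict(by_cat["below_median_recovery"].mean()),
        "top_quartile_recovery_by_category": _as_dict(by_cat["top_quartile_recovery"].mean()),
        "mean_rf_by_category": _as_dict(by_cat["mean_rf"].mean()),
        "mean_pooled_spearman_rho": float(replicate_stats["pooled_rho"].mean()),
        "pooled_spearman_by_replicate": [float(v) for v in replicate_stats["pooled_rho"]],
        "significant_replicates_q05": int((replicate_stats["pooled_q"] < 0.05).sum()),
        "mean_rf_slope_fast_range": float(replicate_stats["rf_slope"].mean()),
    }
    report = {
        "recovery_table": table,
        "per_category": per_category,
        "replicate_stats": replicate_stats,
        "summary": summary,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "recovery_table.tsv", sep="\t", index=False)
        per_category.to_csv(outdir / "per_category.tsv", sep="\t", index=False)
        replicate_stats.to_csv(outdir / "replicate_stats.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return report


def _run_replicate(rep, config, model, cats, prior) -> dict:
    logger.info("replicate %d: simulating %d leaves x %d sites (seed path [%d, %d, *])",
                rep, config.n_leaves, config.n_sites, config.seed, rep)
    tree = random_topology(config.n_leaves, stage_seed(config.seed, rep, 0))
    assign_branch_lengths(tree, prior, stage_seed(config.seed, rep, 1))
    sim = evolve_alignment(tree, model, cats, config.n_sites, stage_seed(config.seed, rep, 2))
    variable, removed = remove_invariant_sites(sim.alignment)
    if config.use_true_tree:
        guide = tree
    else:
        guide = nj_tree(
            pairwise_distance_matrix(variable, model, cats, config.max_distance)
        )
    assignment = assign_site_categories(variable, guide, model, cats)
    bins = bin_sites(assignment)
    ref_masks = tree.split_masks()
    ref_lengths = np.array(list(ref_masks.values()))
    median_bl = float(np.median(ref_lengths))
    q75_bl = float(np.quantile(ref_lengths, 0.75))

    rows = []
    per_category = []
    rf_by_cat = {}
    # an RSAP is rate-pure by construction, so within-partition trees are
    # estimated under the homogeneous (single-rate) model, in the
    # partition's own substitution units
    partition_cats = discretize_gamma(config.alpha, 1)
    for c in range(1, config.k + 1):
        sites = bins[c - 1]
        if sites.size == 0:
            logger.warning("replicate %d: category %d empty, partition skipped", rep, c)
            continue
        rsap = build_rsap(variable, sites, config.n_sites, category=c)
        sample = bootstrap_trees(
            rsap.replicated_alignment,
            config.n_bootstrap,
            model,
            partition_cats,
            seed=stage_seed(config.seed, rep, 3, c),
            max_distance=config.max_distance,
            source=f"rep{rep}_rsap{c}",
        )
        support = mask_support(sample, list(ref_masks))
        rf_vals = [
            len(set(t.split_masks()) ^ set(ref_masks)) for t in sample.trees
        ]
        rf_by_cat[c] = rf_vals
        mean_rate = float(cats.rates[c - 1])
        for m, ln in ref_masks.items():
            rows.append(
                {
                    "replicate": rep,
                    "partition": f"RSAP{c}",
                    "category": c,
                    "mean_rate": mean_rate,
                    "bipartition": f"{m:x}",
                    "branch_length": ln,
                    "support": support[m],
                    "recovered": support[m] >= config.recovery_threshold,
                }
            )
        cat_df = pd.DataFrame(rows[-len(ref_masks):])
        short = cat_df[cat_df["branch_length"] < median_bl]
        long_ = cat_df[cat_df["branch_length"] >= q75_bl]
        rec = cat_df[cat_df["recovered"]]
        per_category.append(
            {
                "replicate": rep,
                "category": c,
                "mean_rate": mean_rate,
                "n_sites_in_bin": int(sites.size),
                "mean_rf": float(np.mean(rf_vals)),
                "below_median_recovery": float(short["recovered"].mean()),
                "top_quartile_recovery": float(long_["recovered"].mean()),
                "n_recovered": int(rec.shape[0]),
                "median_recovered_branch_length": (
                    float(rec["branch_length"].median()) if len(rec) else np.nan
                ),
            }
        )
    table = pd.DataFrame(rows)
    pooled_rho, pooled_p = pooled_rate_branchlength_spearman(table)
    try:
        slope = rf_slope(rf_by_cat, cats.rates, category_range=(9, config.k))
    except ValueError:
        slope = np.nan
    stats = {
        "replicate": rep,
        "n_invariant_removed": int(removed.size),
        "pooled_rho": pooled_rho,
        "pooled_p": pooled_p,
        "rf_slope": slope,
        "median_reference_branch_length": median_bl,
    }
    return {"table": table, "per_category": per_category, "stats": stats}


def _as_dict(series: pd.Series) -> dict:
    return {str(int(k)): float(v) for k, v in series.items()}


# ---------------------------------------------------------------------------
# audit of user-supplied data
# ---------------------------------------------------------------------------

def run_audit(
    alignment: Alignment | str,
    tree: Phylogeny | str | None,
    config: ExperimentConfig,
    outdir=None,
    schemes: tuple[str, ...] = ("none", "slow_trim", "fast_trim", "both_trim"),
) -> dict:
    """Slow-fast audit of a user alignment.

    Flags invariant sites, assigns rate categories against the supplied (or
    self-estimated NJ) guide tree, writes trim-scheme alignments, builds an
    RSAP per category with bootstrap tree samples, and reports recovery,
    RF/MDS tree-space and composition statistics against the reference tree.
    """
    if isinstance(alignment, (str, Path)):
        alignment = Alignment.from_fasta(alignment)
    if alignment.n_taxa < 4:
        raise ValueError(f"audit needs at least 4 taxa, got {alignment.n_taxa}")
    model = load_model(config.model)
    cats = discretize_gamma(config.alpha, config.k)
    if isinstance(tree, (str, Path)):
        tree = Phylogeny.read(tree)
    if tree is None:
        logger.info("no guide tree supplied; estimating one (ML distances + NJ)")
        tree = nj_tree(pairwise_distance_matrix(alignment, model, cats, config.max_distance))
    variable, removed = remove_invariant_sites(alignment)
    assignment = assign_site_categories(variable, tree, model, cats)
    bins = bin_sites(assignment)
    ref_masks = tree.split_masks()

    trims = {}
    for name in schemes:
        trimmed, rep_info = apply_trim(variable, assignment, TrimScheme.named(name))
        trims[name] = {"alignment": trimmed, "report": rep_info}

    whole_profile = aa_frequencies(variable, partition="variable_alignment")
    profiles = []
    rows = []
    samples = {}
    partition_cats = discretize_gamma(config.alpha, 1)  # RSAPs are rate-pure
    for c in range(1, config.k + 1):
        sites = bins[c - 1]
        if sites.size == 0:
            continue
        rsap = build_rsap(variable, sites, config.n_sites, category=c)
        profiles.append(aa_frequencies(variable.select_sites(sites), partition=f"RSAP{c}"))
        sample = bootstrap_trees(
            rsap.replicated_alignment,
            config.n_bootstrap,
            model,
            partition_cats,
            seed=stage_seed(config.seed, 0, 3, c),
            max_distance=config.max_distance,
            source=f"rsap{c}",
        )
        samples[c] = sample
        support = mask_support(sample, list(ref_masks))
        for m, ln in ref_masks.items():
            rows.append(
                {
                    "partition": f"RSAP{c}",
                    "category": c,
                    "mean_rate": float(cats.rates[c - 1]),
                    "bipartition": f"{m:x}",
                    "branch_length": ln,
                    "support": support[m],
                    "recovered": support[m] >= config.recovery_threshold,
                }
            )
    table = pd.DataFrame(rows)
    comp = composition_table(profiles, whole_profile)
    stats = recovery_statistics(table) if table["partition"].nunique() >= 3 else None

    # tree-space picture: subsampled bootstrap trees + the reference
    rng = np.random.default_rng(stage_seed(config.seed, 0, 4))
    chosen, labels = [], []
    for c, sample in samples.items():
        take = min(10, sample.n_replicates)
        for idx in rng.choice(sample.n_replicates, size=take, replace=False):
            chosen.append(sample.trees[idx])
            labels.append(f"RSAP{c}")
    chosen.append(tree)
    labels.append("reference")
    rfm = rf_matrix(chosen)
    coords = mds_embedding(rfm)

    report = {
        "assignment": assignment,
        "recovery_table": table,
        "composition": comp,
        "statistics": stats,
        "trim_reports": {name: t["report"] for name, t in trims.items()},
        "mds": pd.DataFrame(
            {"label": labels, "mds1": coords[:, 0], "mds2": coords[:, 1]}
        ),
        "n_invariant_removed": int(removed.size),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignment.to_tsv(outdir / "site_rates.tsv")
        table.to_csv(outdir / "recovery_table.tsv", sep="\t", index=False)
        comp.to_csv(outdir / "composition.tsv", sep="\t", index=False)
        report["mds"].to_csv(outdir / "mds_coordinates.tsv", sep="\t", index=False)
        np.savetxt(outdir / "rf_matrix.tsv", rfm, delimiter="\t", fmt="%g")
        for name, t in trims.items():
            t["alignment"].to_fasta(outdir / f"trimmed_{name}.fasta")
        for c, sample in samples.items():
            sample.write(outdir / f"bootstrap_rsap{c}.nwk")
        with open(outdir / "trim_reports.json", "w") as fh:
            json.dump(report["trim_reports"], fh, indent=2)
    return report
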