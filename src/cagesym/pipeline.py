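"""End-to-end pipeline: simulate -> profile -> permutation test -> cage stats.

``run_pipeline`` executes the whole analysis on a simulated experiment and
writes every intermediate artifact plus a run manifest with file digests,
so a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .cagestats import (
    compare_climate_years,
    exclude_overfull_cages,
    fit_binomial_props,
    fit_poisson_counts,
    pairwise_contrasts,
    summarize_cages,
)
from .containers import SimConfig
from .permutation import PermConfig, cages_from_bug_table, permutation_richness_test
from .profiles import (
    DEFAULT_AGGLOMERATION_H,
    DEFAULT_RAREFACTION_DEPTH,
    agglomerate_tips,
    group_richness,
    rarefy,
)
from .seeds import substream, substream_seed
from .synthetic import (
    simulate_climate,
    simulate_experiment,
    simulate_phylogeny,
    simulate_reads,
    subsample_bugs,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineOptions", "RunManifest", "run_pipeline"]


@dataclass(frozen=True)
class PipelineOptions:
    """Knobs of the analysis stages (as opposed to the simulated design)."""

    asvs_per_lineage: int = 3
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    agglomeration_h: float = DEFAULT_AGGLOMERATION_H
    linkage_method: str = "average"
    #: rarefy before agglomerating (the default); False swaps the order.
    rarefy_first: bool = True
    n_iter: int = 10_000
    climate_days: int = 35


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, file digests, warnings."""

    root_seed: int
    config: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    substreams: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _glm_report(fit, contrasts: pd.DataFrame, letters: dict) -> dict:
    return {
        "family": fit.family,
        "levels": fit.levels,
        "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
        "fitted": {k: float(v) for k, v in fit.fitted.items()},
        "dispersion": float(fit.dispersion),
        "deviance": float(fit.deviance),
        "null_deviance": float(fit.null_deviance),
        "statistic_name": fit.statistic_name,
        "statistic": float(fit.statistic),
        "df": list(fit.df),
        "p_value": float(fit.p_value),
        "boundary_levels": sorted(fit.boundary_levels),
        "warnings": list(fit.warnings),
        "contrasts": contrasts.to_dict(orient="records"),
        "letters": letters,
        "posthoc_note": "Holm-adjusted Wald contrasts (in place of Tukey HSD)",
    }


def run_pipeline(
    config: SimConfig,
    outdir: str | Path,
    seed: int | None = None,
    options: PipelineOptions = PipelineOptions(),
) -> RunManifest:
    """Run the full simulated analysis and write artifacts to ``outdir``."""
    if seed is None:
        seed = config.seed
    elif seed != config.seed:
        config = dataclasses.replace(config, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        root_seed=seed,
        config=config.to_dict(),
        options=dataclasses.asdict(options),
        substreams={
            name: int(substream_seed(seed, name).generate_state(1)[0])
            for name in ("phylogeny", "experiment", "reads", "climate",
                         "subsample", "rarefy", "permtest")
        },
    )

    stage = "simulate"
    try:
        labels = config.lineage_labels
        tree, partition = simulate_phylogeny(
            len(labels), options.asvs_per_lineage,
            seed=substream(seed, "phylogeny"), lineage_labels=list(labels),
        )
        cages, bugs = simulate_experiment(config)
        caged_bugs = bugs[bugs["origin"] == "caged"]
        wild_bugs = bugs[bugs["origin"] == "wild"]
        tested = pd.concat(
            [subsample_bugs(caged_bugs, seed=substream(seed, "subsample")), wild_bugs]
        )
        reads = simulate_reads(tested, partition, config)

        cio.write_metadata(bugs, outdir / "bugs.tsv")
        cio.write_metadata(tested, outdir / "tested_bugs.tsv")
        cio.write_counts(reads, outdir / "asv_counts.tsv")
        cio.write_tree(tree, outdir / "asv_tree.nwk")
        cio.write_partition(partition, outdir / "true_partition.tsv")

        stage = "profile"
        if options.rarefy_first:
            rarefied = rarefy(reads, options.rarefaction_depth, substream(seed, "rarefy"))
            lineages = agglomerate_tips(
                rarefied, tree, options.agglomeration_h, options.linkage_method
            )
        else:
            collapsed = agglomerate_tips(
                reads, tree, options.agglomeration_h, options.linkage_method
            )
            rarefied_counts = rarefy(
                collapsed.counts, options.rarefaction_depth, substream(seed, "rarefy")
            )
            lineages = dataclasses.replace(collapsed, counts=rarefied_counts)
        cio.write_lineage_matrix(
            lineages, outdir / "lineage_counts.tsv", outdir / "lineage_map.tsv"
        )

        stage = "permtest"
        kept = list(lineages.counts.index)
        cage_groups = cages_from_bug_table(tested, kept)
        wild_ids = sorted(set(wild_bugs["bug_id"]) & set(kept))
        perm_seed = int(substream_seed(seed, "permtest").generate_state(1)[0]) % (2**31)
        if cage_groups and wild_ids:
            perm = permutation_richness_test(
                lineages, cage_groups, wild_ids,
                PermConfig(n_iter=options.n_iter, seed=perm_seed),
            )
            perm_report = perm.to_dict()
            perm_report["caged_group_richness"] = group_richness(
                lineages, [m for ms in cage_groups.values() for m in ms]
            )
            perm_report["wild_group_richness"] = group_richness(lineages, wild_ids)
        else:
            perm_report = {"skipped": "no caged or no wild samples after profiling"}
            manifest.warnings.append("permutation test skipped")

        stage = "cagestats"
        cages_f, bugs_f = exclude_overfull_cages(cages, bugs)
        tested_f = tested[tested["cage_id"].isin(cages_f["cage_id"]) | tested["cage_id"].isna()]
        sum_tested = summarize_cages(tested_f)
        sum_full = summarize_cages(bugs_f[bugs_f["origin"] == "caged"])
        fit_pos = fit_binomial_props(sum_tested, response="positive")
        con_pos, let_pos = pairwise_contrasts(fit_pos)
        fit_late = fit_binomial_props(sum_full, response="late")
        con_late, let_late = pairwise_contrasts(fit_late)
        fit_dead = fit_poisson_counts(sum_full)
        con_dead, let_dead = pairwise_contrasts(fit_dead)
        sum_tested.to_csv(outdir / "cage_summaries_tested.tsv", sep="\t", index=False)
        sum_full.to_csv(outdir / "cage_summaries_full.tsv", sep="\t", index=False)

        stage = "climate"
        climate_rng = substream(seed, "climate")
        clim_a = simulate_climate(
            options.climate_days, temp_max_mean=34.1, rh_max_mean=75.0,
            readings_per_day=288, start=f"{config.year}-09-01",
            seed=climate_rng,
        )
        clim_b = simulate_climate(
            options.climate_days, temp_max_mean=38.1, rh_max_mean=38.0,
            readings_per_day=24, start=f"{config.year + 1}-10-01",
            seed=climate_rng,
        )
        cio.write_climate(clim_a, outdir / "climate_year_a.tsv")
        cio.write_climate(clim_b, outdir / "climate_year_b.tsv")
        climate_report = compare_climate_years(clim_a, clim_b)

        report = {
            "permutation_test": perm_report,
            "proportion_positive": _glm_report(fit_pos, con_pos, let_pos),
            "proportion_late": _glm_report(fit_late, con_late, let_late),
            "mortality": _glm_report(fit_dead, con_dead, let_dead),
            "climate": climate_report,
        }
        cio.write_json_report(report, outdir / "report.json")
        manifest.results = {
            "permutation_p_two": perm_report.get("p_two"),
            "proportion_positive_p": report["proportion_positive"]["p_value"],
            "proportion_late_p": report["proportion_late"]["p_value"],
            "mortality_p": report["mortality"]["p_value"],
        }
    except Exception as exc:
        manifest.warnings.append(f"stage {stage!r} failed: {exc}")
        cio.write_json_report(manifest.to_dict(), outdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.files[f.name] = cio.sha256_of(f)
    cio.write_json_report(manifest.to_dict(), outdir / "manifest.json")
    return manifest
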