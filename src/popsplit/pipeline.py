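"""End-to-end orchestration: filter -> stats -> cluster -> sfs -> fit -> outliers.

Produces a machine-readable summary (JSON) plus per-stage artifact files in
the output directory, every artifact stamped with the configuration hash and
global seed. Stages can be toggled; the demographic fit runs on the four
genetic populations, grouped either from a truth record (synthetic data), by
treating popmap localities as populations, or from the clustering stage's
hard labels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import studydata
from .clustering import select_k
from .demography_fit import FitSettings, compare_models, get_model_spec, staged_fit
from .genotype_io import (
    FilterConfig,
    GenotypeMatrix,
    PopulationMap,
    filter_sites,
    read_popmap,
    read_vcf,
)
from .outlier_scan import NullConfig, fdist_scan
from .popgen_stats import (
    pairwise_fst,
    private_alleles,
    summarize_differentiation,
    variant_heterozygosity,
)
from .sfs import observed_pairwise_jsfs, write_sfs
from .synthetic_data import POPULATION_ORDER

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    outdir: str
    truth: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = ("filter", "stats", "cluster", "sfs", "fit", "outliers")
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    fst_bootstrap: int = 1000
    fst_alpha: float = 0.05
    k_replicates: int = 3
    k_criterion: str = "deltaK"
    #: how individuals map to the four model populations for sfs/fit:
    #: "truth" | "localities" | "clusters"
    population_source: str = "truth"
    projection: int = 8  # haploid projection per population
    fit_models: tuple[str, ...] = ("M3", "M6")
    fit_settings: FitSettings = field(
        default_factory=lambda: FitSettings(n_runs=2, sims_per_eval=150, ecm_cycles=2, line_evals=4)
    )
    outlier_null: NullConfig = field(
        default_factory=lambda: NullConfig(groups=5, demes_per_group=10, n_sims=1500)
    )
    outlier_q: float = 0.05

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _population_groups(
    config: PipelineConfig,
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    cluster_result,
) -> dict[str, list[str]] | None:
    if config.population_source == "truth":
        if config.truth is None:
            return None
        with open(config.truth) as fh:
            truth = json.load(fh)
        pop_of = truth["population_of"]
        return {
            p: [s for s in matrix.individuals if pop_of.get(s) == p]
            for p in POPULATION_ORDER
        }
    if config.population_source == "localities":
        loc = popmap.group_of("locality")
        labels = {
            "SOU": "southern", "NOR": "northern", "JAS": "japanese", "YE": "yalu",
        }
        groups: dict[str, list[str]] = {p: [] for p in POPULATION_ORDER}
        for s in matrix.individuals:
            code = loc[s]
            pop = labels.get(code, studydata.LOCALITY_POPULATION.get(code))
            if pop in groups:
                groups[pop].append(s)
        return groups
    if config.population_source == "clusters":
        if cluster_result is None or cluster_result.k != 4:
            return None
        labels = cluster_result.hard_labels
        # heuristic deme mapping by cluster size rank: northern > southern >
        # japanese > yalu in the emulated design
        sizes = [(np.sum(labels == c), c) for c in range(4)]
        order = [c for _, c in sorted(sizes, reverse=True)]
        rank_to_pop = dict(zip(order, ("northern", "southern", "japanese", "yalu")))
        return {
            p: [s for s, l in zip(matrix.individuals, labels) if rank_to_pop[l] == p]
            for p in POPULATION_ORDER
        }
    raise ValueError(f"unknown population_source {config.population_source!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    report: dict = {"stamp": stamp, "stages": {}, "timings_s": {}}

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.time()
        try:
            report["stages"][name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["timings_s"][name] = round(time.time() - t0, 3)

    matrix = read_vcf(config.vcf)
    popmap = read_popmap(config.popmap)
    state: dict = {"matrix": matrix}

    def stage_filter():
        filtered, rep = filter_sites(state["matrix"], config.filter_config)
        state["matrix"] = filtered
        return rep.as_dict()

    def stage_stats():
        m = state["matrix"]
        het = variant_heterozygosity(m, popmap)
        priv = private_alleles(m, popmap)
        fst = pairwise_fst(
            m,
            popmap,
            n_bootstrap=config.fst_bootstrap,
            gate_alpha=config.fst_alpha,
            seed=config.seed,
        )
        fst.to_frame().to_csv(outdir / "fst_matrix.csv")
        wright = summarize_differentiation(fst)
        return {
            "heterozygosity": {s.population: s.het_variant for s in het},
            "mean_heterozygosity": float(
                np.mean([s.het_variant for s in het if not s.flagged_small])
            ),
            "private_alleles": priv,
            "wright_bins": wright["fractions_pairs"],
            "wright_bins_with_diagonal": wright["fractions_with_diagonal"],
            "max_fst_pair": list(wright["max_pair"]),
            "max_fst": wright["max_value"],
            "excluded_groups": fst.excluded,
        }

    def stage_cluster():
        res = select_k(
            state["matrix"],
            replicates=config.k_replicates,
            criterion=config.k_criterion,
            seed=config.seed,
            popmap=popmap,
        )
        state["clusters"] = res
        np.savetxt(
            outdir / "pc_coordinates.tsv", res.pc_coordinates, delimiter="\t"
        )
        np.savetxt(
            outdir / "soft_assignments.tsv", res.soft_assignments, delimiter="\t"
        )
        return {
            "K": res.k,
            "criterion": res.criterion,
            "variance_explained": [float(v) for v in res.variance_explained],
            "delta_k_profile": {str(k): v for k, v in res.delta_k_profile.items()},
            "bic_profile": {str(k): v for k, v in res.bic_profile.items()},
        }

    def _groups():
        groups = _population_groups(
            config, state["matrix"], popmap, state.get("clusters")
        )
        if groups is None or any(len(v) < config.projection // 2 for v in groups.values()):
            return None
        return groups

    def stage_sfs():
        groups = _groups()
        if groups is None:
            return {"skipped": "population grouping unavailable"}
        m = state["matrix"]
        pm = PopulationMap(
            popmap.frame.assign(
                locality=[
                    next((p for p, mem in groups.items() if s in mem), "other")
                    for s in popmap.frame["individual"]
                ]
            )
        )
        proj = {p: config.projection for p in groups}
        obs = observed_pairwise_jsfs(m, pm, list(groups), proj)
        for (a, b), s in obs.items():
            write_sfs(s, outdir / f"jsfs_{a}_{b}.obs")
        state["obs_jsfs"] = obs
        state["pop_names"] = list(groups)
        return {
            "pairs": [f"{a}|{b}" for a, b in obs],
            "snps_used": float(sum(s.total_mass() for s in obs.values()))
            / max(len(obs), 1),
        }

    def stage_fit():
        if "obs_jsfs" not in state:
            return {"skipped": "no observed JSFS"}
        names = state["pop_names"]
        sizes = tuple(config.projection for _ in names)
        fits = staged_fit(
            state["obs_jsfs"],
            list(config.fit_models),
            sizes,
            settings=config.fit_settings,
            seed=config.seed,
            pop_names=names,
        )
        table = compare_models(fits)
        table.to_csv(outdir / "fit_comparison.tsv", sep="\t", index=False)
        return {
            "ranking": table["model"].tolist(),
            "aic": dict(zip(table["model"], table["AIC"])),
            "delta_l": dict(zip(table["model"], table["delta_L"])),
            "best_model": table["model"].iloc[0],
        }

    def stage_outliers():
        scan = fdist_scan(
            state["matrix"],
            popmap,
            null_config=config.outlier_null,
            fdr_q=config.outlier_q,
            seed=config.seed,
        )
        scan.to_csv(outdir / "outliers.tsv", sep="\t", index=False)
        counts = scan["class"].value_counts().to_dict()
        return {
            "n_sites": int(len(scan)),
            "n_positive": int(counts.get("positive", 0)),
            "n_balancing": int(counts.get("balancing", 0)),
            "target_fst": scan.attrs["target_fst"],
        }

    for name, fn in [
        ("filter", stage_filter),
        ("stats", stage_stats),
        ("cluster", stage_cluster),
        ("sfs", stage_sfs),
        ("fit", stage_fit),
        ("outliers", stage_outliers),
    ]:
        run_stage(name, fn)

    report["total_s"] = round(time.time() - t_start, 3)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
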