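"""FDIST-style F_ST outlier detection against a coalescent island-model null.

Each SNP's multi-population Weir-Cockerham F_ST and total expected
heterozygosity are compared with a null cloud of (heterozygosity, F_ST) pairs
simulated under a neutral hierarchical island model calibrated to the
observed genome-wide F_ST. Two-tailed empirical p-values are computed within
heterozygosity strata (bins of width 0.05, merged until each holds enough
null points), Benjamini-Hochberg FDR correction is applied, and flagged loci
are classified as candidates for positive selection (F_ST above the null
median of their stratum) or balancing selection (below).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coalescent_sim import SampleConfig, simulate_hierarchical_island
from .genotype_io import GenotypeMatrix, PopulationMap
from .popgen_stats import wc_components_per_site

__all__ = ["OutlierRecord", "NullConfig", "fdist_scan", "bh_fdr", "as_records"]


@dataclass(frozen=True)
class OutlierRecord:
    site_id: str
    fst_obs: float
    het_obs: float
    p_value: float
    q_value: float
    classification: str  # positive | balancing | neutral


@dataclass(frozen=True)
class NullConfig:
    """Hierarchical island null settings (survey-scale defaults)."""

    groups: int = 20
    demes_per_group: int = 100
    n_sims: int = 20_000
    target_fst: float | None = None  # default: observed multi-locus mean
    min_bin_points: int = 200
    het_bin_width: float = 0.05
    calibration_loci: int = 400


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q_values, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_values, reject


def as_records(frame: pd.DataFrame) -> list[OutlierRecord]:
    """View a scan result frame as typed per-SNP records."""
    return [
        OutlierRecord(
            site_id=row["site"],
            fst_obs=float(row["fst"]),
            het_obs=float(row["het"]),
            p_value=float(row["p_value"]),
            q_value=float(row["q_value"]),
            classification=row["class"],
        )
        for row in frame.to_dict("records")
    ]


def _per_site_stats(
    matrix: GenotypeMatrix, popmap: PopulationMap, group_by: str
) -> tuple[np.ndarray, np.ndarray]:
    groups = popmap.group_indices(matrix, group_by)
    calls = [matrix.calls[ix, :] for ix in groups.values() if len(ix) >= 2]
    if len(calls) < 2:
        raise ValueError("outlier scan needs >= 2 populations of >= 2 individuals")
    a, b, c = wc_components_per_site(calls)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = a / (a + b + c)
    p = matrix.allele_frequencies()
    het = 2.0 * p * (1.0 - p)
    return fst, het


def _het_bins(
    het_obs: np.ndarray,
    null_het: np.ndarray,
    width: float,
    min_points: int,
) -> list[tuple[float, float]]:
    """Heterozygosity strata [lo, hi) merged until each has enough null mass."""
    edges = list(np.arange(0.0, 0.5 + width, width))
    edges[-1] = 0.5 + 1e-9
    bins = []
    lo = edges[0]
    for hi in edges[1:]:
        count = int(((null_het >= lo) & (null_het < hi)).sum())
        if count >= min_points or hi == edges[-1]:
            bins.append((lo, hi))
            lo = hi
    if not bins:
        raise ValueError("no usable heterozygosity bins; increase n_sims")
    # merge a thin trailing bin backwards
    while len(bins) > 1:
        lo, hi = bins[-1]
        if int(((null_het >= lo) & (null_het < hi)).sum()) >= min_points:
            break
        plo, _ = bins[-2]
        bins = bins[:-2] + [(plo, hi)]
    lo, hi = bins[-1]
    if int(((null_het >= lo) & (null_het < hi)).sum()) < min_points:
        raise ValueError(
            "null sample too small for heterozygosity conditioning; increase n_sims"
        )
    return bins


def fdist_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    null_config: NullConfig | None = None,
    fdr_q: float = 0.05,
    seed: int = 0,
    group_by: str = "locality",
) -> pd.DataFrame:
    """Scan all SNPs for selection against the hierarchical island null.

    Returns a frame with columns site, fst, het, p_value, q_value, class.
    The empirical two-tailed p-value of a SNP is computed from the null F_ST
    values whose heterozygosity falls in the SNP's stratum, as the raw
    empirical proportion p = 2 min{P(null <= obs), P(null >= obs)} capped at
    1. As in the FDIST tradition, an observation outside the whole null
    cloud scores p = 0 (no add-one smoothing): with finitely many simulations
    an extreme locus must be flaggable after FDR correction.
    """
    cfg = null_config or NullConfig()
    fst, het = _per_site_stats(matrix, popmap, group_by)
    usable = np.isfinite(fst) & np.isfinite(het)
    target = cfg.target_fst
    if target is None:
        groups = popmap.group_indices(matrix, group_by)
        calls = [matrix.calls[ix, :] for ix in groups.values() if len(ix) >= 2]
        a, b, c = wc_components_per_site(calls)
        ok = np.isfinite(a)
        target = float(a[ok].sum() / (a + b + c)[ok].sum())
    target = min(max(target, 1e-3), 0.99)
    groups = popmap.group_indices(matrix, group_by)
    sample_sizes = tuple(2 * len(ix) for ix in groups.values() if len(ix) >= 2)
    null, info = simulate_hierarchical_island(
        cfg.groups,
        cfg.demes_per_group,
        target,
        SampleConfig(sample_sizes),
        n_sims=cfg.n_sims,
        seed=seed,
        n_calibration=cfg.calibration_loci,
    )
    null_het, null_fst = null[:, 0], null[:, 1]
    bins = _het_bins(het[usable], null_het, cfg.het_bin_width, cfg.min_bin_points)

    p_vals = np.ones(matrix.n_sites)
    medians = np.zeros(matrix.n_sites)
    for lo, hi in bins:
        in_bin = usable & (het >= lo) & (het < hi)
        nmask = (null_het >= lo) & (null_het < hi)
        nf = null_fst[nmask]
        if len(nf) == 0 or not in_bin.any():
            continue
        nf_sorted = np.sort(nf)
        obs = fst[in_bin]
        n = len(nf_sorted)
        le = np.searchsorted(nf_sorted, obs, side="right") / n
        ge = (n - np.searchsorted(nf_sorted, obs, side="left")) / n
        p_vals[in_bin] = np.minimum(1.0, 2.0 * np.minimum(le, ge))
        medians[in_bin] = np.median(nf)

    q_vals, reject = bh_fdr(p_vals[usable], fdr_q)
    q_full = np.ones(matrix.n_sites)
    q_full[usable] = q_vals
    flag_full = np.zeros(matrix.n_sites, dtype=bool)
    flag_full[usable] = reject

    classification = np.where(
        flag_full,
        np.where(fst > medians, "positive", "balancing"),
        "neutral",
    )
    frame = pd.DataFrame(
        {
            "site": [f"{s.locus_id}:{s.pos}" for s in matrix.sites],
            "fst": fst,
            "het": het,
            "p_value": p_vals,
            "q_value": q_full,
            "class": classification,
        }
    )
    frame.attrs["null_info"] = info
    frame.attrs["target_fst"] = target
    frame.attrs["het_bins"] = bins
    return frame
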