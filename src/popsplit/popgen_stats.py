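"""Diversity and differentiation statistics.

Implements the survey-style summaries: mean observed heterozygosity at variant
positions per group, private-allele counts, multi-locus pairwise F_ST with a
bootstrap significance gate, and Wright's qualitative differentiation bins.

The default F_ST estimator is Weir & Cockerham's theta, combined across loci as
a ratio of sums of the variance components a and a+b+c. A plug-in Wright-style
estimator (1 - Hw/Ht) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "PopStats",
    "FstMatrix",
    "variant_heterozygosity",
    "private_alleles",
    "pairwise_fst",
    "summarize_differentiation",
    "wc_components_per_site",
    "wc_components_from_dosage",
]

WRIGHT_BIN_EDGES = (0.05, 0.15, 0.25)
WRIGHT_BIN_NAMES = ("negligible", "minor", "moderate", "pronounced")


@dataclass(frozen=True)
class PopStats:
    """Per-group diversity summary."""

    population: str
    n_individuals: int
    het_variant: float
    n_private_alleles: int | None = None
    flagged_small: bool = False  # single-individual group: reported but flagged


@dataclass
class FstMatrix:
    """Symmetric pairwise F_ST with companion bootstrap p-values.

    ``p_values[i, j]`` is the one-sided bootstrap probability that the
    multi-locus estimate is <= 0 (loci resampled with replacement). Entries
    with p >= ``gate_alpha`` are flagged as not significantly different from
    zero; :meth:`gated_values` reports them as missing rather than zeroing.
    """

    groups: list[str]
    values: np.ndarray
    p_values: np.ndarray
    gate_alpha: float = 0.05
    n_bootstrap: int = 1000
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.groups)
        assert self.values.shape == (k, k) and self.p_values.shape == (k, k)

    @property
    def flags(self) -> np.ndarray:
        """True where the estimate fails the significance gate."""
        f = self.p_values >= self.gate_alpha
        np.fill_diagonal(f, False)
        return f

    def gated_values(self, mode: str = "missing") -> np.ndarray:
        out = self.values.copy()
        if mode == "missing":
            out[self.flags] = np.nan
        elif mode == "zero":
            out[self.flags] = 0.0
        else:
            raise ValueError("mode must be 'missing' or 'zero'")
        return out

    def to_frame(self, gated: bool = False) -> pd.DataFrame:
        vals = self.gated_values() if gated else self.values
        return pd.DataFrame(vals, index=self.groups, columns=self.groups)


def _group_calls(
    matrix: GenotypeMatrix, popmap: PopulationMap, group_by: str
) -> dict[str, np.ndarray]:
    return {
        g: matrix.calls[ix, :]
        for g, ix in popmap.group_indices(matrix, group_by).items()
    }


def variant_heterozygosity(
    matrix: GenotypeMatrix, popmap: PopulationMap, group_by: str = "locality"
) -> list[PopStats]:
    """Mean observed heterozygosity over the matrix's variant sites, per group.

    For each group the per-site value is (heterozygotes / genotyped group
    members); sites with no genotyped member of the group are skipped for that
    group. "Variant" means variable over the whole filtered matrix, so a group
    fixed at a site contributes 0 for it. Single-individual groups are
    reported but flagged (they carry no meaningful frequency information).
    """
    maf = matrix.minor_allele_frequencies()
    variant = maf > 0
    out = []
    for g, calls in _group_calls(matrix, popmap, group_by).items():
        sub = calls[:, variant]
        if sub.shape[0] == 0:
            raise ValueError(f"group {g!r} has no individuals")
        called = (sub != MISSING).sum(axis=0)
        het = (sub == 1).sum(axis=0)
        ok = called > 0
        value = float(np.mean(het[ok] / called[ok])) if ok.any() else float("nan")
        out.append(
            PopStats(
                population=g,
                n_individuals=sub.shape[0],
                het_variant=value,
                flagged_small=sub.shape[0] < 2,
            )
        )
    return out


def private_alleles(
    matrix: GenotypeMatrix, popmap: PopulationMap, group_by: str = "locality"
) -> dict[str, int]:
    """Count alleles (ref or alt) observed in exactly one group."""
    groups = _group_calls(matrix, popmap, group_by)
    if len(groups) < 2:
        raise ValueError("private alleles need >= 2 groups")
    names = list(groups)
    ref_present = np.stack(
        [((c == 0) | (c == 1)).any(axis=0) for c in groups.values()]
    )  # (G, S)
    alt_present = np.stack([((c == 1) | (c == 2)).any(axis=0) for c in groups.values()])
    counts = dict.fromkeys(names, 0)
    for present in (ref_present, alt_present):
        only_one = present.sum(axis=0) == 1
        if only_one.any():
            owner = present[:, only_one].argmax(axis=0)
            for g_idx in owner:
                counts[names[g_idx]] += 1
    return counts


def _freq_het_counts(calls: np.ndarray):
    """Per-site (n diploid called, alt frequency, het fraction) for one group."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def wc_components_per_site(group_calls: list[np.ndarray]):
    """Weir-Cockerham variance components (a, b, c) per site.

    Sites where any group has fewer than one genotyped diploid, or where the
    mean sample size is 1, return NaN components and should be dropped by the
    caller.
    """
    r = len(group_calls)
    n_i, p_i, h_i = zip(*(_freq_het_counts(c) for c in group_calls))
    n_i = np.stack(n_i)  # (r, S)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)
    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = ~valid | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_components_from_dosage(dosages: list[np.ndarray]) -> tuple[float, float]:
    """Single-locus (a, a+b+c) from per-group diploid dosage vectors."""
    cols = [np.asarray(d, dtype=np.int8).reshape(-1, 1) for d in dosages]
    a, b, c = wc_components_per_site(cols)
    if not np.isfinite(a[0]):
        return 0.0, 0.0
    return float(a[0]), float(a[0] + b[0] + c[0])


def _wright_components_per_site(group_calls: list[np.ndarray]):
    """Plug-in Wright-style components: (Ht - Hw, Ht) per site."""
    n_i, p_i, _ = zip(*(_freq_het_counts(c) for c in group_calls))
    n_i = np.stack(n_i)
    p_i = np.stack(p_i)
    valid = (n_i > 0).all(axis=0)
    with np.errstate(invalid="ignore"):
        hw = np.nanmean(2 * p_i * (1 - p_i), axis=0)
        pt = (n_i * p_i).sum(axis=0) / n_i.sum(axis=0)
        ht = 2 * pt * (1 - pt)
    num = ht - hw
    num[~valid] = np.nan
    ht = np.where(valid, ht, np.nan)
    return num, ht


def pairwise_fst(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    estimator: str = "wc",
    n_bootstrap: int = 1000,
    gate_alpha: float = 0.05,
    seed: int = 0,
    group_by: str = "locality",
    min_group_size: int = 2,
) -> FstMatrix:
    """Multi-locus pairwise F_ST with a bootstrap-over-loci significance gate.

    Groups smaller than ``min_group_size`` are excluded with a warning (a
    single fish cannot support a frequency-based estimate). Negative
    multi-locus estimates are reported as computed.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    groups = _group_calls(matrix, popmap, group_by)
    included = [g for g, c in groups.items() if c.shape[0] >= min_group_size]
    excluded = [g for g in groups if g not in included]
    if excluded:
        import logging

        logging.getLogger(__name__).warning(
            "pairwise_fst: excluding groups with < %d individuals: %s",
            min_group_size,
            excluded,
        )
    if len(included) < 2:
        raise ValueError("need >= 2 groups of sufficient size")
    k = len(included)
    values = np.zeros((k, k))
    pvals = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pair = [groups[included[i]], groups[included[j]]]
            if estimator == "wc":
                a, b, c = wc_components_per_site(pair)
                num, den = a, a + b + c
            elif estimator == "wright":
                num, den = _wright_components_per_site(pair)
            else:
                raise ValueError("estimator must be 'wc' or 'wright'")
            ok = np.isfinite(num) & np.isfinite(den)
            num, den = num[ok], den[ok]
            if den.sum() <= 0 or len(num) == 0:
                theta, p = 0.0, 1.0
            else:
                theta = float(num.sum() / den.sum())
                idx = rng.integers(0, len(num), size=(n_bootstrap, len(num)))
                boot = num[idx].sum(axis=1) / np.maximum(den[idx].sum(axis=1), 1e-300)
                p = float(np.mean(boot <= 0.0))
            values[i, j] = values[j, i] = theta
            pvals[i, j] = pvals[j, i] = p
    return FstMatrix(
        groups=included,
        values=values,
        p_values=pvals,
        gate_alpha=gate_alpha,
        n_bootstrap=n_bootstrap,
        excluded=excluded,
    )


def summarize_differentiation(
    fst: FstMatrix | pd.DataFrame,
    bins: tuple[float, ...] = WRIGHT_BIN_EDGES,
) -> dict:
    """Fractions of pairs per Wright differentiation bin, plus extreme pairs.

    Reports two denominators: unique unordered pairs only, and pairs plus the
    (zero) diagonal — survey reports are not always explicit about which they
    use, and the diagonal-inclusive convention reproduces the printed
    percentages of the study this pipeline emulates.
    """
    if isinstance(fst, FstMatrix):
        frame = fst.to_frame()
    else:
        frame = fst
    groups = list(frame.index)
    k = len(groups)
    vals = frame.to_numpy(dtype=float)
    iu = np.triu_indices(k, 1)
    pair_vals = vals[iu]
    finite = np.isfinite(pair_vals)
    edges = (-np.inf,) + tuple(bins) + (np.inf,)
    counts = {
        name: int(
            ((pair_vals[finite] > lo) & (pair_vals[finite] <= hi)).sum()
        )
        for name, lo, hi in zip(WRIGHT_BIN_NAMES, edges[:-1], edges[1:])
    }
    n_pairs = int(finite.sum())
    with_diag = n_pairs + k  # diagonal zeros fall in the lowest bin
    fractions_pairs = {n: c / n_pairs for n, c in counts.items()}
    counts_diag = dict(counts)
    counts_diag[WRIGHT_BIN_NAMES[0]] += k
    fractions_diag = {n: c / with_diag for n, c in counts_diag.items()}
    order = np.argsort(pair_vals)
    order = [o for o in order if finite[o]]
    pair_names = [(groups[a], groups[b]) for a, b in zip(*iu)]
    return {
        "counts": counts,
        "n_pairs": n_pairs,
        "fractions_pairs": fractions_pairs,
        "fractions_with_diagonal": fractions_diag,
        "max_pair": pair_names[order[-1]] if order else None,
        "max_value": float(pair_vals[order[-1]]) if order else float("nan"),
        "min_pair": pair_names[order[0]] if order else None,
        "min_value": float(pair_vals[order[0]]) if order else float("nan"),
    }
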