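"""Joint site-frequency spectra: observed (from genotypes) and expected (from models).

The two-population joint SFS (JSFS) is the summary statistic for demographic
fitting. Observed spectra are built by hypergeometric expectation-projection of
per-site allele counts down to a fixed projection size, which keeps partially
missing sites and is deterministic. Expected spectra are Monte-Carlo estimates
from structured-coalescent genealogies: every branch contributes its length to
the cell indexed by the leaves it subtends in each population, the
Rao-Blackwellized form of dropping single mutations.

Spectra are folded (minor-allele) by default: no outgroup polarizes these data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

from .coalescent_sim import DemographicModel, SampleConfig, simulate_branch_batches
from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "JointSFS",
    "observed_jsfs",
    "observed_pairwise_jsfs",
    "expected_jsfs",
    "expected_pairwise_jsfs",
    "read_sfs",
    "write_sfs",
]


def _fold_map(nA: int, nB: int):
    """Canonical-cell boolean mask and partner indices for folding."""
    i = np.arange(nA + 1)[:, None]
    j = np.arange(nB + 1)[None, :]
    t = i + j
    s = nA + nB
    canonical = (t < s - t) | (
        (t == s - t) & ((i < nA - i) | ((i == nA - i) & (j <= nB - j)))
    )
    return canonical


@dataclass
class JointSFS:
    """A two-population site-frequency spectrum.

    ``cells[i, j]`` holds mass for sites with ``i`` copies of the (minor,
    if folded) allele in population A out of ``n_a`` sampled haplotypes and
    ``j`` of ``n_b`` in population B. ``kind`` is "counts" for observed
    spectra and "proportions" for model expectations (normalized over
    unmasked cells). The two monomorphic corners are always masked; folded
    spectra additionally mask the fold-redundant half.
    """

    cells: np.ndarray
    pop_pair: tuple[str, str] = ("pop0", "pop1")
    folded: bool = True
    kind: str = "counts"
    n_dropped: int = 0
    n_monomorphic: float = 0.0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2:
            raise ValueError("JSFS cells must be 2-D")
        if (self.cells < -1e-9).any():
            raise ValueError("JSFS cells must be non-negative")
        if self.folded:
            canonical = _fold_map(self.n_a, self.n_b)
            if np.abs(self.cells[~canonical]).sum() > 1e-6 * max(
                1.0, self.cells.sum()
            ):
                raise ValueError("folded spectrum has mass in fold-redundant cells")
        if self.kind == "proportions":
            total = self.cells[self.mask].sum()
            if abs(total - 1.0) > 1e-6:
                raise ValueError("expected proportions must sum to 1 over unmasked cells")

    @property
    def n_a(self) -> int:
        return self.cells.shape[0] - 1

    @property
    def n_b(self) -> int:
        return self.cells.shape[1] - 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of cells that enter the likelihood."""
        m = np.ones_like(self.cells, dtype=bool)
        m[0, 0] = False
        m[self.n_a, self.n_b] = False
        if self.folded:
            m &= _fold_map(self.n_a, self.n_b)
        return m

    def fold(self) -> "JointSFS":
        """Map each cell onto its minor-allele-total equivalent (idempotent)."""
        canonical = _fold_map(self.n_a, self.n_b)
        out = np.zeros_like(self.cells)
        for i in range(self.n_a + 1):
            for j in range(self.n_b + 1):
                ii, jj = (i, j) if canonical[i, j] else (self.n_a - i, self.n_b - j)
                out[ii, jj] += self.cells[i, j]
        return JointSFS(
            out,
            self.pop_pair,
            folded=True,
            kind=self.kind,
            n_dropped=self.n_dropped,
            n_monomorphic=self.n_monomorphic,
        )

    def total_mass(self) -> float:
        return float(self.cells.sum())


def _project_counts(
    called: np.ndarray, alt: np.ndarray, n_proj: int
) -> np.ndarray:
    """Hypergeometric projection: (S,) counts -> (S, n_proj+1) cell masses."""
    k = np.arange(n_proj + 1)[None, :]
    return hypergeom.pmf(k, called[:, None], alt[:, None], n_proj)


def observed_jsfs(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str],
    projection: tuple[int, int],
    folded: bool = True,
    group_by: str = "locality",
) -> JointSFS:
    """Observed JSFS for a pair of groups, projected down to ``projection``.

    Per site, the alt-allele count in each group is hypergeometrically
    projected in expectation to the target haploid sizes, adding fractional
    mass across cells. Sites where a group has fewer called haplotypes than
    its projection size are dropped and counted in ``n_dropped``.
    """
    nA, nB = projection
    groups = popmap.group_indices(matrix, group_by)
    for p in pops:
        if p not in groups:
            raise KeyError(f"population {p!r} not present in popmap {group_by}")
    if any(n < 1 for n in projection):
        raise ValueError("projection sizes must be >= 1")
    for p, n in zip(pops, projection):
        if 2 * len(groups[p]) < n:
            raise ValueError(
                f"projection {n} exceeds available haplotypes for {p!r}"
            )
    cells = np.zeros((nA + 1, nB + 1))
    sub = {p: matrix.calls[groups[p], :] for p in pops}
    called = {p: 2 * (sub[p] != MISSING).sum(axis=0) for p in pops}
    alt = {p: np.where(sub[p] != MISSING, sub[p], 0).sum(axis=0) for p in pops}
    usable = (called[pops[0]] >= nA) & (called[pops[1]] >= nB)
    n_dropped = int((~usable).sum())
    if usable.any():
        pa = _project_counts(called[pops[0]][usable], alt[pops[0]][usable], nA)
        pb = _project_counts(called[pops[1]][usable], alt[pops[1]][usable], nB)
        cells = np.einsum("si,sj->ij", pa, pb)
    out = JointSFS(
        cells,
        pop_pair=pops,
        folded=False,
        kind="counts",
        n_dropped=n_dropped,
    )
    if folded:
        out = out.fold()
    out.n_monomorphic = float(out.cells[0, 0] + out.cells[out.n_a, out.n_b])
    return out


def observed_pairwise_jsfs(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: list[str],
    projection: dict[str, int],
    folded: bool = True,
    group_by: str = "locality",
) -> dict[tuple[str, str], JointSFS]:
    """All pairwise observed JSFS among ``pops`` (composite-likelihood input)."""
    return {
        (a, b): observed_jsfs(
            matrix, popmap, (a, b), (projection[a], projection[b]), folded, group_by
        )
        for a, b in combinations(pops, 2)
    }


def expected_pairwise_jsfs(
    model: DemographicModel,
    config: SampleConfig,
    n_sims: int,
    seed: int = 0,
    pop_names: list[str] | None = None,
    folded: bool = True,
    pairs: list[tuple[int, int]] | None = None,
    max_events_total: int | None = None,
) -> dict[tuple[str, str], JointSFS]:
    """Expected pairwise JSFS proportions under a demographic model.

    Estimated from ``n_sims`` coalescent genealogies of the full model; each
    branch adds its length to the unfolded cell given by its subtended leaf
    counts in the two populations of each pair (all pairs share the same
    genealogies). Zero cells are floored at ``1 / (10 n_sims)`` before
    renormalization so observed cells never meet a zero expectation.
    """
    npop = model.n_pops
    names = pop_names or [f"pop{i}" for i in range(npop)]
    if pairs is None:
        pairs = [
            (i, j)
            for i, j in combinations(range(npop), 2)
            if config.sample_sizes[i] > 0 and config.sample_sizes[j] > 0
        ]
    grids = {
        (i, j): np.zeros((config.sample_sizes[i] + 1, config.sample_sizes[j] + 1))
        for i, j in pairs
    }
    cfg_chunks: list[np.ndarray] = []
    len_chunks: list[np.ndarray] = []
    for cfgs, lens in simulate_branch_batches(
        model, config, n_sims, seed, max_events_total=max_events_total
    ):
        cfg_chunks.append(cfgs)
        len_chunks.append(lens)
    allc = np.concatenate(cfg_chunks, axis=0)
    alll = np.concatenate(len_chunks, axis=0)
    for (i, j), grid in grids.items():
        np.add.at(grid, (allc[:, i], allc[:, j]), alll)
    out: dict[tuple[str, str], JointSFS] = {}
    floor = 1.0 / (10.0 * n_sims)
    for (i, j), grid in grids.items():
        s = JointSFS(grid, pop_pair=(names[i], names[j]), folded=False, kind="raw")
        if folded:
            s = s.fold()
        cells = s.cells
        mask = s.mask
        total = cells[mask].sum()
        p = np.zeros_like(cells)
        if total > 0:
            p[mask] = cells[mask] / total
        p[mask] = np.maximum(p[mask], floor)
        p[mask] /= p[mask].sum()
        out[(names[i], names[j])] = JointSFS(
            p, pop_pair=(names[i], names[j]), folded=folded, kind="proportions"
        )
    return out


def expected_jsfs(
    model: DemographicModel,
    config: SampleConfig,
    n_sims: int,
    seed: int = 0,
    pops: tuple[int, int] = (0, 1),
    pop_names: list[str] | None = None,
    folded: bool = True,
) -> JointSFS:
    """Expected JSFS for one deme pair (see :func:`expected_pairwise_jsfs`)."""
    if len(config.sample_sizes) != model.n_pops:
        raise ValueError("sample config does not match model deme count")
    names = pop_names or [f"pop{i}" for i in range(model.n_pops)]
    result = expected_pairwise_jsfs(
        model, config, n_sims, seed, pop_names=names, folded=folded,
        pairs=[tuple(sorted(pops))],
    )
    key = (names[min(pops)], names[max(pops)])
    return result[key]


def write_sfs(sfs: JointSFS, path: str | os.PathLike) -> None:
    """Write a pairwise SFS in the fastsimcoal-style ``*.obs`` text dialect.

    Line 1: "1 observations". Line 2: tab-led column labels ``d0_i`` for
    population A. Following lines: one row per population-B class ``d1_j``
    with the cell values — i.e. the text matrix is the transpose of
    ``cells``.
    """
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{i}" for i in range(sfs.n_a + 1)) + "\n")
        for j in range(sfs.n_b + 1):
            row = "\t".join(repr(float(sfs.cells[i, j])) for i in range(sfs.n_a + 1))
            fh.write(f"d1_{j}\t{row}\n")


def read_sfs(
    path: str | os.PathLike,
    pop_pair: tuple[str, str] = ("pop0", "pop1"),
    folded: bool = True,
    kind: str = "counts",
) -> JointSFS:
    """Read a pairwise SFS written by :func:`write_sfs`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or "observations" not in lines[0]:
        raise ValueError(f"{path}: missing 'observations' header line")
    header = lines[1].split("\t")
    n_cols = len([h for h in header if h.startswith("d0_")])
    if n_cols < 1:
        raise ValueError(f"{path}: malformed column label line")
    rows = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        if not parts[0].startswith("d1_"):
            raise ValueError(f"{path}: malformed row label {parts[0]!r}")
        vals = [float(x) for x in parts[1:]]
        if len(vals) != n_cols:
            raise ValueError(
                f"{path}: row {parts[0]} has {len(vals)} values, expected {n_cols}"
            )
        if any(v < 0 for v in vals):
            raise ValueError(f"{path}: negative count in row {parts[0]}")
        rows.append(vals)
    cells = np.asarray(rows).T  # rows in file are population B
    return JointSFS(cells, pop_pair=pop_pair, folded=folded, kind=kind)
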