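"""PCA of the genotype matrix and cluster-number selection.

Principal components use the standard allele-frequency normalization for
genotype data (center by twice the allele frequency, scale by
sqrt(2 p (1 - p))), with mean imputation of missing calls. The number of
genetic clusters K is chosen by fitting Gaussian mixtures on the top
components with seeded replicate restarts and applying Evanno's second-order
rate-of-change statistic dK to the replicate log-likelihood profile (with a
BIC alternative, which also handles the boundary values of K that dK cannot
score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

__all__ = ["ClusteringResult", "pca", "select_k"]


@dataclass
class ClusteringResult:
    """PCA coordinates plus the selected mixture clustering."""

    pc_coordinates: np.ndarray  # individuals x components
    variance_explained: np.ndarray
    k: int
    soft_assignments: np.ndarray  # individuals x k responsibilities
    delta_k_profile: dict[int, float]
    bic_profile: dict[int, float]
    loglik_profile: dict[int, list[float]]
    criterion: str = "deltaK"

    @property
    def hard_labels(self) -> np.ndarray:
        return self.soft_assignments.argmax(axis=1)

    def plot_scree(self, ax=None):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ax.plot(
            np.arange(1, len(self.variance_explained) + 1),
            self.variance_explained,
            "o-",
        )
        ax.set_xlabel("component")
        ax.set_ylabel("variance explained")
        return ax


def _scaled_genotypes(matrix: GenotypeMatrix, patterson: bool = True) -> np.ndarray:
    calls = matrix.calls.astype(float)
    calls[matrix.calls == MISSING] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    if np.isnan(p).any():
        raise ValueError("matrix contains all-missing sites; filter first")
    x = calls - 2.0 * p
    x = np.where(np.isnan(x), 0.0, x)  # mean imputation
    if patterson:
        denom = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
        x = x / denom
    return x


def pca(
    matrix: GenotypeMatrix,
    n_components: int = 3,
    patterson: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA via SVD; returns (coordinates, variance_explained)."""
    if matrix.n_individuals < 2 or matrix.n_sites < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 sites")
    x = _scaled_genotypes(matrix, patterson)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2 / np.sum(s**2)
    n_components = min(n_components, len(s))
    return u[:, :n_components] * s[:n_components], var[:n_components]


def significant_components(matrix: GenotypeMatrix, cap: int = 10) -> int:
    """Number of PCs with eigenvalue above the Marchenko-Pastur noise edge.

    With Patterson-normalized genotypes the bulk of the eigenvalue spectrum of
    an unstructured sample lies below ``(1 + sqrt(n/L))^2``; components above
    that edge carry population signal. At least two are always retained.
    """
    x = _scaled_genotypes(matrix)
    n, L = x.shape
    s = np.linalg.svd(x, compute_uv=False)
    lam = s**2 / L
    edge = (1.0 + np.sqrt(n / L)) ** 2
    return int(min(max(int((lam > edge).sum()), 2), cap, n - 1))


def select_k(
    matrix: GenotypeMatrix,
    k_range: tuple[int, int] | None = None,
    replicates: int = 3,
    criterion: str = "bic",
    seed: int = 0,
    n_components: int | str = "auto",
    popmap: PopulationMap | None = None,
) -> ClusteringResult:
    """Choose the number of genetic clusters on the significant principal
    components.

    Candidate K values default to 1 .. (number of regions + 2) when a popmap
    is supplied, else 1 .. min(9, n-1). Each K is scored by ``replicates``
    seeded Gaussian-mixture fits on the PCs above the Marchenko-Pastur noise
    edge. Under the default BIC criterion the best replicate's BIC decides.
    The Evanno criterion computes dK = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))
    on the replicate log-likelihoods and picks its maximum over interior K;
    note that on converged mixture likelihoods dK inherits its well-known
    bias toward the uppermost hierarchical split, and when every replicate
    converges identically (sd = 0 everywhere) the selection falls back to
    BIC with a warning. Soft assignments come from the best replicate at the
    chosen K.
    """
    if k_range is None:
        kmax = (
            len(popmap.regions) + 2 if popmap is not None else min(9, matrix.n_individuals - 1)
        )
        k_range = (1, min(kmax, matrix.n_individuals - 1))
    k_lo, k_hi = k_range
    if not (1 <= k_lo <= k_hi <= matrix.n_individuals - 1):
        raise ValueError("k_range must lie within [1, n_individuals - 1]")
    if criterion not in ("deltaK", "bic"):
        raise ValueError("criterion must be 'deltaK' or 'bic'")
    if n_components == "auto":
        n_components = significant_components(matrix)
    coords, var = pca(matrix, n_components=n_components)
    rng = np.random.default_rng(seed)
    loglik: dict[int, list[float]] = {}
    bic: dict[int, float] = {}
    models: dict[int, GaussianMixture] = {}
    for k in range(k_lo, k_hi + 1):
        fits = []
        for _ in range(replicates):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                reg_covar=1e-4,
                init_params="kmeans",
                n_init=2,
                max_iter=300,
                random_state=int(rng.integers(2**31)),
            ).fit(coords)
            fits.append(gm)
        lls = [float(g.score(coords) * coords.shape[0]) for g in fits]
        loglik[k] = lls
        best = fits[int(np.argmax(lls))]
        bic[k] = float(best.bic(coords))
        models[k] = best

    delta_k: dict[int, float] = {}
    sds = {k: float(np.std(v)) for k, v in loglik.items()}
    means = {k: float(np.mean(v)) for k, v in loglik.items()}
    for k in range(k_lo + 1, k_hi):
        sd = sds[k]
        if sd > 0:
            delta_k[k] = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sd

    chosen_criterion = criterion
    if criterion == "deltaK" and not delta_k:
        logger.warning("zero replicate spread in dK denominator; falling back to BIC")
        chosen_criterion = "bic"
    if chosen_criterion == "deltaK":
        k_sel = max(delta_k, key=delta_k.get)
    else:
        k_sel = min(bic, key=bic.get)

    resp = models[k_sel].predict_proba(coords)
    return ClusteringResult(
        pc_coordinates=coords,
        variance_explained=var,
        k=k_sel,
        soft_assignments=resp,
        delta_k_profile=delta_k,
        bic_profile=bic,
        loglik_profile=loglik,
        criterion=chosen_criterion,
    )
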