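"""Population-structure diagnostics: PCA, IBS similarity, LD decay,
and Euclidean phenotype distance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .grm import GRM, compute_grm
from .panels import GenotypeMatrix
from .pheno import PhenotypeTable

__all__ = [
    "StructureReport",
    "pca",
    "ibs_matrix",
    "ld_decay",
    "pheno_distance",
]


@dataclass
class StructureReport:
    pcs: pd.DataFrame | None = None
    explained: np.ndarray | None = None
    ibs: pd.DataFrame | None = None
    ld_decay: pd.DataFrame | None = None
    pheno_dist: pd.DataFrame | None = None


def pca(data, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components from the GRM eigendecomposition.

    Accepts a GenotypeMatrix (a vanraden1 GRM is built first) or a GRM.
    Coordinates are eigenvector * sqrt(eigenvalue); each component's
    sign is fixed so its largest-magnitude loading is positive.
    Explained-variance fractions are relative to the positive spectrum.
    """
    grm = compute_grm(data) if isinstance(data, GenotypeMatrix) else data
    if not isinstance(grm, GRM):
        raise ConfigurationError("pca expects a GenotypeMatrix or GRM")
    n = grm.n_samples
    if n < n_components + 1:
        raise DataError(f"n={n} too small for {n_components} components")
    evals, evecs = np.linalg.eigh(grm.values)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    if pos.sum() < n_components:
        warnings.warn(
            f"only {int(pos.sum())} positive eigenvalues; truncating", stacklevel=2
        )
        n_components = int(pos.sum())
    total = evals[pos].sum()
    coords = np.empty((n, n_components))
    for k in range(n_components):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, k] = v * np.sqrt(evals[k])
    explained = evals[:n_components] / total
    table = pd.DataFrame(
        coords, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    table.insert(0, "sample_id", grm.sample_ids)
    return table, explained


def ibs_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state similarity.

    IBS(i, j) = mean over shared non-missing variants of
    1 - |x_i - x_j| / 2; the diagonal is 1.  Pairs with no shared
    non-missing variant get NaN.
    """
    if gm.n_variants < 1:
        raise DataError("need at least one variant")
    X = gm.dosage
    # indicator decomposition: sum |xi-xj| = sum_{g,h} |g-h| * N_gh
    A = [np.nan_to_num((X == g).astype(float)) for g in (0.0, 1.0, 2.0)]
    d1 = A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
    d2 = 2.0 * (A[0] @ A[2].T + A[2] @ A[0].T)
    C = A[0] + A[1] + A[2]
    counts = C @ C.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - (d1 + d2) / (2.0 * counts)
    sim[counts == 0] = np.nan
    np.fill_diagonal(sim, 1.0)
    if np.isnan(sim).any():
        warnings.warn("sample pairs with no shared non-missing variants", stacklevel=2)
    return pd.DataFrame(sim, index=gm.sample_ids, columns=gm.sample_ids)


def ld_decay(
    gm: GenotypeMatrix,
    max_distance_bp: int = 1_000_000,
    maf_min: float = 0.05,
    distance_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean squared dosage correlation by intra-chromosomal distance.

    Only variants with MAF > ``maf_min`` enter; bins default to 50
    log-spaced intervals up to ``max_distance_bp``.
    """
    if distance_bins is None:
        distance_bins = np.unique(
            np.round(np.logspace(0, np.log10(max_distance_bp), 51)).astype(int)
        )
    edges = np.asarray(distance_bins, dtype=float)
    maf = gm.maf()
    keep = np.nan_to_num(maf) > maf_min
    pos = gm.variants.table["pos"].to_numpy()
    chroms = gm.variants.table["chrom"].to_numpy()
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero((chroms == chrom) & keep)
        if cidx.size < 2:
            continue
        cpos = pos[cidx]
        X = gm.dosage[:, cidx]
        for a in range(cidx.size - 1):
            b = a + 1
            while b < cidx.size and cpos[b] - cpos[a] <= max_distance_bp:
                ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
                if ok.sum() >= 3:
                    x, y = X[ok, a], X[ok, b]
                    if x.std() > 0 and y.std() > 0:
                        r = np.corrcoef(x, y)[0, 1]
                        d = cpos[b] - cpos[a]
                        bi = np.searchsorted(edges, d, side="right") - 1
                        if 0 <= bi < len(sums):
                            sums[bi] += r * r
                            counts[bi] += 1
                b += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "distance_low": edges[:-1],
            "distance_high": edges[1:],
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def pheno_distance(
    pt: PhenotypeTable, traits: list | None = None, standardize: bool = True
) -> pd.DataFrame:
    """Euclidean distance between individuals on the selected traits.

    Missing trait values are handled pairwise-complete; a pair with no
    shared non-missing trait gets NaN.
    """
    traits = traits or pt.traits
    T = pt.data[list(traits)].to_numpy(float)
    if standardize:
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(T, axis=0, ddof=1)
            T = (T - np.nanmean(T, axis=0)) / np.where(sd > 0, sd, 1.0)
    n = T.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = T - T[i]
        shared = ~np.isnan(diff)
        sq = np.where(shared, diff**2, 0.0).sum(axis=1)
        none_shared = shared.sum(axis=1) == 0
        d = np.sqrt(sq)
        d[none_shared] = np.nan
        dist[i] = d
    np.fill_diagonal(dist, 0.0)
    ids = pt.sample_ids
    return pd.DataFrame(dist, index=ids, columns=ids)
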