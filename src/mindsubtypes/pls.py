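"""Imaging-transcriptomics: PLS1, bootstrap gene scores, spin permutation.

The first partial-least-squares component (PLS1) is the linear combination
of gene expression maximally covarying with a regional case-control t-map.
For a single response, the PLS1 weight vector is the normalized
cross-covariance X'y of the column-standardized expression matrix with the
centred map — equivalently the dominant right singular direction of the
rank-one cross-covariance.  Gene reliability is quantified by resampling
regions with replacement: Z = weight / bootstrap SE, with two-sided normal
p-values and Benjamini-Hochberg correction; genes with Z > 3 (p_FDR <
0.005) are classed PLS1+, Z < -3 PLS1-.

Spatial inference uses spin permutations: region centroids on the unit
sphere are randomly rotated and matched back to the original positions by
optimal assignment, yielding spatial-autocorrelation-preserving null
permutations of one map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .casecontrol import bh_fdr

__all__ = [
    "PlsComponent",
    "SpatialCorrelationResult",
    "fit_pls1",
    "permutation_component_p",
    "bootstrap_gene_z",
    "spin_permutations",
    "spin_correlation",
    "overlap_reference",
]


@dataclass
class PlsComponent:
    weights: np.ndarray          # per-gene, unit norm
    scores: np.ndarray           # per-region
    variance_explained: float    # squared correlation of scores with y
    genes: list


@dataclass
class SpatialCorrelationResult:
    r: float
    p_spin: float
    n_spins: int
    method: str = "pearson"


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def fit_pls1(x, y, genes=None) -> PlsComponent:
    """First PLS component of a region x gene matrix against a regional map.

    Columns of ``x`` are standardized and ``y`` centred internally.  The
    component is oriented so that its region scores correlate positively
    with ``y`` (automatic for a single response).
    """
    if isinstance(x, pd.DataFrame):
        genes = list(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if x.shape[0] != yv.size:
        raise ValueError("x rows and y length differ")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 regions")
    if np.std(yv) == 0:
        raise ValueError("response map has zero variance")
    xs = _standardize_columns(x)
    yc = yv - yv.mean()
    w = xs.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("expression carries no covariance with the map")
    w = w / norm
    scores = xs @ w
    r = np.corrcoef(scores, yv)[0, 1]
    return PlsComponent(weights=w, scores=scores, variance_explained=float(r ** 2),
                        genes=genes if genes is not None else list(range(x.shape[1])))


def permutation_component_p(x, y, n_perm: int = 5000, seed: int = 0) -> float:
    """Permutation p-value for PLS1: shuffle the map across regions."""
    comp = fit_pls1(x, y)
    rng = np.random.default_rng(seed)
    yv = np.asarray(y, dtype=float)
    exceed = 0
    for _ in range(n_perm):
        null = fit_pls1(x, rng.permutation(yv)).variance_explained
        exceed += null >= comp.variance_explained
    return (1 + exceed) / (n_perm + 1)


def bootstrap_gene_z(x, y, n_boot: int = 5000, seed: int = 0,
                     z_thresh: float = 3.0, fdr_thresh: float = 0.005,
                     chunk: int = 250) -> pd.DataFrame:
    """Bootstrap gene reliability scores for PLS1.

    Regions are resampled with replacement; each replicate is oriented
    canonically (region scores positively correlated with the resampled
    map) and scaled by the norm of the *original* cross-covariance rather
    than its own.  Scaling replicates by their own norm would cancel the
    shared component of their fluctuation and understate the standard
    error whenever genes outnumber regions, inflating null Z scores.
    Returns a per-gene table with weight, bootstrap SE, Z, normal p,
    BH-FDR p and sign class.
    """
    if n_boot < 100:
        raise ValueError("n_boot < 100 gives unstable standard errors")
    if isinstance(x, pd.DataFrame):
        genes = list(x.columns)
        xm = x.to_numpy(dtype=float)
    else:
        xm = np.asarray(x, dtype=float)
        genes = list(range(xm.shape[1]))
    yv = np.asarray(y, dtype=float)
    n = xm.shape[0]
    if n < 10:
        raise ValueError("need at least 10 regions to bootstrap")
    base = fit_pls1(xm, yv)
    xs_orig = _standardize_columns(xm)
    base_norm = np.linalg.norm(xs_orig.T @ (yv - yv.mean()))
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, xm.shape[1]))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xb = xm[idx]                                  # (b, n, g)
        yb = yv[idx]                                  # (b, n)
        mu = xb.mean(axis=1, keepdims=True)
        sd = xb.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        xbs = (xb - mu) / sd
        ybc = yb - yb.mean(axis=1, keepdims=True)
        w = np.einsum("bng,bn->bg", xbs, ybc)
        boots[done:done + b] = w / base_norm
        done += b
    se = boots.std(axis=0, ddof=1)
    se = np.where(se == 0, np.finfo(float).tiny, se)
    z = base.weights / se
    p = 2 * stats.norm.sf(np.abs(z))
    p_fdr = bh_fdr(p)
    cls = np.where((z > z_thresh) & (p_fdr < fdr_thresh), "PLS1+",
                   np.where((z < -z_thresh) & (p_fdr < fdr_thresh), "PLS1-", "ns"))
    return pd.DataFrame({"gene": genes, "weight": base.weights,
                         "bootstrap_se": se, "z": z, "p": p, "p_fdr": p_fdr,
                         "cls": cls}).set_index("gene")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def spin_permutations(centroids: np.ndarray, n_spins: int,
                      seed: int = 0) -> np.ndarray:
    """Spatial null permutations from random sphere rotations.

    Each spin rotates the centroids by a uniform random rotation and matches
    rotated to original positions by minimum-cost assignment, so every null
    is an exact permutation of region indices (value multisets preserved).
    """
    c = np.asarray(centroids, dtype=float)
    if c.shape[0] < 4:
        raise ValueError("need at least 4 regions for spin permutations")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_spins, c.shape[0]), dtype=int)
    for s in range(n_spins):
        rot = c @ _random_rotation(rng).T
        _, col = linear_sum_assignment(cdist(c, rot))
        perms[s] = col
    return perms


def spin_correlation(map_a, map_b, centroids, method: str = "pearson",
                     n_spins: int = 5000, seed: int = 0) -> SpatialCorrelationResult:
    """Correlation of two regional maps with a spin-permutation p-value.

    The null rotates ``map_a`` over the sphere; p_spin = (1 + #{|r_null| >=
    |r_obs|}) / (n_spins + 1), two-sided.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size:
        raise ValueError("maps must have equal length")
    if n_spins < 100:
        raise ValueError("n_spins must be at least 100")
    if method == "pearson":
        corr = lambda u, v: np.corrcoef(u, v)[0, 1]
    elif method == "spearman":
        corr = lambda u, v: stats.spearmanr(u, v).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    r_obs = corr(a, b)
    perms = spin_permutations(centroids, n_spins, seed=seed)
    r_null = np.array([corr(a[p], b) for p in perms])
    p = (1 + np.sum(np.abs(r_null) >= np.abs(r_obs))) / (n_spins + 1)
    return SpatialCorrelationResult(r=float(r_obs), p_spin=float(p),
                                    n_spins=n_spins, method=method)


def overlap_reference(scores: pd.DataFrame, reference, x: pd.DataFrame, y,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Intersect significant PLS1 genes with a reference panel.

    For each overlapping gene the Pearson correlation between its regional
    expression profile and the map ``y`` is reported with BH-FDR across the
    overlap.  Reference entries are deduplicated; entries absent from the
    expression matrix are ignored (they cannot be scored).
    """
    ref = list(dict.fromkeys(reference))
    if not ref:
        raise ValueError("empty reference gene list")
    sig = scores.index[scores["cls"] != "ns"]
    overlap = [g for g in ref if g in sig and g in x.columns]
    yv = np.asarray(y, dtype=float)
    rows = []
    for g in overlap:
        r, p = stats.pearsonr(x[g].to_numpy(dtype=float), yv)
        rows.append({"gene": g, "cls": scores.loc[g, "cls"],
                     "z": scores.loc[g, "z"], "r": r, "p": p})
    tab = pd.DataFrame(rows, columns=["gene", "cls", "z", "r", "p"])
    if len(tab):
        tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
        tab["significant"] = tab["p_fdr"] < alpha
    else:
        tab["p_fdr"] = []
        tab["significant"] = []
    return tab.set_index("gene")
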