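"""Morphometric INverse Divergence (MIND) similarity networks.

Each cortical region contributes a cloud of vertices, every vertex carrying
five morphometric features (gray matter volume, surface area, cortical
thickness, sulcal depth, mean curvature).  The similarity between two regions
is defined from the symmetrized Kullback-Leibler divergence between their
multivariate feature distributions::

    s_ij = 1 / (1 + KLsym_ij)          with  KLsym = (KL(a||b) + KL(b||a)) / 2

which maps divergences in [0, inf) onto similarities in (0, 1].  Two
estimators of the divergence are provided: a closed form under a Gaussian
model of each region's feature cloud, and a nonparametric k-nearest-neighbour
estimator (Wang-Kulkarni-Verdu) operating directly on the vertex samples.
The Gaussian form is exact for Gaussian clouds and serves as the fast default
oracle; the k-NN form is consistent for arbitrary distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

FEATURE_NAMES = ("vol", "area", "thick", "sulc", "curv")

__all__ = [
    "FeatureSummary",
    "MINDMatrix",
    "zscore_features",
    "kl_gaussian",
    "kl_knn",
    "mind_matrix",
    "regional_strength",
    "network_strength",
]


@dataclass
class FeatureSummary:
    """Gaussian moment summary of one region's vertex feature cloud."""

    mean: np.ndarray          # (d,)
    cov: np.ndarray           # (d, d) symmetric PSD
    count: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.count < 6:
            raise ValueError("need at least 6 vertices per region")


@dataclass
class MINDMatrix:
    """Symmetric region x region similarity matrix for one subject.

    The diagonal (self-similarity) is stored as NaN and is excluded from
    every strength summary.
    """

    values: np.ndarray
    subject_id: str = ""
    estimator: str = "gaussian"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], atol=1e-10):
            raise ValueError("MIND matrix must be symmetric")
        if np.nanmin(v[off]) < 0 or np.nanmax(v[off]) > 1:
            raise ValueError("off-diagonal similarities must lie in [0, 1]")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def zscore_features(features: np.ndarray) -> np.ndarray:
    """Standardize each feature channel within a subject.

    ``features`` is (region, vertex, feature) for one subject, or
    (subject, region, vertex, feature) for a stack; channels are z-scored
    across all vertices of all regions, per subject, so that features
    measured on incommensurate scales contribute comparably to divergences.
    """
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    single = x.ndim == 3
    if single:
        x = x[None]
    flat = x.reshape(x.shape[0], -1, x.shape[-1])
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    zero = sd[..., 0, :] <= 1e-10 * (np.abs(mu[..., 0, :]) + 1.0)
    if np.any(zero):
        bad = [FEATURE_NAMES[j] if j < len(FEATURE_NAMES) else str(j)
               for j in np.unique(np.where(zero)[1])]
        raise ValueError(f"zero-variance feature channel(s): {', '.join(bad)}")
    out = ((flat - mu) / sd).reshape(x.shape)
    return out[0] if single else out


def _regularize(cov: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    d = cov.shape[-1]
    scale = np.trace(cov) / d if cov.ndim == 2 else None
    if cov.ndim == 2:
        return cov + ridge * max(scale, 1e-12) * np.eye(d)
    tr = np.einsum("...ii->...", cov) / d
    return cov + ridge * np.clip(tr, 1e-12, None)[..., None, None] * np.eye(d)


def kl_gaussian(a: FeatureSummary, b: FeatureSummary) -> float:
    """Symmetrized KL divergence between two Gaussian summaries (nats)."""
    d = a.mean.size
    ca = _regularize(a.cov)
    cb = _regularize(b.cov)
    try:
        ia = np.linalg.inv(ca)
        ib = np.linalg.inv(cb)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge guards this
        raise ValueError("singular covariance after regularization") from exc
    dm = a.mean - b.mean
    kl_ab = 0.5 * (np.trace(ib @ ca) + dm @ ib @ dm - d
                   + np.linalg.slogdet(cb)[1] - np.linalg.slogdet(ca)[1])
    kl_ba = 0.5 * (np.trace(ia @ cb) + dm @ ia @ dm - d
                   + np.linalg.slogdet(ca)[1] - np.linalg.slogdet(cb)[1])
    return max(0.5 * (kl_ab + kl_ba), 0.0)


def _knn_radii(tree: cKDTree, query: np.ndarray, k: int, in_sample: bool) -> np.ndarray:
    kk = k + 1 if in_sample else k
    dist, _ = tree.query(query, k=kk, workers=-1)
    dist = np.atleast_2d(dist)
    return dist[:, -1]


def kl_knn(samples_a: np.ndarray, samples_b: np.ndarray, k: int = 5,
           rng: np.random.Generator | None = None) -> float:
    """Symmetrized k-NN (Wang-Kulkarni-Verdu) KL divergence estimate.

    Each direction uses  D(P||Q) ~ (d/n) * sum_i log(nu_k(i) / rho_k(i))
    + log(m / (n - 1)), where rho_k is the k-th neighbour distance within
    the sample and nu_k the k-th neighbour distance in the other sample.
    Directions are clipped at zero before averaging.  Coincident points
    (zero distances) are broken by a seeded jitter at 1e-9 scale.
    """
    xa = np.atleast_2d(np.asarray(samples_a, dtype=float))
    xb = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if xa.ndim == 2 and xa.shape[1] != xb.shape[1]:
        raise ValueError("sample dimensionalities differ")
    n, m = xa.shape[0], xb.shape[0]
    if k >= min(n, m):
        raise ValueError(f"k={k} must be smaller than both sample sizes ({n}, {m})")

    def one_direction(x, y):
        tx, ty = cKDTree(x), cKDTree(y)
        rho = _knn_radii(tx, x, k, in_sample=True)
        nu = _knn_radii(ty, x, k, in_sample=False)
        if np.any(rho == 0) or np.any(nu == 0):
            jrng = rng if rng is not None else np.random.default_rng(0)
            x = x + jrng.uniform(-1e-9, 1e-9, size=x.shape)
            y = y + jrng.uniform(-1e-9, 1e-9, size=y.shape)
            tx, ty = cKDTree(x), cKDTree(y)
            rho = _knn_radii(tx, x, k, in_sample=True)
            nu = _knn_radii(ty, x, k, in_sample=False)
        d = x.shape[1]
        est = d * np.mean(np.log(nu / rho)) + np.log(len(y) / (len(x) - 1))
        return max(est, 0.0)

    return 0.5 * (one_direction(xa, xb) + one_direction(xb, xa))


def summarize_regions(features: np.ndarray) -> list[FeatureSummary]:
    """Per-region Gaussian moment summaries of a (region, vertex, feature) array."""
    x = np.asarray(features, dtype=float)
    return [FeatureSummary(mean=x[r].mean(axis=0),
                           cov=np.cov(x[r].T, bias=False),
                           count=x[r].shape[0])
            for r in range(x.shape[0])]


def _pairwise_kl_gaussian(features: np.ndarray) -> np.ndarray:
    """Vectorized symmetrized Gaussian KL over all region pairs."""
    x = np.asarray(features, dtype=float)
    R, n, d = x.shape
    mu = x.mean(axis=1)                                     # (R, d)
    xc = x - mu[:, None, :]
    cov = np.einsum("rni,rnj->rij", xc, xc) / (n - 1)       # (R, d, d)
    cov = _regularize(cov)
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    # tr(inv_j cov_i) for all pairs
    tr = np.einsum("jab,iba->ij", inv, cov)                 # [j, i] = tr(inv_j @ cov_i)
    dm = mu[:, None, :] - mu[None, :, :]                    # (i, j, d)
    mah = np.einsum("ijd,jde,ije->ij", dm, inv, dm)         # (mu_i-mu_j)' inv_j (mu_i-mu_j)
    kl = 0.5 * (tr.T + mah - d + logdet[None, :] - logdet[:, None])  # KL(i||j)
    sym = 0.5 * (kl + kl.T)
    np.fill_diagonal(sym, 0.0)
    return np.clip(sym, 0.0, None)


def mind_matrix(features: np.ndarray, estimator: str = "gaussian", k: int = 5,
                subject_id: str = "", standardize: bool = True) -> MINDMatrix:
    """Build one subject's MIND similarity matrix.

    Parameters
    ----------
    features : (region, vertex, feature) array of one subject's vertex data.
    estimator : ``gaussian`` (closed form on region moments) or ``knn``.
    k : neighbour order for the k-NN estimator.
    standardize : z-score feature channels within the subject first.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected a (region, vertex, feature) array")
    if standardize:
        x = zscore_features(x)
    R = x.shape[0]
    if estimator == "gaussian":
        kl = _pairwise_kl_gaussian(x)
    elif estimator == "knn":
        kl = np.zeros((R, R))
        for i in range(R):
            for j in range(i + 1, R):
                try:
                    kl[i, j] = kl[j, i] = kl_knn(x[i], x[j], k=k)
                except ValueError as exc:
                    raise ValueError(f"region pair ({i}, {j}): {exc}") from exc
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    sim = 1.0 / (1.0 + kl)
    np.fill_diagonal(sim, np.nan)
    return MINDMatrix(values=sim, subject_id=subject_id, estimator=estimator)


def regional_strength(m: MINDMatrix) -> np.ndarray:
    """Per-region mean similarity with the other R-1 regions (no threshold)."""
    return np.nanmean(m.values, axis=1)


def network_strength(strengths: pd.DataFrame, region_meta: pd.DataFrame) -> pd.DataFrame:
    """Aggregate subject x region strengths to subject x network means.

    ``strengths`` columns are region ids; ``region_meta`` must map every
    region id (column ``region_id``) to a ``network`` label.
    """
    meta = region_meta.set_index("region_id")["network"]
    missing = [c for c in strengths.columns if c not in meta.index]
    if missing:
        raise ValueError(f"regions without a network mapping: {missing[:5]}")
    nets = meta.loc[strengths.columns]
    return strengths.T.groupby(nets.values).mean().T


def matrix_to_frame(m: MINDMatrix, region_ids) -> pd.DataFrame:
    return pd.DataFrame(m.values, index=region_ids, columns=region_ids)
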