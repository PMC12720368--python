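"""Semi-supervised convex-polytope max-margin subtyping (HYDRA-style).

Patients are separated from controls by K linear max-margin hyperplanes
that together form a convex polytope: each patient is assigned to the
hyperplane giving it the largest margin, and each hyperplane is refit as a
soft-margin classifier between all controls (label -1) and its assigned
patients (label +1).  Clusters are therefore defined by *direction of
deviation from controls* rather than by proximity among patients.  Model
order K is selected by cross-validated clustering agreement (adjusted Rand
index between fold-trained assignments), and run-to-run variability is
absorbed by consensus clustering over random initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn import metrics as _skmetrics
from sklearn.svm import LinearSVC

__all__ = [
    "HydraConfig",
    "SubtypeSolution",
    "adjusted_rand_index",
    "fit_polytope",
    "consensus_cluster",
    "select_k",
    "fit_subtypes",
    "split_half_validate",
]


@dataclass
class HydraConfig:
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8, 9, 10)
    c_reg: float = 0.25          # soft-margin regularization C
    n_iter: int = 50             # alternation iterations
    n_consensus: int = 20        # random initializations per consensus fit
    n_folds: int = 10
    standardize: bool = True     # z-score each regional feature across subjects
    seed: int = 0

    def __post_init__(self):
        ks = tuple(int(k) for k in self.k_range)
        if not ks or min(ks) < 1 or max(ks) > 10:
            raise ValueError("k_range must lie within [1, 10]")
        self.k_range = ks
        if self.c_reg <= 0:
            raise ValueError("c_reg must be positive")


@dataclass
class SubtypeSolution:
    labels: np.ndarray               # per-patient cluster in 1..K
    hyperplanes: tuple               # (weights (K, p), offsets (K,))
    co_assignment: np.ndarray        # patient x patient consensus frequency
    cv_ari_by_k: dict                # K -> mean pairwise cross-fold ARI
    chosen_k: int

    def __post_init__(self):
        c = self.co_assignment
        if c.size and (not np.allclose(c, c.T) or c.min() < 0 or c.max() > 1):
            raise ValueError("co-assignment must be symmetric with entries in [0,1]")


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(_skmetrics.adjusted_rand_score(a, b))


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _fit_hyperplane(x_ctrl, x_pat, c_reg, seed):
    x = np.vstack([x_ctrl, x_pat])
    y = np.concatenate([-np.ones(len(x_ctrl)), np.ones(len(x_pat))])
    clf = LinearSVC(C=c_reg, random_state=seed, max_iter=5000, tol=1e-4)
    clf.fit(x, y)
    return clf.coef_[0], float(clf.intercept_[0])


def fit_polytope(x: np.ndarray, y: np.ndarray, k: int, cfg: HydraConfig,
                 init_seed: int = 0):
    """One alternating-minimization run at fixed K.

    Returns per-patient labels in 1..K and the (weights, offsets) of the K
    hyperplanes.  Controls never receive cluster labels.  If a hyperplane
    loses all its patients it is reseeded from the patients with the
    smallest current margins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("y must contain both classes coded -1 / +1")
    if cfg.standardize:
        x = _standardize(x)
    ctrl = x[y == -1]
    pat = x[y == 1]
    n_pat = len(pat)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(init_seed)
    # initialize from K directionally diverse seeds: each anchor is a random
    # patient's deviation from the control centroid, and patients join the
    # best-aligned anchor; a random partition would start all hyperplanes
    # at the same average direction and stall in a degenerate optimum
    anchors = pat[rng.choice(n_pat, size=k, replace=k > n_pat)] - ctrl.mean(axis=0)
    norms = np.linalg.norm(anchors, axis=1)
    anchors /= np.where(norms == 0, 1.0, norms)[:, None]
    assign = np.argmax((pat - ctrl.mean(axis=0)) @ anchors.T, axis=1)

    weights = np.zeros((k, x.shape[1]))
    offsets = np.zeros(k)
    for it in range(cfg.n_iter):
        for j in range(k):
            members = np.where(assign == j)[0]
            if members.size == 0:
                # reseed from worst-classified patients under current planes
                nrm = np.linalg.norm(weights, axis=1)
                nrm[nrm == 0] = 1.0
                margins = ((pat @ weights.T + offsets) / nrm).max(axis=1)
                members = np.argsort(margins)[:max(1, n_pat // (2 * k))]
                assign[members] = j
            weights[j], offsets[j] = _fit_hyperplane(
                ctrl, pat[members], cfg.c_reg, seed=init_seed)
        norms = np.linalg.norm(weights, axis=1)
        norms[norms == 0] = 1.0
        new_assign = np.argmax((pat @ weights.T + offsets) / norms, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return assign + 1, (weights, offsets)


def consensus_cluster(runs, k: int | None = None):
    """Combine label vectors from repeated runs into a consensus partition.

    ``co_assignment[i, j]`` is the fraction of runs in which patients i and
    j share a cluster; the final K-way partition cuts an average-linkage
    tree built on 1 - co_assignment.
    """
    runs = [np.asarray(r) for r in runs]
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    n = runs[0].size
    if any(r.size != n for r in runs):
        raise ValueError("runs must cover the identical patient set")
    co = np.zeros((n, n))
    for r in runs:
        co += (r[:, None] == r[None, :]).astype(float)
    co /= len(runs)
    if k is None:
        k = max(len(np.unique(r)) for r in runs)
    if n == 1 or k == 1:
        return np.ones(n, dtype=int), co
    dist = squareform(1.0 - co, checks=False)
    z = linkage(dist, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return labels, co


def assign_to_polytope(x: np.ndarray, hyperplanes) -> np.ndarray:
    """Nearest-polytope-face rule: argmax geometric margin over K hyperplanes."""
    weights, offsets = hyperplanes
    norms = np.linalg.norm(weights, axis=1)
    norms[norms == 0] = 1.0
    return np.argmax((x @ weights.T + offsets) / norms, axis=1) + 1


def _consensus_fit(x, y, k, cfg, seed):
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_consensus)
    runs = [fit_polytope(x, y, k, cfg, init_seed=s)[0] for s in seeds]
    labels, co = consensus_cluster(runs, k=k)
    # refit hyperplanes once against the consensus partition
    xs = _standardize(np.asarray(x, dtype=float)) if cfg.standardize else np.asarray(x, float)
    ctrl, pat = xs[y == -1], xs[y == 1]
    weights = np.zeros((k, xs.shape[1]))
    offsets = np.zeros(k)
    for j in range(k):
        members = np.where(labels == j + 1)[0]
        if members.size == 0:
            continue
        weights[j], offsets[j] = _fit_hyperplane(ctrl, pat[members], cfg.c_reg, int(seeds[0]))
    return labels, co, (weights, offsets)


def select_k(x: np.ndarray, y: np.ndarray, cfg: HydraConfig):
    """Cross-validated model-order selection.

    For each K, the polytope is fit (with consensus) on each fold's training
    patients plus all controls; every fold-trained model then assigns *all*
    patients by the nearest-polytope rule, and the criterion is the mean
    adjusted Rand index over all fold pairs.  Returns (cv_ari_by_k, chosen_k).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    pat_idx = np.where(y == 1)[0]
    n_pat = pat_idx.size
    if n_pat < cfg.n_folds:
        raise ValueError("fewer patients than folds")
    rng = np.random.default_rng(cfg.seed)
    fold_of = np.repeat(np.arange(cfg.n_folds), -(-n_pat // cfg.n_folds))[:n_pat]
    fold_of = rng.permutation(fold_of)
    xs = _standardize(x) if cfg.standardize else x
    x_pat = xs[pat_idx]

    cv_ari = {}
    for k in cfg.k_range:
        labelings = []
        for f in range(cfg.n_folds):
            keep = np.concatenate([np.where(y == -1)[0], pat_idx[fold_of != f]])
            sub_cfg = HydraConfig(**{**vars(cfg), "k_range": (k,), "standardize": False})
            _, _, planes = _consensus_fit(xs[keep], y[keep], k, sub_cfg,
                                          seed=cfg.seed * 1000 + k * 100 + f)
            labelings.append(assign_to_polytope(x_pat, planes))
        aris = [adjusted_rand_index(labelings[i], labelings[j])
                for i in range(len(labelings)) for j in range(i + 1, len(labelings))]
        cv_ari[k] = float(np.mean(aris)) if aris else 1.0
    chosen = max(cv_ari, key=cv_ari.get)
    return cv_ari, chosen


def fit_subtypes(x: np.ndarray, y: np.ndarray, cfg: HydraConfig,
                 select: bool = True) -> SubtypeSolution:
    """Full subtyping: (optional) K selection, then consensus fit at chosen K."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if select and len(cfg.k_range) > 1:
        cv_ari, chosen = select_k(x, y, cfg)
    else:
        chosen = cfg.k_range[0]
        cv_ari = {chosen: 1.0}
    labels, co, planes = _consensus_fit(x, y, chosen, cfg, seed=cfg.seed)
    return SubtypeSolution(labels=labels, hyperplanes=planes, co_assignment=co,
                           cv_ari_by_k=cv_ari, chosen_k=chosen)


def split_half_validate(strengths: np.ndarray, y: np.ndarray,
                        covariates, centroids: np.ndarray,
                        cfg: HydraConfig, k: int = 2, seed: int = 0,
                        n_spins: int = 199):
    """Split-subset reproducibility of subtype alteration maps.

    Controls and patients are each split into random disjoint halves; the
    subtyping + covariate-adjusted case-control t-map pipeline runs per
    half; subtypes are matched across halves by the sign of their global
    strength change versus controls, and matched t-maps are compared by
    spatial correlation with a spin-permutation p-value.
    """
    from .casecontrol import adjust_covariates, group_ttest
    from .pls import spin_correlation

    strengths = np.asarray(strengths, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    halves = []
    for grp in (-1, 1):
        idx = np.where(y == grp)[0]
        if idx.size < 2 * cfg.n_folds and grp == 1:
            raise ValueError("too few patients for split-half folds")
        perm = rng.permutation(idx)
        halves.append((perm[: idx.size // 2], perm[idx.size // 2:]))
    cfg_k = HydraConfig(**{**vars(cfg), "k_range": (k,)})
    results = []
    for h in range(2):
        sel = np.concatenate([halves[0][h], halves[1][h]])
        sol = fit_subtypes(strengths[sel], y[sel], cfg_k, select=False)
        adj, _ = adjust_covariates(strengths[sel], covariates.iloc[sel])
        y_h = y[sel]
        tmaps = {}
        deltas = {}
        for c in np.unique(sol.labels):
            in_c = np.zeros(len(sel), dtype=bool)
            in_c[np.where(y_h == 1)[0][sol.labels == c]] = True
            tm = group_ttest(adj, np.where(in_c, 1, np.where(y_h == -1, -1, 0)))
            tmaps[c] = tm.t
            deltas[c] = adj[in_c].mean() - adj[y_h == -1].mean()
        results.append((sol, tmaps, deltas))
    # match clusters across halves by sign/size of global strength change
    order0 = sorted(results[0][2], key=results[0][2].get)
    order1 = sorted(results[1][2], key=results[1][2].get)
    correlations = []
    for c0, c1 in zip(order0, order1):
        res = spin_correlation(results[0][1][c0], results[1][1][c1],
                               centroids, n_spins=n_spins, seed=seed)
        correlations.append(res)
    return results[0][0], results[1][0], correlations
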