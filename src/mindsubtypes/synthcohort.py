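"""Synthetic cohorts with planted subtype structure and known ground truth.

The generator emulates the inputs of a cortical morphometry case-control
study: healthy controls plus two patient subtypes with opposite-signed
alterations of inter-regional similarity, subject covariates (age, sex,
total intracranial volume) with configurable effects, region geometry on the
unit sphere with hemispheres and a seven-level network partition, a
region x gene expression matrix with a planted subset of genes spatially
coupled to a target map, and cell-type gene sets with planted overlap.

Every vertex feature cloud is drawn from a 5-D Gaussian whose mean and
covariance vary smoothly over the cortical sheet (a low-rank basis in the
centroid coordinates), so similarity matrices inherit realistic spatial
structure.  Subtype 1 distorts the feature covariance of its planted
regions (inflating some directions, compressing others), which increases
their divergence from everywhere else and lowers their similarity
strength; subtype 2 shrinks its planted regions' moments
toward the cortical average, which lowers divergence and raises strength.
Both act on the full distribution rather than on feature means, matching
the distributional definition of the similarity measure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "CohortBundle",
    "SyntheticExpression",
    "make_region_table",
    "generate_cohort",
    "generate_expression",
    "generate_gene_sets",
    "write_bundle",
]

N_FEATURES = 5
CELL_TYPE_NAMES = (
    "astrocytes", "endothelial", "microglia", "excitatory",
    "inhibitory", "oligodendrocytes", "OPCs",
)

# Reference cohort group summaries the covariate sampler emulates:
# age mean/sd, male fraction, MoCA, and patient clinical scores.
_GROUP_STATS = {
    0: dict(age=(58.03, 6.03), male=44 / 101, moca=(25.42, 1.93)),
    1: dict(age=(57.91, 8.77), male=27 / 67, moca=(21.22, 5.46),
            duration=(7.82, 3.66), hy=(2.60, 0.81), updrs=(36.91, 19.40),
            ledd=(725.06, 233.24)),
    2: dict(age=(58.92, 7.80), male=29 / 60, moca=(21.62, 5.17),
            duration=(8.38, 3.66), hy=(2.30, 0.73), updrs=(29.20, 17.20),
            ledd=(685.43, 192.70)),
}


@dataclass
class CohortConfig:
    """Ground-truth parameters of a synthetic cohort."""

    n_hc: int = 101
    n_sub1: int = 67
    n_sub2: int = 60
    n_regions: int = 308
    n_vertices: int = 120
    effect_sub1: float = 0.8      # covariance inflation -> lower similarity
    effect_sub2: float = 0.8      # homogenization -> higher similarity
    affected_frac: float = 0.2    # fraction of regions planted per subtype
    beta_age: float = 0.1         # covariate effects on regional feature means
    beta_sex: float = 0.1
    beta_tiv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hc, self.n_sub1, self.n_sub2) < 2:
            raise ValueError("all group counts must be >= 2")
        if self.n_regions < 2 or self.n_vertices < 6:
            raise ValueError("need >= 2 regions and >= 6 vertices per region")
        if not 0 < self.affected_frac < 1:
            raise ValueError("affected_frac must lie in (0, 1)")
        n_aff = max(1, round(self.affected_frac * self.n_regions))
        if 2 * n_aff > self.n_regions:
            raise ValueError(
                "affected_frac too large: the two planted region sets would overlap")
        if self.effect_sub1 < 0 or self.effect_sub2 < 0:
            raise ValueError("effect sizes must be non-negative")


@dataclass
class CohortBundle:
    """A generated cohort: features, covariates, truth labels, geometry."""

    features: np.ndarray            # (subject, region, vertex, feature)
    covariates: pd.DataFrame        # subject_id, age, sex, tiv, diagnosis, scores
    true_subtype: np.ndarray        # 0 = HC, 1, 2
    region_meta: pd.DataFrame       # region_id, hemisphere, network, x, y, z
    planted_regions: dict           # {1: array of region ids, 2: ...}
    config: CohortConfig

    def __post_init__(self):
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature array must be finite")
        diag = self.covariates["diagnosis"].to_numpy()
        if not set(np.unique(diag)) <= {-1, 1}:
            raise ValueError("diagnosis must be coded -1 (HC) / +1 (patient)")
        if not np.array_equal(self.true_subtype == 0, diag == -1):
            raise ValueError("true_subtype 0 must coincide with diagnosis -1")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def left_region_ids(self) -> np.ndarray:
        m = self.region_meta
        return m.loc[m["hemisphere"] == "L", "region_id"].to_numpy()


@dataclass
class SyntheticExpression:
    """Left-region x gene matrix with a planted spatially-coupled gene subset."""

    expression: pd.DataFrame        # rows = left region ids, cols = gene symbols
    planted_gene_ids: list
    planted_map: np.ndarray
    coupling: float


def make_region_table(n_regions: int, rng: np.random.Generator) -> pd.DataFrame:
    """Region metadata: mirrored unit-sphere centroids, hemisphere, 7 networks.

    Right-hemisphere centroids are mirror images (x -> -x) of left ones, and
    the network partition splits each hemisphere into seven contiguous
    azimuthal sectors of near-equal size, so all seven levels are occupied
    in both hemispheres.
    """
    n_left = n_regions - n_regions // 2
    n_right = n_regions // 2
    pts = rng.standard_normal((n_left, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts[:, 0] = -np.abs(pts[:, 0])          # left hemisphere: x < 0
    mirrored = pts[:n_right].copy()
    mirrored[:, 0] *= -1
    xyz = np.vstack([pts, mirrored])
    hemi = np.array(["L"] * n_left + ["R"] * n_right)

    networks = np.empty(n_regions, dtype=int)
    for h in ("L", "R"):
        idx = np.where(hemi == h)[0]
        az = np.arctan2(xyz[idx, 2], xyz[idx, 1])
        order = np.argsort(az, kind="stable")
        nets = (np.arange(idx.size) * 7) // idx.size
        networks[idx[order]] = nets

    return pd.DataFrame({
        "region_id": np.arange(1, n_regions + 1),
        "hemisphere": hemi,
        "network": [f"net{n + 1}" for n in networks],
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    })


def _anatomy(xyz: np.ndarray, rng: np.random.Generator):
    """Smooth per-region Gaussian moments: mean field + SPD covariance field."""
    R = xyz.shape[0]
    basis = np.column_stack([np.ones(R), xyz])                  # (R, 4)
    M = rng.standard_normal((4, N_FEATURES)) * np.array([0.0, 1.2, 1.2, 1.2])[:, None]
    means = basis @ M                                           # (R, 5)
    A0 = rng.standard_normal((N_FEATURES, N_FEATURES)) * 0.4
    A_mod = rng.standard_normal((3, N_FEATURES, N_FEATURES)) * 0.15
    A = A0[None] + np.einsum("rc,cij->rij", xyz, A_mod)         # (R, 5, 5)
    covs = np.einsum("rij,rkj->rik", A, A) + 0.5 * np.eye(N_FEATURES)
    return means, covs


def _covariate_frame(groups: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = groups.size
    rows = {
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "age": np.empty(n), "sex": np.empty(n, dtype=int), "tiv": np.empty(n),
        "diagnosis": np.where(groups == 0, -1, 1),
        "updrs_iii": np.full(n, np.nan), "hy": np.full(n, np.nan),
        "moca": np.full(n, np.nan), "ledd": np.full(n, np.nan),
        "duration": np.full(n, np.nan),
    }
    for i, g in enumerate(groups):
        st = _GROUP_STATS[g]
        rows["age"][i] = rng.normal(*st["age"])
        rows["sex"][i] = int(rng.random() < st["male"])
        rows["tiv"][i] = np.exp(rng.normal(np.log(1.5e6), 0.08))
        rows["moca"][i] = np.clip(rng.normal(*st["moca"]), 0, 30)
        if g != 0:
            rows["duration"][i] = max(rng.normal(*st["duration"]), 0.5)
            rows["hy"][i] = np.clip(rng.normal(*st["hy"]), 1, 5)
            rows["updrs_iii"][i] = max(rng.normal(*st["updrs"]), 0.0)
            rows["ledd"][i] = max(rng.normal(*st["ledd"]), 0.0)
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a full synthetic cohort with planted subtype effects.

    Identical configs (including seed) reproduce bit-identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    R, V = config.n_regions, config.n_vertices
    region_meta = make_region_table(R, rng)
    xyz = region_meta[["x", "y", "z"]].to_numpy()
    means, covs = _anatomy(xyz, rng)
    mean_bar = means.mean(axis=0)
    cov_bar = covs.mean(axis=0)

    n_aff = max(1, round(config.affected_frac * R))
    pick = rng.permutation(R)
    planted = {1: np.sort(pick[:n_aff]) + 1, 2: np.sort(pick[n_aff:2 * n_aff]) + 1}

    groups = np.concatenate([
        np.zeros(config.n_hc, dtype=int),
        np.ones(config.n_sub1, dtype=int),
        np.full(config.n_sub2, 2, dtype=int),
    ])
    cov_frame = _covariate_frame(groups, rng)
    z_age = (cov_frame["age"] - 58.0) / 7.0
    sex_c = cov_frame["sex"] - 0.5
    z_tiv = (np.log(cov_frame["tiv"]) - np.log(1.5e6)) / 0.08

    # covariate effects enter as a smooth region pattern times a fixed
    # feature-space direction, so they perturb inter-regional divergences
    u = rng.standard_normal(N_FEATURES)
    u /= np.linalg.norm(u)
    pattern = xyz[:, 1]                                     # smooth over cortex
    cov_shift = (config.beta_age * z_age + config.beta_sex * sex_c
                 + config.beta_tiv * z_tiv).to_numpy()      # (n,)

    w2 = config.effect_sub2 / (1.0 + config.effect_sub2)    # homogenization weight
    chol = np.linalg.cholesky(covs)                         # (R, 5, 5)
    # subtype 1: anisotropic covariance distortion D Sigma D (inflate some
    # feature directions, compress others); raises divergence to every other
    # region regardless of how large the inter-regional mean separation is
    signs = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
    D1 = np.diag(np.exp(0.5 * config.effect_sub1 * signs))
    chol1 = D1[None] @ chol
    means2 = (1 - w2) * means + w2 * mean_bar
    chol2 = np.linalg.cholesky((1 - w2) * covs + w2 * cov_bar)

    feats = np.empty((groups.size, R, V, N_FEATURES))
    aff1 = planted[1] - 1
    aff2 = planted[2] - 1
    for i, g in enumerate(groups):
        mu_i = means + cov_shift[i] * pattern[:, None] * u[None, :]
        L_i = np.broadcast_to(chol, (R, N_FEATURES, N_FEATURES)).copy()
        if g == 1:
            L_i[aff1] = chol1[aff1]
        elif g == 2:
            mu_i = mu_i.copy()
            mu_i[aff2] = means2[aff2] + cov_shift[i] * pattern[aff2, None] * u[None, :]
            L_i[aff2] = chol2[aff2]
        z = rng.standard_normal((R, V, N_FEATURES))
        feats[i] = mu_i[:, None, :] + np.einsum("rvj,rij->rvi", z, L_i)

    return CohortBundle(features=feats, covariates=cov_frame,
                        true_subtype=groups, region_meta=region_meta,
                        planted_regions=planted, config=config)


def generate_expression(region_meta: pd.DataFrame, n_genes: int, n_planted: int,
                        planted_map: np.ndarray, coupling: float,
                        seed: int = 0) -> SyntheticExpression:
    """Left-hemisphere region x gene matrix with planted spatial coupling.

    Planted gene columns are ``coupling * standardized(planted_map)
    + sqrt(1 - coupling^2) * noise``; the rest are pure standard noise.
    """
    if not 0 <= coupling < 1:
        raise ValueError("coupling must lie in [0, 1)")
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    left = region_meta.loc[region_meta["hemisphere"] == "L", "region_id"].to_numpy()
    pm = np.asarray(planted_map, dtype=float)
    if pm.size != left.size:
        raise ValueError(
            f"planted_map length {pm.size} != number of left regions {left.size}")
    if pm.std() == 0:
        raise ValueError("planted_map must not be constant")
    rng = np.random.default_rng(seed)
    target = (pm - pm.mean()) / pm.std()
    x = rng.standard_normal((left.size, n_genes))
    if n_planted:
        # orthogonalize the noise part against the target so the sample
        # correlation of each planted column equals the coupling exactly
        noise = x[:, :n_planted] - x[:, :n_planted].mean(axis=0)
        noise -= target[:, None] * (target @ noise) / (target @ target)
        sd = noise.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        x[:, :n_planted] = (coupling * target[:, None]
                            + np.sqrt(1.0 - coupling ** 2) * noise / sd)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    expr = pd.DataFrame(x, index=pd.Index(left, name="region_id"), columns=genes)
    planted = genes[:n_planted]
    if coupling > 0 and n_planted:
        r = np.array([np.corrcoef(expr[g], target)[0, 1] for g in planted])
        if np.any(r < coupling - 0.15):
            raise RuntimeError("planted coupling construction check failed")
    return SyntheticExpression(expression=expr, planted_gene_ids=planted,
                               planted_map=pm, coupling=coupling)


def generate_gene_sets(all_genes, n_sets: int = 7, set_size: int = 50,
                       planted_overlap: dict | None = None,
                       seed: int = 0) -> dict[str, list]:
    """Named gene sets (cell-type style) with guaranteed planted members."""
    genes = list(all_genes)
    if set_size > len(genes):
        raise ValueError("set_size exceeds the gene universe")
    planted_overlap = planted_overlap or {}
    names = list(CELL_TYPE_NAMES[:n_sets]) if n_sets <= 7 else (
        list(CELL_TYPE_NAMES) + [f"set{i}" for i in range(8, n_sets + 1)])
    for name, members in planted_overlap.items():
        if name not in names:
            raise ValueError(f"unknown set name {name!r}")
        absent = set(members) - set(genes)
        if absent:
            raise ValueError(f"planted genes absent from universe: {sorted(absent)[:5]}")
        if len(members) > set_size:
            raise ValueError("planted overlap larger than set_size")
    rng = np.random.default_rng(seed)
    sets = {}
    for name in names:
        fixed = list(planted_overlap.get(name, []))
        pool = [g for g in genes if g not in fixed]
        fill = rng.choice(len(pool), size=set_size - len(fixed), replace=False)
        members = fixed + [pool[i] for i in sorted(fill)]
        sets[name] = members
    return sets


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write a bundle as plain-text tables plus a ground-truth record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "subjects").mkdir(exist_ok=True)
    cols = ["vol", "area", "thick", "sulc", "curv"]
    rids = bundle.region_meta["region_id"].to_numpy()
    for i, sid in enumerate(bundle.covariates["subject_id"]):
        R, V, F = bundle.features.shape[1:]
        tab = pd.DataFrame(bundle.features[i].reshape(R * V, F), columns=cols)
        tab.insert(0, "vertex_id", np.tile(np.arange(V), R))
        tab.insert(0, "region_id", np.repeat(rids, V))
        tab.to_csv(out / "subjects" / f"{sid}.tsv", sep="\t", index=False)
    bundle.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    bundle.region_meta.to_csv(out / "regions.tsv", sep="\t", index=False)
    truth = {
        "true_subtype": bundle.true_subtype.tolist(),
        "planted_regions": {str(k): v.tolist() for k, v in bundle.planted_regions.items()},
        "config": {k: getattr(bundle.config, k) for k in vars(bundle.config)},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
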