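"""Probe-level microarray preprocessing to a left-hemisphere region x gene matrix.

A simplified re-implementation of the standard five-step pipeline used for
donor-brain microarray atlases: (i) probes are mapped to gene symbols,
(ii) probes below background in more than half of samples are dropped,
(iii) among multiple probes per gene the one with the highest differential
stability (mean inter-donor Spearman correlation of its regional profile)
is kept, (iv) tissue samples are assigned to regions within a 2 mm
tolerance beyond the region boundary, and (v) expression is normalized
across samples with a scaled robust sigmoid before donor-wise averaging
into regions.  Only the left hemisphere is retained in the final matrix.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_probes",
    "select_probe",
    "select_probes",
    "assign_samples",
    "scaled_robust_sigmoid",
    "build_matrix",
    "preprocess",
]


def filter_probes(probes: pd.DataFrame, above: pd.DataFrame) -> pd.DataFrame:
    """Drop probes below background noise in strictly more than 50% of samples.

    ``probes``: one row per probe with at least probe_id and gene_symbol.
    ``above``: boolean probe x sample table of above-background calls.
    """
    missing = set(probes["probe_id"]) - set(above.index)
    if missing:
        raise ValueError(f"missing background calls for probes: {sorted(missing)[:5]}")
    frac_below = 1.0 - above.loc[probes["probe_id"]].mean(axis=1)
    keep = frac_below.to_numpy() <= 0.5
    return probes.loc[keep].reset_index(drop=True)


def _differential_stability(profiles: dict[str, pd.DataFrame], probe) -> float:
    """Mean Spearman correlation of a probe's regional profile across donor pairs."""
    donors = sorted(profiles)
    cors = []
    for a, b in itertools.combinations(donors, 2):
        common = profiles[a].index.intersection(profiles[b].index)
        if len(common) < 3:
            continue
        r = stats.spearmanr(profiles[a].loc[common, probe],
                            profiles[b].loc[common, probe]).statistic
        if np.isfinite(r):
            cors.append(r)
    return float(np.mean(cors)) if cors else float("-inf")


def select_probe(probe_ids, profiles: dict[str, pd.DataFrame]):
    """Pick the single probe with the highest differential stability.

    ``profiles`` maps donor id to a region x probe expression table.  With a
    single donor (no donor pairs) the fallback criterion is the probe with
    the highest variance across regions.
    """
    probe_ids = list(probe_ids)
    if len(probe_ids) == 1:
        return probe_ids[0]
    if len(profiles) >= 2:
        scores = {p: _differential_stability(profiles, p) for p in probe_ids}
        if any(np.isfinite(s) for s in scores.values()):
            return max(probe_ids, key=lambda p: scores[p])
    donor = next(iter(profiles.values()))
    return max(probe_ids, key=lambda p: float(donor[p].var()))


def select_probes(probes: pd.DataFrame, profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Apply select_probe per gene; single-probe genes pass through."""
    rows = []
    for gene, grp in probes.groupby("gene_symbol", sort=True):
        chosen = select_probe(grp["probe_id"].tolist(), profiles)
        rows.append(grp[grp["probe_id"] == chosen].iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


def assign_samples(samples: pd.DataFrame, regions: pd.DataFrame,
                   region_radius: float, tolerance: float = 2.0) -> pd.Series:
    """Map tissue samples to regions; drop samples too far from any region.

    Regions are modelled as balls of ``region_radius`` (mm) around their
    centroids (columns x, y, z).  A sample inside a ball is assigned to it;
    otherwise it goes to the nearest region if its distance beyond the
    boundary is at most ``tolerance`` mm, else it is dropped.  Returns a
    Series sample_id -> region_id for the retained samples.
    """
    if regions.empty:
        raise ValueError("no regions provided")
    cent = regions[["x", "y", "z"]].to_numpy(dtype=float)
    coords = samples[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(coords[:, None, :] - cent[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    beyond = d.min(axis=1) - region_radius
    keep = beyond <= tolerance
    return pd.Series(regions["region_id"].to_numpy()[nearest[keep]],
                     index=samples.loc[keep, "sample_id"], name="region_id")


def scaled_robust_sigmoid(x) -> np.ndarray:
    """Outlier-robust sigmoid normalization, min-max rescaled to [0, 1].

    y = 1 / (1 + exp(-(x - median) / IQR)), then (y - min) / (max - min).
    Strictly order-preserving.
    """
    x = np.asarray(x, dtype=float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        raise ValueError("zero interquartile range")
    y = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / iqr))
    return (y - y.min()) / (y.max() - y.min())


def build_matrix(expression: pd.DataFrame, sample_meta: pd.DataFrame,
                 assignment: pd.Series, regions: pd.DataFrame,
                 normalize: bool = True) -> pd.DataFrame:
    """Aggregate sample-level expression into a left-hemisphere region x gene matrix.

    ``expression``: sample x gene values (rows indexed by sample_id).
    Per donor, each gene is sigmoid-normalized across that donor's retained
    samples, samples are averaged within region, and donor matrices are then
    averaged.  Regions (left hemisphere) with no samples are dropped.
    """
    left = regions.loc[regions["hemisphere"] == "L", "region_id"]
    meta = sample_meta.set_index("sample_id")
    donor_frames = []
    for donor, sids in meta.groupby("donor_id").groups.items():
        sids = [s for s in sids if s in assignment.index]
        if not sids:
            continue
        ex = expression.loc[sids]
        if normalize:
            ex = ex.apply(lambda col: scaled_robust_sigmoid(col.to_numpy())
                          if col.nunique() > 1 else np.full(len(col), 0.5), axis=0,
                          result_type="broadcast")
        ex = ex.copy()
        ex["region_id"] = assignment.loc[sids].to_numpy()
        donor_frames.append(ex.groupby("region_id").mean())
    if not donor_frames:
        raise ValueError("no assigned samples")
    stacked = pd.concat(donor_frames, keys=range(len(donor_frames)))
    mat = stacked.groupby(level="region_id").mean()
    mat = mat.loc[mat.index.intersection(left)]
    mat.index.name = "region_id"
    return mat


def preprocess(probes: pd.DataFrame, above: pd.DataFrame,
               expression: pd.DataFrame, samples: pd.DataFrame,
               regions: pd.DataFrame, region_radius: float,
               tolerance: float = 2.0):
    """Run the full probe-to-region pipeline; returns (matrix, provenance).

    ``probes``: probe_id, gene_symbol (NaN symbols are unmapped and dropped
    in step i); ``above``: probe x sample above-background calls;
    ``expression``: sample x probe values; ``samples``: sample_id, donor_id,
    x, y, z.  Provenance records the count surviving each step.
    """
    prov = {"n_probes_in": int(len(probes))}
    mapped = probes.dropna(subset=["gene_symbol"]).reset_index(drop=True)
    prov["n_probes_mapped"] = int(len(mapped))

    kept = filter_probes(mapped, above)
    prov["n_probes_above_background"] = int(len(kept))

    assignment = assign_samples(samples, regions, region_radius, tolerance)
    prov["n_samples_in"] = int(len(samples))
    prov["n_samples_assigned"] = int(len(assignment))

    # per-donor regional profiles over retained probes, for probe selection
    meta = samples.set_index("sample_id")
    profiles = {}
    for donor, sids in meta.groupby("donor_id").groups.items():
        sids = [s for s in sids if s in assignment.index]
        if not sids:
            continue
        prof = expression.loc[sids, kept["probe_id"]].copy()
        prof["region_id"] = assignment.loc[sids].to_numpy()
        profiles[donor] = prof.groupby("region_id").mean()
    selected = select_probes(kept, profiles) if profiles else kept
    prov["n_genes"] = int(selected["gene_symbol"].nunique())

    expr_sel = expression.loc[:, selected["probe_id"]]
    expr_sel.columns = selected["gene_symbol"].to_numpy()
    matrix = build_matrix(expr_sel, samples, assignment, regions)
    prov["n_regions_out"] = int(len(matrix))
    return matrix, prov
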