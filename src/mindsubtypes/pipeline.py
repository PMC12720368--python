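"""End-to-end orchestration: simulate -> mind -> subtype -> casecontrol -> pls -> enrich.

Each stage consumes and produces plain-text artifacts (TSV/GMT/JSON) in a
run directory, so any stage can also be run standalone on externally
supplied tables with the same schemas.  A single global seed fans out to
per-stage seeds which are recorded, together with a config hash and
per-stage row counts, in ``manifest.json``; identical config and inputs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import casecontrol, genesets, hydra, mindnet, pls, synthcohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full"]

_STAGES = ("simulate", "mind", "subtype", "casecontrol", "pls", "enrich")


@dataclass
class RunConfig:
    """Serializable parameters of a full synthetic run."""

    seed: int = 0
    # cohort
    n_hc: int = 30
    n_sub1: int = 15
    n_sub2: int = 15
    n_regions: int = 40
    n_vertices: int = 120
    effect_sub1: float = 0.8
    effect_sub2: float = 0.8
    affected_frac: float = 0.2
    # mind
    estimator: str = "gaussian"
    knn_k: int = 5
    # hydra
    k_range: tuple = (2, 3, 4)
    c_reg: float = 0.25
    n_iter: int = 50
    n_consensus: int = 20
    n_folds: int = 10
    # stats
    alpha: float = 0.05
    # transcriptomics
    n_genes: int = 200
    n_planted: int = 20
    coupling: float = 0.8
    n_boot: int = 1000
    n_spins: int = 199
    n_perm: int = 1000
    set_size: int = 50
    write_subject_tables: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(d["k_range"])
        return d


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _truth_map_left(bundle) -> np.ndarray:
    """Ground-truth alteration pattern over left regions (planted signs)."""
    left = bundle.left_region_ids
    m = np.zeros(left.size)
    m[np.isin(left, bundle.planted_regions[1])] = -1.0
    m[np.isin(left, bundle.planted_regions[2])] = 1.0
    if m.std() == 0:  # no planted region on the left: fall back to smooth noise
        m = bundle.region_meta.set_index("region_id").loc[left, "y"].to_numpy()
    return m


def run_full(config: RunConfig, outdir) -> Path:
    """Execute all stages into ``outdir``; returns the run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    seeds = {s: _stage_seed(config.seed, s) for s in _STAGES}

    # --- simulate ------------------------------------------------------
    logger.info("stage simulate")
    cfg = synthcohort.CohortConfig(
        n_hc=config.n_hc, n_sub1=config.n_sub1, n_sub2=config.n_sub2,
        n_regions=config.n_regions, n_vertices=config.n_vertices,
        effect_sub1=config.effect_sub1, effect_sub2=config.effect_sub2,
        affected_frac=config.affected_frac, seed=seeds["simulate"])
    bundle = synthcohort.generate_cohort(cfg)
    bundle.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    bundle.region_meta.to_csv(out / "regions.tsv", sep="\t", index=False)
    if config.write_subject_tables:
        synthcohort.write_bundle(bundle, out / "bundle")
    truth_map = _truth_map_left(bundle)
    expr = synthcohort.generate_expression(
        bundle.region_meta, n_genes=config.n_genes, n_planted=config.n_planted,
        planted_map=truth_map, coupling=config.coupling, seed=seeds["simulate"])
    expr.expression.to_csv(out / "expression.tsv", sep="\t")
    sets = synthcohort.generate_gene_sets(
        list(expr.expression.columns), set_size=config.set_size,
        planted_overlap={"excitatory": expr.planted_gene_ids[: config.set_size]},
        seed=seeds["simulate"])
    coll = genesets.GeneSetCollection(sets=sets, universe=list(expr.expression.columns))
    genesets.write_gmt(coll, out / "sets.gmt")
    (out / "ground_truth.json").write_text(json.dumps({
        "true_subtype": bundle.true_subtype.tolist(),
        "planted_regions": {k: v.tolist() for k, v in bundle.planted_regions.items()},
        "planted_genes": expr.planted_gene_ids,
    }, indent=1))
    counts["simulate"] = {"subjects": int(bundle.n_subjects),
                          "regions": int(config.n_regions)}

    # --- mind ----------------------------------------------------------
    logger.info("stage mind (%s estimator)", config.estimator)
    strengths = np.array([
        mindnet.regional_strength(
            mindnet.mind_matrix(bundle.features[i], estimator=config.estimator,
                                k=config.knn_k))
        for i in range(bundle.n_subjects)])
    rid = bundle.region_meta["region_id"]
    sframe = pd.DataFrame(strengths, columns=rid,
                          index=bundle.covariates["subject_id"])
    sframe.to_csv(out / "strengths.tsv", sep="\t")
    net = mindnet.network_strength(sframe, bundle.region_meta)
    net.to_csv(out / "network_strengths.tsv", sep="\t")
    counts["mind"] = {"subjects": int(sframe.shape[0]), "regions": int(sframe.shape[1])}

    # --- subtype -------------------------------------------------------
    logger.info("stage subtype")
    hcfg = hydra.HydraConfig(k_range=config.k_range, c_reg=config.c_reg,
                             n_iter=config.n_iter, n_consensus=config.n_consensus,
                             n_folds=config.n_folds, seed=seeds["subtype"])
    y = bundle.covariates["diagnosis"].to_numpy()
    sol = hydra.fit_subtypes(strengths, y, hcfg)
    pat_ids = bundle.covariates.loc[y == 1, "subject_id"]
    pd.DataFrame({"subject_id": pat_ids, "subtype": sol.labels}).to_csv(
        out / "labels.tsv", sep="\t", index=False)
    pd.DataFrame({"k": list(sol.cv_ari_by_k), "cv_ari": list(sol.cv_ari_by_k.values())}
                 ).to_csv(out / "cv_ari.tsv", sep="\t", index=False)
    pd.DataFrame(sol.co_assignment, index=pat_ids, columns=pat_ids).to_csv(
        out / "co_assignment.tsv", sep="\t")
    counts["subtype"] = {"patients": int(len(sol.labels)), "chosen_k": int(sol.chosen_k)}

    # --- casecontrol ---------------------------------------------------
    logger.info("stage casecontrol")
    adjusted, _ = casecontrol.adjust_covariates(strengths, bundle.covariates)
    est_sub = np.zeros(bundle.n_subjects, dtype=int)
    est_sub[y == 1] = sol.labels
    tmaps = {}
    for c in sorted(set(sol.labels)):
        grp = np.where(y == -1, -1, 0)
        grp[(y == 1) & (est_sub == c)] = 1
        tm = casecontrol.group_ttest(adjusted, grp, alpha=config.alpha)
        tmaps[c] = tm
        pd.DataFrame({"region_id": rid, "t": tm.t, "p": tm.p,
                      "sig_bonferroni": tm.corrected_significant}).to_csv(
            out / f"tmap_subtype{c}.tsv", sep="\t", index=False)
    tm_pooled = casecontrol.group_ttest(adjusted, y, alpha=config.alpha)
    pd.DataFrame({"region_id": rid, "t": tm_pooled.t, "p": tm_pooled.p,
                  "sig_bonferroni": tm_pooled.corrected_significant}).to_csv(
        out / "tmap_pooled.tsv", sep="\t", index=False)
    adj_net, _ = casecontrol.adjust_covariates(net.to_numpy(), bundle.covariates)
    tm_net = casecontrol.group_ttest(adj_net, y, alpha=config.alpha, m=net.shape[1])
    pd.DataFrame({"network": net.columns, "t": tm_net.t, "p": tm_net.p,
                  "sig_bonferroni": tm_net.corrected_significant}).to_csv(
        out / "tmap_networks.tsv", sep="\t", index=False)
    report = casecontrol.demographics_report(bundle.covariates, est_sub)
    (out / "demographics_report.json").write_text(json.dumps(report, indent=1))
    counts["casecontrol"] = {"tmaps": len(tmaps) + 2}

    # --- pls -----------------------------------------------------------
    logger.info("stage pls")
    left = bundle.left_region_ids
    left_pos = bundle.region_meta.set_index("region_id").loc[left, ["x", "y", "z"]]
    gene_tables = {}
    spin_rows = []
    summary = {}
    for c, tm in tmaps.items():
        y_map = tm.t[np.isin(rid.to_numpy(), left)]
        comp = pls.fit_pls1(expr.expression, y_map)
        table = pls.bootstrap_gene_z(expr.expression, y_map, n_boot=config.n_boot,
                                     seed=seeds["pls"] + c)
        table.to_csv(out / f"gene_scores_subtype{c}.tsv", sep="\t")
        gene_tables[c] = table
        spin = pls.spin_correlation(comp.scores, y_map, left_pos.to_numpy(),
                                    n_spins=config.n_spins, seed=seeds["pls"] + c)
        spin_rows.append({"contrast": f"subtype{c}", "r": spin.r,
                          "p_spin": spin.p_spin, "n_spins": spin.n_spins})
        summary[f"subtype{c}"] = {
            "variance_explained": comp.variance_explained,
            "n_pls1_plus": int((table["cls"] == "PLS1+").sum()),
            "n_pls1_minus": int((table["cls"] == "PLS1-").sum()),
        }
    pd.DataFrame(spin_rows).to_csv(out / "spin_results.tsv", sep="\t", index=False)
    (out / "pls_summary.json").write_text(json.dumps(summary, indent=1))
    counts["pls"] = {"genes": int(expr.expression.shape[1])}

    # --- enrich --------------------------------------------------------
    logger.info("stage enrich")
    coll_h = coll.harmonized(list(expr.expression.columns))
    for c, table in gene_tables.items():
        for sign, tag in (("PLS1+", "plus"), ("PLS1-", "minus")):
            lst = list(table.index[table["cls"] == sign])
            if not lst:
                continue
            enr = genesets.celltype_overlap(lst, coll_h, n_perm=config.n_perm,
                                            seed=seeds["enrich"] + c)
            enr.to_csv(out / f"enrichment_subtype{c}_{tag}.tsv", sep="\t")
    counts["enrich"] = {"sets": len(coll_h.sets)}

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": seeds,
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
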