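"""Gene-set overlap: permutation-tested cell-type assignment and hypergeometric ORA.

Signed gene lists (e.g. the PLS1+/PLS1- classes) are overlapped with named
gene sets such as the seven canonical cortical cell classes (astrocytes,
endothelial cells, microglia, excitatory neurons, inhibitory neurons,
oligodendrocytes, OPCs).  Significance comes from size-matched random draws
out of the scored-gene universe: p = (1 + #{null overlap >= observed}) /
(n_perm + 1), BH-FDR corrected across sets.  An exact hypergeometric upper
tail is provided as the analytic counterpart (the permutation null with
uniform draws converges to it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .casecontrol import bh_fdr

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "celltype_overlap",
    "hypergeom_enrich",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict                       # name -> list of gene symbols
    universe: list = field(default_factory=list)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.sets)) != len(self.sets):
            raise ValueError("set names must be unique")

    def harmonized(self, universe) -> "GeneSetCollection":
        """Restrict every set to the given universe."""
        uni = list(dict.fromkeys(universe))
        us = set(uni)
        return GeneSetCollection(
            sets={k: [g for g in v if g in us] for k, v in self.sets.items()},
            universe=uni, descriptions=dict(self.descriptions))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members)."""
    sets, desc = {}, {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {ln}: expected >= 3 fields")
        name, description, *members = parts
        members = [m for m in members if m]
        uniq = list(dict.fromkeys(members))
        if len(uniq) < len(members):
            logger.warning("GMT line %d (%s): dropped duplicate members", ln, name)
        sets[name] = uniq
        desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "na")
        lines.append("\t".join([name, desc] + list(members)))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def celltype_overlap(gene_list, collection: GeneSetCollection, universe=None,
                     n_perm: int = 5000, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Permutation-tested overlap of a gene list with each named set.

    The null draws lists of the same size uniformly from the universe
    (defaults to the collection's universe).  Returns a table with the
    observed overlap, overlapping genes, permutation p and BH-FDR p.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValueError("empty gene list")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    uni = list(dict.fromkeys(universe if universe is not None else collection.universe))
    if not uni:
        raise ValueError("no universe defined")
    uset = set(uni)
    outside = [g for g in genes if g not in uset]
    if outside:
        raise ValueError(f"gene list members outside universe: {outside[:5]}")
    rng = np.random.default_rng(seed)
    idx_of = {g: i for i, g in enumerate(uni)}
    draws = np.empty((n_perm, len(genes)), dtype=int)
    for i in range(n_perm):
        draws[i] = rng.choice(len(uni), size=len(genes), replace=False)
    member_mask = {name: np.isin(np.arange(len(uni)),
                                 [idx_of[g] for g in members if g in idx_of])
                   for name, members in collection.sets.items()}
    rows = []
    for name, members in collection.sets.items():
        mset = set(members) & uset
        hit = sorted(set(genes) & mset)
        null = member_mask[name][draws].sum(axis=1)
        p = (1 + np.sum(null >= len(hit))) / (n_perm + 1)
        rows.append({"set": name, "overlap_n": len(hit),
                     "genes": ",".join(hit), "p": p})
    tab = pd.DataFrame(rows).set_index("set")
    tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
    tab["significant"] = tab["p_fdr"] < alpha
    return tab


def hypergeom_enrich(gene_list, collection: GeneSetCollection,
                     universe=None, alpha: float = 0.05) -> pd.DataFrame:
    """Exact hypergeometric over-representation P(X >= observed) per set."""
    genes = list(dict.fromkeys(gene_list))
    uni = list(dict.fromkeys(universe if universe is not None else collection.universe))
    if not uni:
        raise ValueError("no universe defined")
    uset = set(uni)
    if len(genes) > len(uni):
        raise ValueError("gene list larger than universe")
    if set(genes) - uset:
        raise ValueError("gene list members outside universe")
    rows = []
    for name, members in collection.sets.items():
        mset = set(members) & uset
        hit = sorted(set(genes) & mset)
        p = float(stats.hypergeom.sf(len(hit) - 1, len(uni), len(mset), len(genes)))
        rows.append({"set": name, "overlap_n": len(hit),
                     "genes": ",".join(hit), "p": min(p, 1.0)})
    tab = pd.DataFrame(rows).set_index("set")
    tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
    tab["significant"] = tab["p_fdr"] < alpha
    return tab
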