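"""Compositional transforms and alpha/beta diversity.

The beta-diversity workhorse is the Aitchison distance: Euclidean
distance between centered log-ratio (CLR) transformed counts.  A
pseudocount (default 1.0) handles sampling zeros; no rarefaction is
applied anywhere.  Phylogenetic measures (Faith's PD, UniFrac) delegate
to scikit-bio and require a rooted tree whose tips cover the taxa; Faith's
PD includes the path to the root, which shifts absolute values but not
trends across samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _faith_pd

from .io import CountTable

__all__ = [
    "clr_transform",
    "aitchison_distance",
    "alpha_diversity",
    "unifrac",
]


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform of a count table.

    Returns a samples x taxa DataFrame where each row is
    ``ln(x + pc) - mean_taxa(ln(x + pc))``; rows sum to zero.
    """
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    x = table.matrix() + pseudocount
    if (x <= 0).any():
        raise ValueError("nonpositive values after pseudocount")
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.taxon_ids)


def aitchison_distance(clr: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between CLR rows (the Aitchison metric)."""
    if clr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    arr = clr.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite CLR values")
    return DistanceMatrix(squareform(pdist(arr, metric="euclidean")), ids=list(clr.index))


def alpha_diversity(
    table: CountTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample alpha diversity: Shannon (nats), Simpson, richness, Faith's PD.

    Samples with zero total counts get NaN for every measure.  ``faith_pd``
    is only computed when a tree is supplied.
    """
    mat = table.matrix()  # samples x taxa
    totals = mat.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mat / totals[:, None]
    shannon = np.full(len(totals), np.nan)
    simpson = np.full(len(totals), np.nan)
    richness = np.full(len(totals), np.nan)
    ok = totals > 0
    plogp = np.where(mat > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon[ok] = -plogp[ok].sum(axis=1)
    simpson[ok] = 1.0 - np.nansum(p[ok] ** 2, axis=1)
    richness[ok] = (mat[ok] > 0).sum(axis=1)
    out = pd.DataFrame(
        {"shannon": shannon, "simpson": simpson, "richness": richness},
        index=table.sample_ids,
    )
    if tree is not None:
        taxa = table.taxon_ids
        pd_vals = np.full(len(totals), np.nan)
        for i in np.flatnonzero(ok):
            pd_vals[i] = _faith_pd(mat[i], taxa, tree)
        out["faith_pd"] = pd_vals
    return out


def unifrac(
    table: CountTable, tree: TreeNode, weighted: bool = False
) -> DistanceMatrix:
    """UniFrac distances between samples on a rooted phylogeny.

    Unweighted UniFrac is the fraction of branch length unique to either
    sample; weighted UniFrac is the normalized variant so values lie in
    [0, 1] and are comparable across pairs.
    """
    if len(tree.children) == 0:
        raise ValueError("tree has no tips")
    tips = {t.name for t in tree.tips()}
    missing = set(table.taxon_ids) - tips
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)[:5]}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": True} if weighted else {}
    return beta_diversity(
        metric,
        table.matrix(),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        **kwargs,
    )
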