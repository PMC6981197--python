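"""Lineage diversity: sesPD under a tip-shuffling null, and its controls.

Lineage diversity (LD) is the standardized effect size of Faith's PD: the
z-score of a community's observed PD against a null built by randomly
shuffling the tip labels of the whole phylogeny and recomputing PD.  It
measures the excess or deficit of evolutionary history given the number of
genera present.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from ._rng import spawn_rng
from .phylo import PhyloTree, PhyloError, prune, graft_missing

__all__ = [
    "genus_mean_map",
    "ses_pd",
    "rarefy_ld",
    "ld_across_trees",
    "validate_matrix",
]

log = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_DEGENERATE = "degenerate_null"
FLAG_LOW_RICHNESS = "low_richness"


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a site x genus incidence frame; drop and log empty genera."""
    if matrix.index.duplicated().any():
        raise ValueError("duplicate site ids in matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate genus ids in matrix")
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("incidence matrix must be 0/1")
    empty = matrix.columns[vals.sum(axis=0) == 0]
    if len(empty):
        log.info("dropping %d genera with zero occurrences: %s",
                 len(empty), list(empty[:10]))
        matrix = matrix.drop(columns=empty)
    return matrix


def genus_mean_map(matrix: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Precipitation niche per genus: mean MAP over its occupied sites.

    Returns a frame indexed by genus with ``mean_map`` (mm/yr) and
    ``n_sites_occupied``; genera occupying no site are dropped (logged).
    """
    matrix = validate_matrix(matrix)
    site_map = sites.set_index("site_id")["map_mm"]
    missing_sites = set(matrix.index) - set(site_map.index)
    if missing_sites:
        raise ValueError(f"matrix sites missing from site table: {sorted(missing_sites)[:10]}")
    map_vec = site_map.loc[matrix.index].to_numpy(dtype=float)
    if np.isnan(map_vec).any():
        bad = matrix.index[np.isnan(map_vec)]
        raise ValueError(f"missing MAP for occupied sites: {list(bad)}")
    inc = matrix.to_numpy(dtype=float)
    occ = inc.sum(axis=0)
    mean_map = (inc * map_vec[:, None]).sum(axis=0) / occ
    return pd.DataFrame(
        {"mean_map": mean_map, "n_sites_occupied": occ.astype(int)},
        index=pd.Index(matrix.columns, name="genus"),
    )


def _aligned_indicator(matrix: pd.DataFrame, tips: Sequence[str]) -> np.ndarray:
    """Sites x tree-tips 0/1 array, columns in tree tip order."""
    tip_pos = {t: j for j, t in enumerate(tips)}
    absent = [g for g in matrix.columns if g not in tip_pos]
    if absent:
        raise PhyloError(f"matrix genera absent from tree: {absent[:10]}")
    m = np.zeros((matrix.shape[0], len(tips)), dtype=np.float64)
    vals = matrix.to_numpy()
    for j, g in enumerate(matrix.columns):
        m[:, tip_pos[g]] = vals[:, j]
    return m


def _pd_from_counts(counts: np.ndarray, richness: np.ndarray, lengths: np.ndarray,
                    include_root: bool) -> np.ndarray:
    if include_root:
        hit = counts > 0
    else:
        hit = (counts > 0) & (counts < richness[:, None])
    return hit @ lengths


def ses_pd(matrix: pd.DataFrame, tree: PhyloTree, n_null: int, seed: int,
           include_root: bool = True, shared_permutation: bool = True,
           exhaustive: bool = False) -> pd.DataFrame:
    """Standardized effect size of PD per site (the study's lineage diversity).

    The null shuffles the tip labels of the whole phylogeny ``n_null``
    times; by default one permutation per iteration is shared by all sites.
    ``ld = (pd_obs - null_mean) / null_sd``.  Sites where the null is
    permutation-invariant get flag ``degenerate_null``; sites with fewer
    than 2 genera get ``low_richness``; both have missing ``ld``.

    With ``exhaustive=True`` (feasible only for tiny trees) all tip-label
    permutations are enumerated instead of sampled, and the null moments
    are the exact population moments of that distribution.
    """
    import itertools
    import math as _math

    if n_null < 1 and not exhaustive:
        raise ValueError("n_null must be >= 1")
    matrix = validate_matrix(matrix)
    lengths, inc, tips = tree.edge_arrays()
    m = _aligned_indicator(matrix, tips)
    inc_sp = sparse.csr_matrix(inc)  # edges x tips
    richness = m.sum(axis=1).astype(int)
    counts_obs = (inc_sp @ m.T).T
    pd_obs = _pd_from_counts(counts_obs, richness, lengths, include_root)
    rng = spawn_rng(seed, "sespd")
    n_sites, n_tips = m.shape
    null_sum = np.zeros(n_sites)
    null_sq = np.zeros(n_sites)
    if exhaustive:
        if n_tips > 8:
            raise ValueError("exhaustive null is limited to trees with <= 8 tips")
        perms = list(itertools.permutations(range(n_tips)))
    else:
        perms = None
    n_iter = len(perms) if exhaustive else n_null
    for it in range(n_iter):
        if exhaustive:
            mp = m[:, list(perms[it])]
        elif shared_permutation:
            perm = rng.permutation(n_tips)
            mp = m[:, perm]
        else:
            mp = np.zeros_like(m)
            for i in range(n_sites):
                mp[i, rng.choice(n_tips, size=richness[i], replace=False)] = 1.0
        counts = (inc_sp @ mp.T).T
        pd_null = _pd_from_counts(counts, richness, lengths, include_root)
        null_sum += pd_null
        null_sq += pd_null ** 2
    null_mean = null_sum / n_iter
    null_var = np.maximum(null_sq / n_iter - null_mean ** 2, 0.0)
    # sampled null: unbiased (n-1) variance; exhaustive: exact population variance
    if not exhaustive and n_iter > 1:
        null_var = null_var * n_iter / (n_iter - 1)
    null_sd = np.sqrt(null_var)
    n_null = n_iter
    ld = np.full(n_sites, np.nan)
    flags = np.full(n_sites, FLAG_OK, dtype=object)
    degen = np.isclose(null_sd, 0.0, atol=1e-12)
    low = richness < 2
    okm = ~degen & ~low
    ld[okm] = (pd_obs[okm] - null_mean[okm]) / null_sd[okm]
    flags[degen] = FLAG_DEGENERATE
    flags[low] = FLAG_LOW_RICHNESS
    return pd.DataFrame({
        "site_id": matrix.index,
        "richness": richness,
        "pd_obs": pd_obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "ld": ld,
        "n_null": n_null,
        "flag": flags,
    }).set_index("site_id")


def rarefy_ld(matrix: pd.DataFrame, tree: PhyloTree, target_richness: int,
              n_reps: int, n_null: int, seed: int) -> pd.DataFrame:
    """Richness-controlled LD: subsample each qualifying site to a fixed
    genus count, recompute sesPD, and average over repetitions.

    Sites with richness below ``target_richness`` are excluded (listed in
    the result's ``attrs['excluded']``).  In each repetition the tree is
    pruned to the genus pool of the rarefied matrix before the null is
    built, so the shuffle pool tracks the rarefied data.
    """
    if target_richness < 2:
        raise ValueError("target_richness must be >= 2")
    matrix = validate_matrix(matrix)
    richness = matrix.sum(axis=1)
    qualifying = matrix.index[richness >= target_richness]
    excluded = [s for s in matrix.index if s not in set(qualifying)]
    if len(qualifying) == 0:
        raise ValueError("no site reaches the rarefaction target richness")
    sub = matrix.loc[qualifying]
    vals = sub.to_numpy()
    rng = spawn_rng(seed, "rarefy")
    per_rep = np.zeros((n_reps, len(qualifying)))
    for rep in range(n_reps):
        rare = np.zeros_like(vals)
        for i in range(vals.shape[0]):
            present = np.flatnonzero(vals[i])
            keep = rng.choice(present, size=target_richness, replace=False)
            rare[i, keep] = 1
        rmat = pd.DataFrame(rare, index=sub.index, columns=sub.columns)
        pool = rmat.columns[rare.sum(axis=0) > 0]
        rtree = prune(tree, list(pool))
        tab = ses_pd(rmat[list(pool)], rtree, n_null=n_null,
                     seed=int(rng.integers(2 ** 31)))
        per_rep[rep] = tab["ld"].to_numpy()
    out = pd.DataFrame({
        "ld_mean": np.nanmean(per_rep, axis=0),
        "ld_sd": np.nanstd(per_rep, axis=0, ddof=1) if n_reps > 1 else np.nan,
        "n_reps": n_reps,
    }, index=pd.Index(qualifying, name="site_id"))
    out.attrs["excluded"] = excluded
    return out


def ld_across_trees(matrix: pd.DataFrame, trees: Sequence[PhyloTree], n_null: int,
                    seed: int, clade_maps: Sequence[Mapping] | None = None,
                    split_seeds: bool = True) -> pd.DataFrame:
    """LD averaged over a set of trees (e.g. a posterior sample).

    Each tree gets its own sesPD run (seeds split per tree unless
    ``split_seeds`` is False); trees missing matrix genera must come with a
    clade map for grafting.  Returns per-site mean and sd of LD across trees.
    """
    if len(trees) == 0:
        raise ValueError("empty tree list")
    matrix = validate_matrix(matrix)
    genera = set(matrix.columns)
    lds = []
    for i, tree in enumerate(trees):
        missing = genera - set(tree.tip_labels)
        if missing:
            if clade_maps is None or clade_maps[i] is None:
                raise PhyloError(
                    f"tree {i} is missing {len(missing)} matrix genera and no "
                    "clade map was supplied")
            cm = {g: clade_maps[i][g] for g in missing}
            tree = graft_missing(tree, cm, seed=seed + i if split_seeds else seed)
        s = seed + 1000003 * i if split_seeds else seed
        tab = ses_pd(matrix, tree, n_null=n_null, seed=s)
        lds.append(tab["ld"].to_numpy())
    arr = np.vstack(lds)
    return pd.DataFrame({
        "ld_mean": np.nanmean(arr, axis=0),
        "ld_sd": np.nanstd(arr, axis=0, ddof=1) if len(trees) > 1 else 0.0,
        "n_trees": len(trees),
    }, index=matrix.index)
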