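"""Phylogenetic core: trees, Faith's PD, Pagel's lambda, pruning and grafting.

The tree container wraps a :class:`dendropy.Tree` and adds the array views
the diversity and signal machinery needs: an edge-by-tip incidence matrix,
tip depths, and the Brownian-motion covariance implied by shared root-to-MRCA
path lengths.  Branch lengths are in millions of years throughout.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "PhyloTree",
    "LambdaFit",
    "PhyloError",
    "read_newick",
    "write_newick",
    "faith_pd",
    "lambda_transform",
    "pagel_lambda",
    "prune",
    "graft_missing",
]

ULTRAMETRIC_RTOL = 1e-6


class PhyloError(ValueError):
    """Raised for malformed trees or invalid phylogenetic operations."""


class PhyloTree:
    """Rooted tree with branch lengths; tips are genus labels.

    Thin wrapper over dendropy that caches the array representations used
    by PD and likelihood computations.  Mutating operations return new
    trees; the wrapped dendropy tree should not be modified in place.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._cache: dict[str, object] = {}

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        labels = [lf.taxon.label if lf.taxon else None for lf in self._tree.leaf_node_iter()]
        if any(lb is None or lb == "" for lb in labels):
            raise PhyloError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise PhyloError(f"duplicate tip labels: {dupes}")
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.edge.length is None:
                raise PhyloError(f"missing branch length above node {nd.taxon.label if nd.taxon else nd.label!r}")
            if nd.edge.length < 0:
                raise PhyloError(f"negative branch length: {nd.edge.length}")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- basic geometry -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        key = "tip_labels"
        if key not in self._cache:
            self._cache[key] = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        return list(self._cache[key])

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def node_depths(self) -> dict[dendropy.Node, float]:
        depths: dict[dendropy.Node, float] = {}
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + nd.edge.length
        return depths

    def tip_depths(self) -> np.ndarray:
        depths = self.node_depths()
        return np.array([depths[lf] for lf in self._tree.leaf_node_iter()])

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    @property
    def total_branch_length(self) -> float:
        return float(sum(nd.edge.length for nd in self._tree.preorder_node_iter()
                         if nd.parent_node is not None))

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths()
        h = d.max()
        return h == 0 or float(d.max() - d.min()) <= rtol * h

    def require_ultrametric(self, what: str = "operation") -> None:
        if not self.is_ultrametric():
            d = self.tip_depths()
            labels = self.tip_labels
            lo, hi = int(np.argmin(d)), int(np.argmax(d))
            raise PhyloError(
                f"{what} requires an ultrametric tree; tip depths range from "
                f"{d[lo]:.6g} ({labels[lo]}) to {d[hi]:.6g} ({labels[hi]})"
            )

    # -- array views ----------------------------------------------------

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """``(lengths, incidence, tip_labels)`` over non-root edges.

        ``incidence[e, t]`` is True when tip ``t`` descends through edge
        ``e``; PD of a tip set is the length-sum over edges its indicator
        hits.  Cached: the tree is treated as immutable.
        """
        key = "edge_arrays"
        if key not in self._cache:
            tips = self.tip_labels
            tip_index = {lb: i for i, lb in enumerate(tips)}
            edges = [nd for nd in self._tree.preorder_node_iter() if nd.parent_node is not None]
            lengths = np.array([nd.edge.length for nd in edges], dtype=float)
            inc = np.zeros((len(edges), len(tips)), dtype=bool)
            tipsets: dict[dendropy.Node, np.ndarray] = {}
            for nd in self._tree.postorder_node_iter():
                if nd.is_leaf():
                    vec = np.zeros(len(tips), dtype=bool)
                    vec[tip_index[nd.taxon.label]] = True
                else:
                    vec = np.zeros(len(tips), dtype=bool)
                    for ch in nd.child_nodes():
                        vec |= tipsets[ch]
                tipsets[nd] = vec
            for e, nd in enumerate(edges):
                inc[e] = tipsets[nd]
            self._cache[key] = (lengths, inc, tips)
        lengths, inc, tips = self._cache[key]
        return lengths, inc, list(tips)

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Brownian covariance: shared root-to-MRCA path length per tip pair."""
        key = "vcv"
        if key not in self._cache:
            lengths, inc, tips = self.edge_arrays()
            a = inc.astype(float)
            c = a.T @ (lengths[:, None] * a)
            self._cache[key] = (c, tips)
        c, tips = self._cache[key]
        return c.copy(), list(tips)

    def mrca(self, taxa: Iterable[str]) -> dendropy.Node:
        labels = set(taxa)
        leaves = [lf for lf in self._tree.leaf_node_iter()
                  if lf.taxon and lf.taxon.label in labels]
        if len(leaves) != len(labels):
            found = {lf.taxon.label for lf in leaves}
            raise PhyloError(f"taxa not in tree: {sorted(labels - found)}")
        if len(leaves) == 1:
            return leaves[0]

        def ancestors(nd):
            path = []
            while nd is not None:
                path.append(nd)
                nd = nd.parent_node
            return path

        common = set(ancestors(leaves[0]))
        for lf in leaves[1:]:
            common &= set(ancestors(lf))
        # the deepest common ancestor is the one with maximal root distance
        return max(common, key=lambda nd: len(ancestors(nd)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips}, height={self.height:.3g})"


# -- newick I/O ---------------------------------------------------------


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (lengths after colons, internal labels kept)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise PhyloError(f"newick parse error: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    out = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    return out.strip()


# -- Faith's PD ---------------------------------------------------------


def faith_pd(tree: PhyloTree, taxa: Iterable[str], include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a community, in Myr.

    Sum of branch lengths of the minimal subtree spanning ``taxa`` and the
    root (default convention); with ``include_root=False`` the subtree
    spans the taxa and their MRCA only.
    """
    taxa = set(taxa)
    if not taxa:
        raise PhyloError("faith_pd: empty taxon set")
    lengths, inc, tips = tree.edge_arrays()
    unknown = taxa - set(tips)
    if unknown:
        raise PhyloError(f"faith_pd: taxa not in tree: {sorted(unknown)}")
    mask = np.isin(tips, list(taxa)).astype(np.int64)
    counts = inc.astype(np.int64) @ mask
    if include_root:
        hit = counts > 0
    else:
        hit = (counts > 0) & (counts < mask.sum())
    return float(lengths[hit].sum())


# -- Pagel's lambda -----------------------------------------------------


def lambda_transform(tree: PhyloTree, lam: float) -> PhyloTree:
    """Pagel's lambda branch-length transform on an ultrametric tree.

    Internal branches are multiplied by ``lam`` and terminal branches
    stretched so every tip keeps its depth; the implied BM covariance keeps
    its diagonal and has off-diagonals scaled by ``lam``.
    """
    if not 0.0 <= lam <= 1.0:
        raise PhyloError(f"lambda must be in [0, 1], got {lam}")
    tree.require_ultrametric("lambda_transform")
    new = tree.dendropy_tree.clone(depth=1)
    depths: dict[dendropy.Node, float] = {}
    for nd in new.preorder_node_iter():
        depths[nd] = 0.0 if nd.parent_node is None else depths[nd.parent_node] + nd.edge.length
    for nd in new.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.is_leaf():
            # terminal: keep tip depth while the parent moved to lam * depth
            nd.edge.length = depths[nd] - lam * depths[nd.parent_node]
        else:
            nd.edge.length = lam * nd.edge.length
    return PhyloTree(new)


@dataclass(frozen=True)
class LambdaFit:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0."""

    lambda_hat: float
    sigma2_hat: float
    root_state_hat: float
    loglik: float
    loglik_lambda0: float
    lrt_stat: float
    p_value: float
    n_tips: int

    @property
    def p_value_boundary(self) -> float:
        """Boundary-corrected p (50:50 mixture of chi2_0 and chi2_1)."""
        if self.lrt_stat <= 0:
            return 1.0
        return 0.5 * stats.chi2.sf(self.lrt_stat, df=1)


def _lambda_profile_loglik(lam: float, c: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood at lambda; returns (loglik, mu_hat, sigma2_hat)."""
    n = len(y)
    v = lam * c
    np.fill_diagonal(v, np.diag(c))
    try:
        cho = linalg.cho_factor(v, lower=True)
    except linalg.LinAlgError:
        # nearly coincident tips can push the matrix to the PSD boundary
        try:
            cho = linalg.cho_factor(v + 1e-10 * float(np.mean(np.diag(c))) * np.eye(n),
                                    lower=True)
        except linalg.LinAlgError as exc:
            raise PhyloError(
                "singular phylogenetic covariance (duplicated tip depths / "
                "zero-length terminal branches?)"
            ) from exc
    ones = np.ones(n)
    vi_one = linalg.cho_solve(cho, ones)
    vi_y = linalg.cho_solve(cho, y)
    mu = float(ones @ vi_y) / float(ones @ vi_one)
    r = y - mu
    vi_r = vi_y - mu * vi_one
    sigma2 = float(r @ vi_r) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.log(np.diag(cho[0])).sum()
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def pagel_lambda(tree: PhyloTree, trait: Mapping[str, float]) -> LambdaFit:
    """ML Pagel's lambda for a continuous tip trait, with an LRT against 0.

    lambda scales the off-diagonal phylogenetic covariance: 0 means tip
    values are independent of the tree, 1 means plain Brownian motion.
    The root state and rate are profiled out analytically (GLS given
    lambda); lambda is maximised on [0, 1] with a coarse multi-start grid
    followed by bounded refinement.  The p-value uses chi-square with 1 df;
    a boundary-mixture p is also exposed on the fit.
    """
    keys = [k for k in trait if not (trait[k] is None or (isinstance(trait[k], float) and math.isnan(trait[k])))]
    usable = sorted(set(keys) & set(tree.tip_labels))
    if len(usable) < 4:
        raise PhyloError(f"pagel_lambda needs >= 4 tips with trait values, got {len(usable)}")
    sub = prune(tree, usable) if len(usable) < tree.n_tips else tree
    c, tips = sub.vcv()
    y = np.array([float(trait[t]) for t in tips])

    def negll(lam: float) -> float:
        return -_lambda_profile_loglik(lam, c, y)[0]

    starts = [0.0, 0.25, 0.5, 0.75, 1.0]
    grid = [(negll(s), s) for s in starts]
    best_val, best_lam = min(grid)
    lo = max(0.0, best_lam - 0.25)
    hi = min(1.0, best_lam + 0.25)
    res = optimize.minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    cand = [(best_val, best_lam)]
    if res.success or np.isfinite(res.fun):
        cand.append((float(res.fun), float(res.x)))
    best_val, best_lam = min(cand)
    ll_hat, mu_hat, s2_hat = _lambda_profile_loglik(best_lam, c, y)
    ll0 = _lambda_profile_loglik(0.0, c, y)[0]
    lrt = max(2.0 * (ll_hat - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    return LambdaFit(
        lambda_hat=float(best_lam),
        sigma2_hat=float(s2_hat),
        root_state_hat=float(mu_hat),
        loglik=float(ll_hat),
        loglik_lambda0=float(ll0),
        lrt_stat=float(lrt),
        p_value=p,
        n_tips=len(tips),
    )


# -- pruning and grafting ----------------------------------------------


def prune(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``taxa``; unbranched nodes are suppressed with
    their lengths summed, so tip depths are preserved."""
    keep = sorted(set(taxa) & set(tree.tip_labels))
    if not keep:
        raise PhyloError("prune: no requested taxa present in tree")
    new = tree.dendropy_tree.clone(depth=1)
    new.retain_taxa_with_labels(keep)
    # drop a dangling root edge left by unifurcation suppression
    if new.seed_node.edge.length:
        new.seed_node.edge.length = None
    return PhyloTree(new)


CladeMap = Mapping[str, frozenset | str]


def _resolve_clade(tree: PhyloTree, label: frozenset | str) -> dendropy.Node:
    if isinstance(label, str):
        for nd in tree.dendropy_tree.preorder_node_iter():
            nm = nd.taxon.label if nd.taxon else nd.label
            if nm == label:
                return nd
        raise PhyloError(f"clade label {label!r} not found in tree")
    tipset = set(label)
    missing = tipset - set(tree.tip_labels)
    if missing:
        raise PhyloError(f"clade tips absent from tree: {sorted(missing)}")
    if len(tipset) == 1:
        (only,) = tipset
        for lf in tree.dendropy_tree.leaf_node_iter():
            if lf.taxon.label == only:
                return lf
    return tree.mrca(tipset)


def graft_missing(tree: PhyloTree, clade_map: CladeMap, seed: int) -> PhyloTree:
    """Attach genera missing from the phylogeny at random positions inside
    their most derived consensus clades (MDCCs).

    For each missing genus an edge of its MDCC subtree (stem edge included)
    is drawn with probability proportional to its length, the attachment
    time is uniform along that edge, and the new terminal branch runs to
    the present, keeping the tree ultrametric.
    """
    from ._rng import spawn_rng

    tree.require_ultrametric("graft_missing")
    existing = set(tree.tip_labels)
    for g in clade_map:
        if g in existing:
            raise PhyloError(f"graft label collides with existing tip: {g}")
    new = PhyloTree(tree.dendropy_tree.clone(depth=1))
    dtree = new.dendropy_tree
    height = new.height
    rng = spawn_rng(seed, "graft")
    for genus in sorted(clade_map):
        target = _resolve_clade(new, clade_map[genus])
        depths: dict[dendropy.Node, float] = {}
        for nd in dtree.preorder_node_iter():
            depths[nd] = 0.0 if nd.parent_node is None else depths[nd.parent_node] + nd.edge.length
        # candidate edges: subtree of the MDCC plus its stem edge
        cand: list[dendropy.Node] = []
        stack = [target]
        while stack:
            nd = stack.pop()
            if nd.parent_node is not None:
                cand.append(nd)
            stack.extend(nd.child_nodes())
        cand = [nd for nd in cand if nd.edge.length and nd.edge.length > 0]
        if not cand:
            raise PhyloError(f"MDCC for {genus!r} has zero total edge length")
        lens = np.array([nd.edge.length for nd in cand])
        pick = cand[int(rng.choice(len(cand), p=lens / lens.sum()))]
        parent = pick.parent_node
        top = depths[parent]
        bottom = depths[pick]
        attach_depth = float(rng.uniform(top, bottom))
        mid = dendropy.Node()
        parent.remove_child(pick)
        parent.add_child(mid)
        mid.edge.length = attach_depth - top
        mid.add_child(pick)
        pick.edge.length = bottom - attach_depth
        taxon = dtree.taxon_namespace.new_taxon(label=genus)
        tipnode = dendropy.Node(taxon=taxon)
        mid.add_child(tipnode)
        tipnode.edge.length = height - attach_depth
        new = PhyloTree(dtree)
    out = PhyloTree(dtree)
    out.require_ultrametric("graft_missing output")
    return out
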