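"""Phylogenetic correlation matrices and Pagel's lambda.

A dated (ultrametric) tree induces a Brownian-motion covariance among
species: C[i, j] is the shared root-to-MRCA path length, so C has the
tree height on the diagonal and R = C / height is a correlation matrix.
Species absent from the tree can be grafted at the basal node of their
genus or family before pruning, the convention for placing unsampled
taxa into a dated mega-tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve

__all__ = [
    "PhyloCorrelation",
    "read_tree",
    "read_and_prune",
    "bind_at_basal_node",
    "correlation_matrix",
    "pagels_lambda",
]

ULTRAMETRIC_RTOL = 1e-6


@dataclass
class PhyloCorrelation:
    """Species-by-species phylogenetic correlation (unit diagonal)."""

    species: list
    R: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.R, index=self.species, columns=self.species)


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string or file path (underscores kept literal)."""
    src = {"path": newick} if "(" not in newick else {"data": newick}
    # force-rooted: bipartition operations (e.g. MRCA) silently deroot
    # unrooted trees, which would break ultrametricity from the seed node
    return dendropy.Tree.get(**src, schema="newick", preserve_underscores=True,
                             rooting="force-rooted")


def _tip_labels(tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def read_and_prune(newick, keep) -> dendropy.Tree:
    """Restrict a tree to ``keep`` tips, preserving path lengths among them."""
    tree = read_tree(newick) if isinstance(newick, str) else newick
    keep = list(keep)
    if not keep:
        raise ValueError("empty species set")
    present = set(_tip_labels(tree))
    missing = sorted(set(keep) - present)
    if missing:
        raise ValueError(f"species absent from the tree: {missing}")
    tree.retain_taxa_with_labels(keep)
    return tree


def _genus(label: str) -> str:
    return label.replace("_", " ").split()[0]


def bind_at_basal_node(
    tree: dendropy.Tree,
    species: str,
    anchor: str,
    taxonomy: pd.DataFrame | None = None,
) -> dendropy.Tree:
    """Graft a missing species at the basal node of its genus or family.

    ``anchor`` is matched against tip-name genus prefixes, or against the
    genus/family columns of a (species, genus, family) taxonomy table.
    The new pendant edge is sized so the tree stays ultrametric; a
    monotypic anchor is split at the midpoint of its pendant edge, making
    the new tip sister to the single congener.
    """
    members = set()
    if taxonomy is not None:
        tax = taxonomy.set_index("species")
        for col in ("genus", "family"):
            if col in tax.columns:
                members |= set(tax.index[tax[col] == anchor])
    tips = [lf for lf in tree.leaf_node_iter()
            if _genus(lf.taxon.label) == anchor or lf.taxon.label in members]
    if not tips:
        raise ValueError(f"anchor {anchor!r} matches no tips in the tree")

    height = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    taxon = tree.taxon_namespace.require_taxon(label=species)
    if len(tips) == 1:
        leaf = tips[0]
        e = leaf.edge.length or 0.0
        parent = leaf.parent_node
        joint = parent.new_child(edge_length=e / 2.0)
        parent.remove_child(leaf)
        joint.add_child(leaf)
        leaf.edge.length = e / 2.0
        depth = joint.distance_from_root()
    else:
        joint = tree.mrca(taxa=[t.taxon for t in tips])
        depth = joint.distance_from_root()
    joint.new_child(taxon=taxon, edge_length=height - depth)
    return tree


def correlation_matrix(tree, extend: bool = False) -> PhyloCorrelation:
    """Brownian-motion correlation matrix of an ultrametric tree.

    C[i, j] is the depth of the most recent common ancestor of tips i and
    j; R = C / height. A tree whose tip depths differ by more than
    ``ULTRAMETRIC_RTOL`` x height is rejected unless ``extend=True``,
    which lengthens each pendant edge to the maximum tip depth first.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    leaves = list(tree.leaf_node_iter())
    depths = np.array([lf.distance_from_root() for lf in leaves])
    height = float(depths.max())
    if height <= 0:
        raise ValueError("tree has zero height")
    if np.max(height - depths) > ULTRAMETRIC_RTOL * height:
        if not extend:
            raise ValueError(
                "tree is not ultrametric within tolerance; pass extend=True to "
                "lengthen pendant edges to the tree height"
            )
        for lf, d in zip(leaves, depths):
            lf.edge.length += height - d

    species = [lf.taxon.label for lf in leaves]
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    np.fill_diagonal(C, height)

    node_depth = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            node_depth[id(nd)] = 0.0  # a root edge is not shared ancestry
            continue
        node_depth[id(nd)] = node_depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    below: dict[int, list] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = [idx[id(nd)]]
            continue
        kids = [below.pop(id(ch)) for ch in nd.child_nodes()]
        d = node_depth[id(nd)]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    C[i, kids[b]] = d
                    C[kids[b], i] = d
        below[id(nd)] = [i for kid in kids for i in kid]
    return PhyloCorrelation(species=species, R=C / height)


def _lambda_loglik(lam: float, x: np.ndarray, R: np.ndarray) -> float:
    n = len(x)
    Rl = lam * R + (1.0 - lam) * np.eye(n)
    cR = None
    for jitter in (0.0, 1e-10, 1e-8):
        try:
            cR = cho_factor(Rl + jitter * np.eye(n), lower=True)
            break
        except LinAlgError:
            continue
    if cR is None:
        # numerically singular (e.g. effectively identical tips at lambda = 1):
        # treat as unattainable rather than aborting the profile search
        return -np.inf
    one = np.ones(n)
    Ri1 = cho_solve(cR, one)
    Rix = cho_solve(cR, x)
    mu = float(one @ Rix) / float(one @ Ri1)
    r = x - mu
    s2 = float(r @ cho_solve(cR, r)) / n
    if s2 <= 0:
        return -np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(cR[0]))))
    return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def pagels_lambda(estimates, corr: PhyloCorrelation | pd.DataFrame) -> tuple[float, float]:
    """ML estimate of Pagel's lambda on species-level values, with a
    likelihood-ratio p-value against lambda = 0.

    lambda scales the off-diagonal phylogenetic correlations; the mean is
    profiled by GLS and sigma^2 analytically at each lambda. The LRT
    p-value is halved (boundary mixture); a flat likelihood (e.g. a star
    tree) reports lambda = 0 with p = 1.
    """
    if isinstance(corr, PhyloCorrelation):
        species, R = corr.species, corr.R
    else:
        species, R = list(corr.index), corr.to_numpy(dtype=float)
    if isinstance(estimates, pd.DataFrame):
        est = estimates.set_index("species")["estimate"].reindex(species)
        if est.isna().any():
            raise ValueError("estimates missing for some species in the correlation matrix")
        x = est.to_numpy(dtype=float)
    else:
        x = np.asarray(estimates, dtype=float)
    if len(x) < 4:
        raise ValueError("Pagel's lambda needs at least 4 species")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite species estimates")

    probe = [_lambda_loglik(l, x, R) for l in (0.0, 0.5, 1.0)]
    if max(probe) - min(probe) < 1e-9:
        return 0.0, 1.0
    res = optimize.minimize_scalar(
        lambda l: -_lambda_loglik(l, x, R), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    cands = [(probe[0], 0.0), (probe[2], 1.0), (-res.fun, float(res.x))]
    ll_hat, lam_hat = max(cands, key=lambda t: t[0])
    lr = 2.0 * (ll_hat - probe[0])
    p = 1.0 if lr <= 1e-8 else 0.5 * float(stats.chi2.sf(lr, 1))
    return lam_hat, p
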