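"""Tree handling: pruning, basal grafting, Brownian correlation matrices
and Pagel's lambda."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from dielmeta.phylo import (bind_at_basal_node, correlation_matrix, pagels_lambda,
                            read_and_prune, read_tree)
from dielmeta.simulate import simulate_tree


def biopython_mrca_depth_oracle(newick):
    """Quadratic-time correlation oracle through an independent library:
    C[i, j] = depth of the MRCA of tips i and j; R = C / height."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    tree.root.branch_length = None  # root edge is not shared ancestry
    depths = tree.depths()
    tips = tree.get_terminals()
    names = [t.name for t in tips]
    height = max(depths[t] for t in tips)
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depths[tips[i]]
        for j in range(i + 1, n):
            mrca = tree.common_ancestor(tips[i], tips[j])
            C[i, j] = C[j, i] = depths[mrca]
    return names, C / height


def test_star_tree_identity():
    corr = correlation_matrix("(A:1,B:1,C:1,D:1);")
    assert np.allclose(corr.R, np.eye(4))


def test_sisters_at_half_depth(balanced_tree_newick):
    corr = correlation_matrix(balanced_tree_newick).to_frame()
    assert corr.loc["A", "B"] == pytest.approx(0.5)
    assert corr.loc["C", "D"] == pytest.approx(0.75)
    assert corr.loc["A", "C"] == pytest.approx(0.0)
    assert np.allclose(np.diag(corr.to_numpy()), 1.0)


@pytest.mark.parametrize("n,seed", [(8, 3), (12, 11), (16, 42)])
def test_correlation_matches_brute_force_oracle(n, seed):
    newick = simulate_tree(n, seed)
    corr = correlation_matrix(read_tree(newick))
    names, R_oracle = biopython_mrca_depth_oracle(newick)
    ours = corr.to_frame().loc[names, names].to_numpy()
    assert np.allclose(ours, R_oracle, atol=1e-9)
    # PSD with unit diagonal
    assert np.min(np.linalg.eigvalsh(ours)) > -1e-8


def test_non_ultrametric_rejected_and_repairable():
    newick = "((A:0.5,B:0.2):0.5,C:1.0);"
    with pytest.raises(ValueError, match="ultrametric"):
        correlation_matrix(newick)
    corr = correlation_matrix(read_tree(newick), extend=True)
    assert np.allclose(np.diag(corr.R), 1.0)


def test_prune_preserves_path_lengths():
    newick = simulate_tree(10, seed=5)
    full_bio = Phylo.read(io.StringIO(newick), "newick")
    keep = sorted(t.name for t in full_bio.get_terminals())[:4]
    pruned = read_and_prune(newick, keep)
    pdm = pruned.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pruned.taxon_namespace if t.label in keep}
    for i, a in enumerate(keep):
        for b in keep[i + 1:]:
            ours = pdm.distance(taxa[a], taxa[b])
            oracle = full_bio.distance(a, b)  # path sum on the unpruned tree
            assert ours == pytest.approx(oracle, abs=1e-9)


def test_prune_identity_and_errors(balanced_tree_newick):
    tree = read_and_prune(balanced_tree_newick, ["A", "B", "C", "D"])
    assert np.allclose(correlation_matrix(tree).to_frame().loc["A", "B"], 0.5)
    with pytest.raises(ValueError, match="empty"):
        read_and_prune(balanced_tree_newick, [])
    with pytest.raises(ValueError, match="absent"):
        read_and_prune(balanced_tree_newick, ["A", "Zz"])


def test_bind_to_monotypic_genus():
    newick = "((Aus_a:0.5,Bus_b:0.5):0.5,Cus_c:1.0);"
    tree = bind_at_basal_node(read_tree(newick), "Bus_new", "Bus")
    corr = correlation_matrix(tree).to_frame()
    # sister of the single congener, joined halfway along its pendant edge
    assert corr.loc["Bus_new", "Bus_b"] == pytest.approx(0.75)
    assert corr.loc["Bus_new", "Aus_a"] == pytest.approx(0.5)
    assert np.allclose(np.diag(corr.to_numpy()), 1.0)  # stays ultrametric


def test_bind_to_clade_preserves_original_distances():
    newick = "(((Aus_a:0.3,Aus_b:0.3):0.4,Bus_b:0.7):0.3,Cus_c:1.0);"
    before = correlation_matrix(read_tree(newick)).to_frame()
    tree = bind_at_basal_node(read_tree(newick), "Aus_new", "Aus")
    after = correlation_matrix(tree).to_frame()
    orig = ["Aus_a", "Aus_b", "Bus_b", "Cus_c"]
    assert np.allclose(after.loc[orig, orig], before.loc[orig, orig], atol=1e-12)
    # grafted at the genus MRCA (depth 0.3 from the root side = corr 0.7)
    assert after.loc["Aus_new", "Aus_a"] == pytest.approx(0.7)
    with pytest.raises(ValueError, match="anchor"):
        bind_at_basal_node(tree, "X_y", "Zus")


def test_taxonomy_table_binding():
    newick = "((Aus_a:0.5,Bus_b:0.5):0.5,Cus_c:1.0);"
    tax = pd.DataFrame({"species": ["Aus_a", "Bus_b", "Cus_c"],
                        "genus": ["Aus", "Bus", "Cus"],
                        "family": ["Fam1", "Fam1", "Fam2"]})
    tree = bind_at_basal_node(read_tree(newick), "New_sp", "Fam1", taxonomy=tax)
    corr = correlation_matrix(tree).to_frame()
    # family MRCA is at depth 0.5 from the tips' side: corr 0.5 with both members
    assert corr.loc["New_sp", "Aus_a"] == pytest.approx(0.5)
    assert corr.loc["New_sp", "Bus_b"] == pytest.approx(0.5)


def test_lambda_star_tree_flat_likelihood():
    corr = correlation_matrix("(A:1,B:1,C:1,D:1,E:1);")
    lam, p = pagels_lambda(np.array([0.3, -0.2, 0.5, 0.1, -0.4]), corr)
    assert lam == 0.0 and p == 1.0


def test_lambda_requires_four_species(balanced_tree_newick):
    corr = correlation_matrix(balanced_tree_newick)
    with pytest.raises(ValueError):
        pagels_lambda(np.array([1.0, 2.0, 3.0]), pd.DataFrame(corr.R[:3, :3],
                      index=corr.species[:3], columns=corr.species[:3]))


def test_lambda_likelihood_beats_endpoints(rng):
    newick = simulate_tree(40, seed=9)
    corr = correlation_matrix(read_tree(newick))
    L = np.linalg.cholesky(corr.R + 1e-10 * np.eye(40))
    x = 0.7 * (L @ rng.standard_normal(40)) + 0.7 * rng.standard_normal(40)
    lam, p = pagels_lambda(x, corr)
    assert 0.0 <= lam <= 1.0
    from dielmeta.phylo import _lambda_loglik
    ll_hat = _lambda_loglik(lam, x, corr.R)
    assert ll_hat >= _lambda_loglik(0.0, x, corr.R) - 1e-8
    assert ll_hat >= _lambda_loglik(1.0, x, corr.R) - 1e-8


def test_lambda_aligns_estimates_by_species(balanced_tree_newick):
    corr = correlation_matrix(balanced_tree_newick)
    df = pd.DataFrame({"species": list(reversed(corr.species)),
                       "estimate": [0.1, 0.2, 0.3, 0.4]})
    lam, p = pagels_lambda(df, corr)  # must not raise; alignment by name
    assert 0.0 <= lam <= 1.0
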