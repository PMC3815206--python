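"""Cluster curation: threshold filters, pan-orthologs, paralog rules,
discordance flagging, and RBH recovery on simulated data."""

import pytest

import alphacomp.simulate as sim
from alphacomp import clustering as cl
from alphacomp.io_formats import ClusterSet, read_newick


def _cluster_set(spec: dict[str, list[tuple[str, str]]], taxa) -> ClusterSet:
    return ClusterSet(spec, frozenset(taxa))


TAXA4 = ["A", "B", "C", "D"]


def _members(counts: dict[str, int], cid: str) -> list[tuple[str, str]]:
    out = []
    for genome, k in counts.items():
        out += [(genome, f"{genome}|{cid}_{i}") for i in range(k)]
    return out


@pytest.fixture
def toy_clusters() -> ClusterSet:
    """Five clusters with taxa counts 4,4,3,2,4; max copies 1,4,1,1,2;
    sizes 4,7,3,2,5."""
    spec = {
        "c1": _members({"A": 1, "B": 1, "C": 1, "D": 1}, "c1"),
        "c2": _members({"A": 4, "B": 1, "C": 1, "D": 1}, "c2"),
        "c3": _members({"A": 1, "B": 1, "C": 1}, "c3"),
        "c4": _members({"A": 1, "B": 1}, "c4"),
        "c5": _members({"A": 2, "B": 1, "C": 1, "D": 1}, "c5"),
    }
    return _cluster_set(spec, TAXA4)


def test_filter_toy_set_keeps_1_3_5(toy_clusters):
    """Enumerating the three predicates by hand over the toy set:
    c2 fails copies and size, c4 fails taxa coverage."""
    params = cl.ClusterFilterParams(3, 3, 6)
    kept, report = cl.filter_clusters(toy_clusters, params)
    assert sorted(kept.clusters) == ["c1", "c3", "c5"]
    assert report["taxa"] == 1 and report["copies"] == 1 and report["size"] == 1
    assert report["kept"] == 3


def test_filter_is_idempotent(toy_clusters):
    params = cl.ClusterFilterParams(3, 3, 6)
    kept, _ = cl.filter_clusters(toy_clusters, params)
    again, report = cl.filter_clusters(kept, params)
    assert again.clusters == kept.clusters
    assert report["kept"] == report["total"]


def test_filter_rejects_inconsistent_params(toy_clusters):
    with pytest.raises(ValueError):
        cl.filter_clusters(toy_clusters, cl.ClusterFilterParams(5, 3, 6))


def test_pan_orthologs_require_exactly_one_copy_everywhere(toy_clusters):
    pan = cl.find_pan_orthologs(toy_clusters)
    assert sorted(pan.clusters) == ["c1"]  # c3 misses D, c5 duplicates in A


def test_pan_orthologs_equal_strictest_filter(toy_clusters):
    n = len(toy_clusters.taxa)
    pan = cl.find_pan_orthologs(toy_clusters)
    strict, _ = cl.filter_clusters(toy_clusters, cl.ClusterFilterParams(n, 1, n))
    assert pan.clusters == strict.clusters


# ---------------------------------------------------------------------------
# Paralog resolution
# ---------------------------------------------------------------------------

def _resolve(newick: str, members, ingroup, outgroup=None):
    return cl.resolve_paralogs(
        "OG1", members, read_newick(newick), set(ingroup), set(outgroup or ())
    )


def test_sister_paralogs_keep_shortest_branch():
    members = [("a", "a|1"), ("a", "a|2"), ("b", "b|1"), ("c", "c|1")]
    tree = "((a|1:0.1,a|2:0.3):0.2,(b|1:0.1,c|1:0.1):0.2);"
    decisions, pruned = _resolve(tree, members, "abc")
    assert [d.action for d in decisions] == ["keep_shortest_branch"]
    assert decisions[0].affected == ("a|2",)
    assert ("a", "a|1") in pruned and ("a", "a|2") not in pruned


def test_shortest_branch_tie_keeps_lexicographically_smallest():
    members = [("a", "a|1"), ("a", "a|2"), ("b", "b|1"), ("c", "c|1")]
    tree = "((a|2:0.1,a|1:0.1):0.2,(b|1:0.1,c|1:0.1):0.2);"
    decisions, pruned = _resolve(tree, members, "abc")
    assert decisions[0].affected == ("a|2",)


def test_copy_inside_outgroup_clade_is_removed():
    members = [("a", "a|1"), ("a", "a|2"), ("b", "b|1"),
               ("o", "o|1"), ("p", "p|1")]
    tree = "((a|1:0.1,b|1:0.1):0.2,((o|1:0.1,a|2:0.1):0.1,p|1:0.1):0.2);"
    decisions, pruned = _resolve(tree, members, "ab", "op")
    actions = {d.action for d in decisions}
    assert actions == {"remove_outgroup_copy"}
    assert ("a", "a|2") not in pruned and ("a", "a|1") in pruned


def test_paralogs_at_different_positions_remove_whole_cluster():
    members = [("a", "a|1"), ("a", "a|2"), ("b", "b|1"), ("c", "c|1")]
    tree = "((a|1:0.1,b|1:0.1):0.2,(a|2:0.1,c|1:0.1):0.2);"
    decisions, pruned = _resolve(tree, members, "abc")
    assert [d.action for d in decisions] == ["remove_cluster"]
    assert pruned == []


def test_scattered_outgroup_copies_all_removed():
    members = [("a", "a|1"), ("b", "b|1"), ("c", "c|1"),
               ("o", "o|1"), ("o", "o|2"), ("p", "p|1")]
    tree = ("((a|1:0.1,b|1:0.1):0.2,"
            "((o|1:0.1,p|1:0.1):0.1,(o|2:0.1,c|1:0.1):0.1):0.2);")
    decisions, pruned = _resolve(tree, members, "abc", "op")
    assert any(d.action == "remove_all_copies" for d in decisions)
    assert all(g != "o" for g, _ in pruned)


def test_resolution_never_increases_copy_number():
    members = [("a", "a|1"), ("a", "a|2"), ("b", "b|1"), ("c", "c|1")]
    tree = "((a|1:0.1,a|2:0.3):0.2,(b|1:0.1,c|1:0.1):0.2);"
    _, pruned = _resolve(tree, members, "abc")
    per_genome = {}
    for g, _ in pruned:
        per_genome[g] = per_genome.get(g, 0) + 1
    assert all(v <= 1 for v in per_genome.values())


def test_tree_cluster_leaf_mismatch_is_error():
    members = [("a", "a|1"), ("b", "b|1"), ("c", "c|1")]
    tree = "((a|1:0.1,x|9:0.1):0.1,(b|1:0.1,c|1:0.1):0.1);"
    with pytest.raises(ValueError, match="not in cluster"):
        _resolve(tree, members, "abc")


# ---------------------------------------------------------------------------
# Discordance
# ---------------------------------------------------------------------------

SPECIES6 = "(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):2);"


def _brute_force_incompatible(side_a: set, side_b: set, universe: set) -> bool:
    """Two splits conflict iff all four intersections are non-empty."""
    ca, cb = universe - side_a, universe - side_b
    return all([side_a & side_b, side_a & cb, ca & side_b, ca & cb])


def test_identical_tree_is_concordant():
    t = read_newick(SPECIES6)
    s = read_newick(SPECIES6)
    assert cl.discordance_flag(t, s) == "concordant"


def test_strongly_supported_conflict_is_discordant():
    # {a, c} vs the species split {a, b}: verify the conflict by brute force
    universe = set("abcdef")
    assert _brute_force_incompatible({"a", "c"}, {"a", "b"}, universe)
    conflicted = "(((a:1,c:1)0.95:1,(b:1,d:1)0.95:1):1,(e:1,f:1)0.95:2);"
    assert cl.discordance_flag(read_newick(conflicted), read_newick(SPECIES6)) == "discordant"


def test_weakly_supported_conflict_is_concordant():
    conflicted = "(((a:1,c:1)0.5:1,(b:1,d:1)0.5:1):1,(e:1,f:1)0.5:2);"
    assert (
        cl.discordance_flag(read_newick(conflicted), read_newick(SPECIES6), 0.9)
        == "concordant"
    )


def test_support_scale_0_100_normalized():
    conflicted = "(((a:1,c:1)95:1,(b:1,d:1)95:1):1,(e:1,f:1)95:2);"
    assert cl.discordance_flag(read_newick(conflicted), read_newick(SPECIES6)) == "discordant"


# ---------------------------------------------------------------------------
# RBH clustering
# ---------------------------------------------------------------------------

def test_rbh_recovers_truth_at_zero_divergence():
    cfg = sim.SimulationConfig(
        n_taxa=4, root_gene_count=25, protein_length_mean=60.0,
        protein_length_sd=10.0, gain_rate=0.0, loss_rate=0.0, dup_rate=0.0,
        inversion_rate=0.0, translocation_rate=0.0, subst_rate=0.0, seed=5,
    )
    ds = sim.simulate_dataset(cfg)
    rbh = cl.rbh_cluster(ds.proteomes)
    truth = {frozenset(m) for m in ds.truth.clusters.clusters.values()}
    found = {frozenset(m) for m in rbh.clusters.values()}
    assert found == truth


def test_rbh_recovers_most_clusters_under_moderate_divergence():
    cfg = sim.SimulationConfig(
        n_taxa=5, root_gene_count=40, protein_length_mean=80.0,
        protein_length_sd=15.0, gain_rate=0.0, loss_rate=0.0, dup_rate=0.0,
        inversion_rate=0.0, translocation_rate=0.0, subst_rate=0.15, seed=9,
    )
    ds = sim.simulate_dataset(cfg)
    rbh = cl.rbh_cluster(ds.proteomes)
    truth = {frozenset(m) for m in ds.truth.clusters.clusters.values()}
    found = {frozenset(m) for m in rbh.clusters.values()}
    assert len(truth & found) / len(truth) >= 0.95
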