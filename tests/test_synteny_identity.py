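"""Synteny and normalized-bit-score identity: worked toys, an independent
adjacency-set oracle, permutation null, degradation trends, pair classes,
and outlier fencing."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import alphacomp.simulate as sim
from alphacomp import synteny_identity as syn
from alphacomp.io_formats import TaxonomyTable


# ---------------------------------------------------------------------------
# Normalized bit score
# ---------------------------------------------------------------------------

def test_normalized_bitscore_worked_example():
    assert syn.normalized_bitscore(50, 200, 100) == pytest.approx(0.5)


def test_normalized_bitscore_clips_to_unit_interval():
    assert syn.normalized_bitscore(150, 200, 100) == 1.0
    assert syn.normalized_bitscore(-3, 200, 100) == 0.0


def test_identical_sequences_score_one():
    s = "MKVLGAARPW" * 8
    bits = syn.karlin_altschul_bits(syn.sw_score(s, s))
    self_bits = syn.karlin_altschul_bits(syn.self_score(s))
    assert syn.normalized_bitscore(bits, self_bits, self_bits) == pytest.approx(1.0)


def test_pair_identity_is_mean_of_normalized_scores():
    pm = syn.OrthologPairMap(
        "A", "B",
        [("a1", "b1", 40.0, 100.0, 120.0), ("a2", "b2", 60.0, 100.0, 110.0)],
    )
    assert syn.pair_identity(pm) == pytest.approx((0.4 + 0.6) / 2)


def test_pair_map_rejects_non_bijective_mapping():
    with pytest.raises(ValueError, match="one-to-one"):
        syn.OrthologPairMap(
            "A", "B",
            [("a1", "b1", 1.0, 2.0, 2.0), ("a1", "b2", 1.0, 2.0, 2.0)],
        )


# ---------------------------------------------------------------------------
# Synteny fraction
# ---------------------------------------------------------------------------

IDENT = {f"g{i}": f"g{i}" for i in range(1, 7)}


def test_identical_orders_fully_syntenic():
    order = [f"g{i}" for i in range(1, 7)]
    assert syn.synteny_fraction(order, order, IDENT) == 1.0


def test_reversed_order_fully_syntenic():
    order = [f"g{i}" for i in range(1, 7)]
    assert syn.synteny_fraction(order, order[::-1], IDENT) == 1.0


def test_shuffled_toy_keeps_only_g4_g5():
    a = [f"g{i}" for i in range(1, 7)]
    b = ["g3", "g1", "g4", "g5", "g2", "g6"]
    assert syn.synteny_fraction(a, b, IDENT) == pytest.approx(2 / 6)


def test_fully_scrambled_toy_has_no_synteny():
    a = [f"g{i}" for i in range(1, 6)]
    b = ["g1", "g3", "g5", "g2", "g4"]
    mapping = {f"g{i}": f"g{i}" for i in range(1, 6)}
    assert syn.synteny_fraction(a, b, mapping) == 0.0


def test_symmetric_in_genome_order():
    rng = np.random.default_rng(0)
    a = [f"g{i}" for i in range(30)]
    b = list(rng.permutation(a))
    mapping = {g: g for g in a}
    inv = {v: k for k, v in mapping.items()}
    assert syn.synteny_fraction(a, b, mapping) == syn.synteny_fraction(b, a, inv)


def test_circular_wrap_adjacency_counts():
    # linear: ends g1,g4 not adjacent; circular: the ring closes
    a = ["g1", "g2", "g3", "g4"]
    b = ["g2", "g3", "g4", "g1"]
    mapping = {g: g for g in a}
    assert syn.synteny_fraction(a, b, mapping, circular_a=True, circular_b=True) == 1.0
    assert syn.synteny_fraction(a, b, mapping) < 1.0


def _oracle_synteny(order_a, order_b, mapping):
    """Brute-force O(n^2): for each shared gene scan both full orders for
    its neighbours, then test conservation pair by pair."""
    a = [g for g in order_a if g in mapping]
    bmap = {v: k for k, v in mapping.items()}
    b = [g for g in order_b if g in bmap]
    pos_b = {g: i for i, g in enumerate(b)}
    count = 0
    for i, g in enumerate(a):
        neighbours = [a[j] for j in (i - 1, i + 1) if 0 <= j < len(a)]
        hit = False
        for n in neighbours:
            pi, pj = pos_b[mapping[g]], pos_b[mapping[n]]
            if abs(pi - pj) == 1:
                hit = True
        if hit:
            count += 1
    return count / len(a)


def test_matches_brute_force_oracle_on_random_permutations():
    rng = np.random.default_rng(42)
    for _ in range(500):
        n = int(rng.integers(2, 201))
        genes = [f"g{i}" for i in range(n)]
        a = list(rng.permutation(genes))
        b = list(rng.permutation(genes))
        mapping = {g: g for g in genes}
        assert syn.synteny_fraction(a, b, mapping) == pytest.approx(
            _oracle_synteny(a, b, mapping)
        )


def test_random_permutation_synteny_matches_monte_carlo_expectation():
    """Observed mean synteny of random permutations at n=50 sits within
    3 SE of the brute-force permutation oracle's Monte-Carlo mean."""
    n, reps = 50, 1000
    genes = [f"g{i}" for i in range(n)]
    mapping = {g: g for g in genes}
    rng_oracle = np.random.default_rng(7)
    oracle_vals = [
        _oracle_synteny(genes, list(rng_oracle.permutation(genes)), mapping)
        for _ in range(reps)
    ]
    mu = np.mean(oracle_vals)
    se = np.std(oracle_vals, ddof=1) / np.sqrt(reps)
    rng_obs = np.random.default_rng(8)
    observed = np.mean(
        [
            syn.synteny_fraction(genes, list(rng_obs.permutation(genes)), mapping)
            for _ in range(reps)
        ]
    )
    assert mu < 0.25  # random gene order retains little adjacency
    assert abs(observed - mu) < 3 * se


def test_median_synteny_degrades_with_inversion_count():
    """Applying k = 0..20 random inversions to a 200-gene order yields
    median synteny strongly decreasing in k."""
    n, reps = 200, 50
    genes = [f"g{i}" for i in range(n)]
    mapping = {g: g for g in genes}
    rng = np.random.default_rng(3)
    medians = []
    for k in range(21):
        vals = []
        for _ in range(reps):
            order = list(genes)
            for _ in range(k):
                i, j = sorted(rng.integers(0, n, size=2))
                order[i : j + 1] = order[i : j + 1][::-1]
            vals.append(syn.synteny_fraction(genes, order, mapping))
        medians.append(np.median(vals))
    rho, _ = spearmanr(range(21), medians)
    assert rho < -0.9


# ---------------------------------------------------------------------------
# Pair classes, scan, outliers
# ---------------------------------------------------------------------------

TAX = TaxonomyTable(
    {
        "A": ("g1", "f1", "o1"),
        "B": ("g1", "f1", "o1"),
        "C": ("g2", "f1", "o1"),
        "D": ("g3", "f2", "o1"),
        "E": ("g4", "f3", "o2"),
    }
)


@pytest.mark.parametrize(
    "pair,expected",
    [
        (("A", "B"), "within_genus"),
        (("A", "C"), "within_family"),
        (("A", "D"), "within_order"),
        (("A", "E"), "between_orders"),
    ],
)
def test_classify_pair_most_specific_stratum(pair, expected):
    assert syn.classify_pair(*pair, TAX) == expected


def test_pair_scan_emits_all_pairs_at_identity_one(zero_rate_dataset):
    ds = zero_rate_dataset
    tax = sim.taxonomy_from_tree(ds.truth.species_tree)
    records = syn.pair_scan(
        ds.annotations, ds.proteomes, ds.truth.clusters, tax, mode="clusters"
    )
    n = len(ds.annotations)
    assert len(records) == n * (n - 1) // 2
    for r in records:
        assert r.avg_norm_bitscore == pytest.approx(1.0)
        assert r.synteny_fraction == 1.0


def test_within_clade_pairs_more_syntenic_than_cross(rogue_preset, rogue_dataset):
    ds = rogue_dataset
    tax = sim.taxonomy_from_tree(ds.truth.species_tree)
    records = syn.pair_scan(
        ds.annotations, ds.proteomes, ds.truth.clusters, tax,
        mode="clusters", compute_identity=False,
    )
    clade = set(rogue_preset.focal_clade)
    within = [
        r.synteny_fraction for r in records
        if r.genome_a in clade and r.genome_b in clade
    ]
    cross = [
        r.synteny_fraction for r in records
        if (r.genome_a in clade) != (r.genome_b in clade)
    ]
    assert np.mean(within) > np.mean(cross)


def _record(cat, x, y, i):
    return syn.PairRecord(f"A{i}", f"B{i}", cat, 10, x, y)


def test_flag_outliers_finds_planted_extreme():
    xs = np.linspace(0.45, 0.55, 20)
    ys = np.linspace(0.40, 0.50, 20)
    records = [
        _record("between_orders", x, y, i) for i, (x, y) in enumerate(zip(xs, ys))
    ]
    planted = _record("between_orders", 0.95, 0.95, 99)
    flagged = syn.flag_outliers(records + [planted])
    assert flagged == [planted]


def test_flag_outliers_empty_or_uniform_categories():
    assert syn.flag_outliers([]) == []
    uniform = [_record("within_genus", 0.8, 0.9, i) for i in range(10)]
    assert syn.flag_outliers(uniform) == []
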