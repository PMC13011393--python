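import numpy as np
import pytest

import betanull.phylo as phylo_mod
from betanull.phylo import (
    PairwiseProcessMetrics,
    Phylogeny,
    beta_mntd,
    beta_nti,
    classify_process,
    partition_processes,
    rc_bray,
    region_process_metrics,
)
from betanull.tables import CommunityTable, pool_region


def brute_force_mntd(x, y, dist, weighted):
    """Independent double-loop oracle."""
    sx = [i for i in range(len(x)) if x[i] > 0]
    sy = [i for i in range(len(y)) if y[i] > 0]
    tx = sum(x[i] for i in sx)
    ty = sum(y[i] for i in sy)
    acc_x = 0.0
    for i in sx:
        dmin = min(dist[i][j] for j in sy)
        acc_x += (x[i] / tx if weighted else 1.0 / len(sx)) * dmin
    acc_y = 0.0
    for j in sy:
        dmin = min(dist[j][i] for i in sx)
        acc_y += (y[j] / ty if weighted else 1.0 / len(sy)) * dmin
    return 0.5 * (acc_x + acc_y)


THREE_TIP = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])


class TestBetaMntd:
    def test_identity_is_zero(self):
        x = np.array([3, 0, 2])
        assert beta_mntd(x, x, THREE_TIP) == 0.0

    def test_three_tip_hand_example(self):
        x = np.array([1, 0, 0])  # {A}
        y = np.array([0, 1, 0])  # {B}
        assert beta_mntd(x, y, THREE_TIP, weighted=False) == pytest.approx(2.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.random((8, 8))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            x = rng.integers(0, 5, 8)
            y = rng.integers(0, 5, 8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            v = beta_mntd(x, y, d)
            assert v >= 0
            assert v == pytest.approx(beta_mntd(y, x, d))

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(7)
        for _ in range(50):
            d = rng.random((10, 10)) * 5
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            x = rng.integers(0, 6, 10)
            y = rng.integers(0, 6, 10)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert beta_mntd(x, y, d, weighted=weighted) == pytest.approx(
                brute_force_mntd(x.tolist(), y.tolist(), d.tolist(), weighted),
                abs=1e-10,
            )

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            beta_mntd(np.zeros(3), np.array([1, 0, 0]), THREE_TIP)

    def test_uncovered_taxon_rejected(self):
        x = np.array([0, 0, 0, 1])
        y = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError):
            beta_mntd(x, y, THREE_TIP)


class TestBetaNti:
    def test_star_phylogeny_degenerate(self):
        n = 6
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        x = np.array([1, 1, 0, 0, 0, 0])
        y = np.array([0, 0, 1, 1, 0, 0])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert np.isnan(beta_nti(x, y, d, n_null=99, seed=0))

    def test_n_null_floor(self):
        with pytest.raises(ValueError):
            beta_nti(np.array([1, 0, 0]), np.array([0, 1, 0]), THREE_TIP, n_null=10)

    def test_clade_split_strong_positive(self):
        # two 5-tip clades far apart; one community per clade -> betaNTI > 2
        within = np.random.default_rng(1).random((10, 10)) * 0.1
        d = (within + within.T) / 2
        d[:5, 5:] += 10.0
        d[5:, :5] += 10.0
        np.fill_diagonal(d, 0.0)
        x = np.array([1] * 5 + [0] * 5)
        y = np.array([0] * 5 + [1] * 5)
        assert beta_nti(x, y, d, n_null=199, seed=0) > 2


def make_pool(counts):
    n_taxa, n_samples = counts.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    table = CommunityTable(
        [f"t{i}" for i in range(n_taxa)],
        sample_ids,
        counts,
        {s: "R" for s in sample_ids},
    )
    return table, pool_region(table, "R")


class TestRcBray:
    def test_range_and_reproducibility(self):
        rng = np.random.default_rng(3)
        counts = rng.multinomial(30, np.full(6, 1 / 6), size=4).T
        _, pool = make_pool(counts)
        full = np.zeros(6, dtype=np.int64)
        full[pool.taxa_idx] = 0
        x = counts[pool.taxa_idx, 0]
        y = counts[pool.taxa_idx, 1]
        a = rc_bray(x, y, pool, n_null=199, seed=5)
        b = rc_bray(x, y, pool, n_null=199, seed=5)
        assert -1.0 <= a <= 1.0
        assert a == b

    def test_boundaries_via_stubbed_null(self, monkeypatch):
        counts = np.array([[4, 1], [1, 4]])
        _, pool = make_pool(counts)
        # null always identical pair -> null BC = 0 < obs -> RC = +1
        monkeypatch.setattr(
            phylo_mod,
            "draw_null_sample_counts",
            lambda rng, rel, freq, richness, total: np.array([3, 2]),
        )
        assert rc_bray(counts[:, 0], counts[:, 1], pool, n_null=100, seed=0) == 1.0
        # null always maximally different -> null BC = 1 > obs -> RC = -1
        state = {"flip": False}

        def alternating(rng, rel, freq, richness, total):
            state["flip"] = not state["flip"]
            return np.array([5, 0]) if state["flip"] else np.array([0, 5])

        monkeypatch.setattr(phylo_mod, "draw_null_sample_counts", alternating)
        assert rc_bray(counts[:, 0], counts[:, 1], pool, n_null=100, seed=0) == -1.0

    def test_all_ties_give_zero(self):
        # gamma = 1: every null sample equals the observed one
        counts = np.array([[5, 3]])
        _, pool = make_pool(counts)
        assert rc_bray(counts[:, 0], counts[:, 1], pool, n_null=99, seed=1) == 0.0

    def test_richness_exceeding_gamma_rejected(self):
        counts = np.array([[4, 1], [1, 4]])
        _, pool = make_pool(counts)
        with pytest.raises(ValueError):
            rc_bray(np.array([1, 1, 1]), np.array([1, 1, 0]), pool, n_null=99)


class TestClassify:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (-3.0, 0.0, "HoS"),
            (3.0, 0.0, "HeS"),
            (1.0, 0.99, "DL"),
            (0.0, -0.99, "HD"),
            (0.0, 0.0, "DR"),
            (2.0, 0.96, "DL"),  # boundary: |bnti| <= 2 falls through to RC
            (-2.0, -0.5, "DR"),
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_process(bnti, rc) == expected

    def test_custom_thresholds(self):
        assert classify_process(1.5, 0.0, bnti_threshold=1.0) == "HeS"
        assert classify_process(0.0, 0.9, rc_threshold=0.8) == "DL"

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_process(float("nan"), 0.0)

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            label = classify_process(rng.normal(0, 3), rng.uniform(-1, 1))
            assert label in {"HeS", "HoS", "HD", "DL", "DR"}


def _metric(process, bnti=0.0):
    return PairwiseProcessMetrics(
        region="R",
        sample_i="a",
        sample_j="b",
        bray_curtis=0.5,
        beta_mntd_obs=1.0,
        beta_nti=bnti,
        rc_bray=0.0,
        process=process,
    )


class TestPartition:
    def test_forced_single_label(self):
        part = partition_processes([_metric("HoS", -3.0)] * 4)
        assert part.fractions == {"HeS": 0, "HoS": 1.0, "HD": 0, "DL": 0, "DR": 0}

    def test_counting(self):
        metrics = [_metric(p) for p in ["HeS", "HoS", "DR", "DR"]]
        part = partition_processes(metrics)
        assert part.fractions == {
            "HeS": 0.25,
            "HoS": 0.25,
            "DR": 0.5,
            "HD": 0.0,
            "DL": 0.0,
        }

    def test_undefined_pairs_excluded_with_warning(self):
        metrics = [_metric("DR"), _metric(None)]
        metrics[1].process = None
        with pytest.warns(RuntimeWarning, match="undefined"):
            part = partition_processes(metrics)
        assert part.n_pairs == 1

    def test_fractions_sum_to_one_random(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            labels = rng.choice(["HeS", "HoS", "HD", "DL", "DR"], size=rng.integers(1, 30))
            part = partition_processes([_metric(p) for p in labels])
            assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            partition_processes([])


class TestPhylogeny:
    def test_from_newick_patristic(self, tmp_path):
        p = tmp_path / "tree.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        tree = Phylogeny.from_newick(p)
        d = tree.submatrix(["A", "B", "C"])
        np.testing.assert_allclose(d, THREE_TIP)

    def test_missing_taxon_named(self, tmp_path):
        p = tmp_path / "tree.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        tree = Phylogeny.from_newick(p)
        with pytest.raises(KeyError, match="Z"):
            tree.submatrix(["A", "Z"])

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            Phylogeny(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            Phylogeny(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestRegionProcessMetrics:
    @pytest.mark.parametrize("shuffle_pool", ["tree", "region"])
    def test_smoke_and_contracts(self, shuffle_pool):
        rng = np.random.default_rng(4)
        counts = rng.multinomial(10, np.full(24, 1 / 24), size=5).T
        table, _ = make_pool(counts)
        d = rng.random((24, 24))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = Phylogeny([f"t{i}" for i in range(24)], d)
        metrics = region_process_metrics(
            table, "R", tree, n_null=99, seed=0, shuffle_pool=shuffle_pool
        )
        assert len(metrics) == 10  # 5 choose 2
        for m in metrics:
            assert -1.0 <= m.rc_bray <= 1.0
            assert m.process in {"HeS", "HoS", "HD", "DL", "DR"}
        part = partition_processes(metrics)
        assert sum(part.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_shuffle_pool(self, region_table):
        tree = Phylogeny(
            list(region_table.taxa_ids), np.zeros((6, 6))
        )
        with pytest.raises(ValueError):
            region_process_metrics(region_table, "R", tree, shuffle_pool="global")
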