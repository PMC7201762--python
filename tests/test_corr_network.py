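import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokesig.corr_network import (
    DCSConfig,
    bicor,
    build_weight_network,
    correlate_probes_genes,
    dcs_select,
    intersect_sets,
    pick_soft_threshold,
    spearman_rho,
)


def bicor_oracle(x, y):
    """Literal definitional formula, written independently of the package."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def norm(v):
        med = np.median(v)
        u = (v - med) / (9 * np.median(np.abs(v - med)))
        a = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        d = a * (v - med)
        return d / np.sqrt(np.sum(d**2))

    return float(np.dot(norm(x), norm(y)))


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_positive_affine_equivariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert bicor(x, 3.0 * y + 7.0) == pytest.approx(bicor(x, y), abs=1e-12)

    def test_matches_definitional_oracle(self, rng):
        for _ in range(25):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_outlier_robustness_beats_pearson(self, rng):
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=200)
            z[0] = [10.0, -10.0]  # one gross contaminating point
            b = bicor(z[:, 0], z[:, 1])
            p = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
            wins += abs(b - 0.8) < abs(p - 0.8)
        assert wins >= 0.9 * n_rep

    def test_zero_mad_fallback_and_error_modes(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 9.0])  # MAD = 0
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="zero MAD"):
            bicor(x, y)
        with pytest.raises(ValueError):
            bicor(x, y, zero_mad="error")

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            bicor([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_close_to_pearson_on_clean_gaussian(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=500)
        b = bicor(z[:, 0], z[:, 1])
        p = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
        assert abs(b - p) < 0.02


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=30)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_midrank_ties_match_scipy_enumeration(self, rng):
        from scipy import stats

        for _ in range(10):
            x = rng.integers(0, 3, size=5).astype(float)
            y = rng.integers(0, 3, size=5).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            # midrank Pearson computed directly
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelateProbesGenes:
    def test_planted_pairs_show_differential_correlation(self, small_study):
        sig = sorted(small_study.truth_signature_probes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = correlate_probes_genes(
                small_study.methylation.loc[sig],
                small_study.expression,
                small_study.metadata,
                method="spearman",
            )
        detail = small_study.dcs_detail.set_index(["probe_id", "gene_id"])
        hits = table.set_index(["probe_id", "gene_id"]).loc[detail.index]
        for (probe, gene), row in hits.iterrows():
            coupled = detail.loc[(probe, gene), "coupled_group"]
            hi = row["r_current"] if coupled == "current" else row["r_never"]
            lo = row["r_never"] if coupled == "current" else row["r_current"]
            assert abs(hi) > abs(lo)

    def test_methods_agree_on_clean_gaussian(self, rng):
        n = 100
        samples = [f"S{i}" for i in range(2 * n)]
        rho = 0.7
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2 * n)
        meth = pd.DataFrame(
            (z[:, 0:1].T - z[:, 0].min()) / np.ptp(z[:, 0]), index=["cg1"], columns=samples
        )
        expr = pd.DataFrame(z[:, 1:2].T, index=["G1"], columns=samples)
        from conftest import make_metadata

        meta = make_metadata(samples, ["current"] * n + ["never"] * n)
        for method in ("bicor", "spearman"):
            t = correlate_probes_genes(meth, expr, meta, method=method)
            assert t["r_current"].iloc[0] == pytest.approx(rho, abs=0.15)
            assert t["r_never"].iloc[0] == pytest.approx(rho, abs=0.15)

    def test_constant_gene_skipped_with_warning(self, rng):
        samples = [f"S{i}" for i in range(20)]
        meth = pd.DataFrame(
            rng.uniform(size=(1, 20)), index=["cg1"], columns=samples
        )
        expr = pd.DataFrame(np.full((1, 20), 5.0), index=["G1"], columns=samples)
        from conftest import make_metadata

        meta = make_metadata(samples, ["current"] * 10 + ["never"] * 10)
        with pytest.warns(UserWarning, match="skipped"):
            t = correlate_probes_genes(meth, expr, meta, method="spearman")
        assert t[["r_current", "r_never"]].isna().any(axis=None)

    def test_small_group_rejected(self, rng):
        samples = [f"S{i}" for i in range(8)]
        meth = pd.DataFrame(rng.uniform(size=(1, 8)), index=["cg1"], columns=samples)
        expr = pd.DataFrame(rng.normal(size=(1, 8)), index=["G1"], columns=samples)
        from conftest import make_metadata

        meta = make_metadata(samples, ["current"] * 5 + ["never"] * 3)
        with pytest.raises(ValueError, match="never"):
            correlate_probes_genes(meth, expr, meta)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "method", "r_current", "r_never"]
    )


class TestDcsSelect:
    @pytest.mark.parametrize(
        "rc,rn,expected",
        [
            (0.8, 0.1, True),  # high in current, low in never
            (0.5, 0.5, False),  # neither side crosses
            (0.6, 0.3, True),  # inclusive boundary
            (-0.7, 0.2, True),  # magnitudes, not signs
            (0.1, -0.9, True),  # symmetric in the two groups
            (0.8, 0.45, False),  # high but not low enough in the other
        ],
    )
    def test_rule_examples(self, rc, rn, expected):
        t = _table([("cg1", "G1", "bicor", rc, rn)])
        selected, genes = dcs_select(t)
        assert (len(selected) == 1) is expected
        assert (genes == ["G1"]) is expected

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DCSConfig(ts1=0.6, ts2=0.3)

    @given(
        st.floats(0.0, 0.29),
        st.floats(0.61, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_thresholds(self, ts1, ts2):
        rng = np.random.default_rng(99)
        t = _table(
            [
                (f"cg{i}", f"G{i}", "bicor", rc, rn)
                for i, (rc, rn) in enumerate(
                    zip(rng.uniform(-1, 1, 80), rng.uniform(-1, 1, 80))
                )
            ]
        )
        base, _ = dcs_select(t, DCSConfig(ts1=0.3, ts2=0.6))
        tighter_ts2, _ = dcs_select(t, DCSConfig(ts1=0.3, ts2=ts2))
        tighter_ts1, _ = dcs_select(t, DCSConfig(ts1=ts1, ts2=0.6))
        # raising TS2 never adds pairs; lowering TS1 never adds pairs
        assert set(map(tuple, tighter_ts2[["probe_id", "gene_id"]].values)) <= set(
            map(tuple, base[["probe_id", "gene_id"]].values)
        )
        assert set(map(tuple, tighter_ts1[["probe_id", "gene_id"]].values)) <= set(
            map(tuple, base[["probe_id", "gene_id"]].values)
        )


class TestWeightNetwork:
    def test_perfect_correlation_gives_full_connectivity(self):
        base = np.arange(10.0)
        expr = pd.DataFrame(
            [base, 2 * base + 1, -base + 5, 3 * base],
            index=["G1", "G2", "G3", "G4"],
        )
        net = build_weight_network(expr, beta_soft=6)
        assert np.allclose(net.connectivity, 3.0)

    def test_large_power_sends_connectivity_to_zero(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 40)), index=[f"G{i}" for i in range(6)])
        net = build_weight_network(expr, beta_soft=200.0)
        assert net.connectivity.max() < 1e-6

    def test_hub_threshold_flags_constructed_module(self, rng):
        # 34 genes: 9 share a near-unit loading on a latent factor, the
        # other 25 load at 0.8; with beta_soft=6 the 9 exceed k=10.75 and
        # the 25 stay well below.
        n = 500
        g = rng.normal(size=n)
        rows = []
        names = []
        for i in range(9):
            rows.append(0.999 * g + np.sqrt(1 - 0.999**2) * rng.normal(size=n))
            names.append(f"HUB{i}")
        for i in range(25):
            rows.append(0.8 * g + 0.6 * rng.normal(size=n))
            names.append(f"LEAF{i}")
        net = build_weight_network(pd.DataFrame(rows, index=names), beta_soft=6)
        assert sorted(net.hubs) == sorted(f"HUB{i}" for i in range(9))

    def test_constant_gene_excluded(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.normal(size=(3, 20)), np.full((1, 20), 2.0)]),
            index=["G1", "G2", "G3", "FLAT"],
        )
        with pytest.warns(UserWarning, match="constant"):
            net = build_weight_network(expr)
        assert "FLAT" not in net.genes

    def test_sample_permutation_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)), index=[f"G{i}" for i in range(5)])
        perm = rng.permutation(expr.columns)
        a = build_weight_network(expr).adjacency
        b = build_weight_network(expr[perm]).adjacency
        pd.testing.assert_frame_equal(a, b)

    def test_soft_threshold_chooser_returns_power(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 60)))
        expr.iloc[:10] += rng.normal(size=60) * 2  # one co-expressed block
        power = pick_soft_threshold(expr, powers=range(1, 8))
        assert 1 <= power <= 7


class TestIntersectSets:
    def test_basic_overlap(self):
        r = intersect_sets({"A", "B", "C"}, {"B", "C", "D"})
        assert r.common_genes == ("B", "C")

    def test_disjoint(self):
        assert intersect_sets({"A"}, {"B"}).common_genes == ()

    def test_both_methods_recover_planted_genes(self, small_study):
        sig = sorted(small_study.truth_signature_probes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gene_sets = {}
            for method in ("bicor", "spearman"):
                t = correlate_probes_genes(
                    small_study.methylation.loc[sig],
                    small_study.expression,
                    small_study.metadata,
                    method=method,
                )
                _, gene_sets[method] = dcs_select(t)
        r = intersect_sets(gene_sets["bicor"], gene_sets["spearman"])
        truth_genes = {g for _, g in small_study.truth_dcs_pairs}
        assert len(set(r.common_genes) & truth_genes) >= 0.6 * len(truth_genes)
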