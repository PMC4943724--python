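import numpy as np
import pandas as pd
import pytest

from pleioscan import (
    GRM,
    TraitData,
    compute_grm,
    conditional_scan,
    fit_null,
    gwa_loco,
    loco_grms,
    score_test,
    score_test_batch,
)

from conftest import make_gm

rng = np.random.default_rng(20240917)


def make_trait(y, w=None, ids=None, h2=0.3):
    n = len(y)
    rec = pd.DataFrame(
        {
            "animal_id": ids if ids is not None else [f"ind{i}" for i in range(n)],
            "debv": np.asarray(y, dtype=float),
            "reliability": 1.0,
            "w": np.ones(n) if w is None else np.asarray(w, dtype=float),
        }
    )
    return TraitData(trait_id="T", h2=h2, records=rec)


def random_fit(n, seed=0, w=None):
    r = np.random.default_rng(seed)
    A = r.standard_normal((n, n))
    K = 0.5 * (A @ A.T / n + (A @ A.T / n).T)
    y = r.standard_normal(n)
    w = r.uniform(0.5, 2.0, n) if w is None else w
    grm = GRM(K, np.array([f"ind{i}" for i in range(n)]))
    return fit_null(make_trait(y, w), grm), K, y, w


class TestGRM:
    def test_hand_worked_vanraden(self):
        dos = np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [1, 2, 1]], dtype=float
        )
        gm = make_gm(dos)
        K = compute_grm(gm).K
        p = dos.mean(axis=0) / 2.0
        Z = dos - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_identical_genomes_share_relationship(self):
        dos = rng.binomial(2, 0.4, size=(5, 50)).astype(float)
        dos[1] = dos[0]
        K = compute_grm(make_gm(dos)).K
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_excluding_everything_raises(self):
        dos = rng.binomial(2, 0.4, size=(4, 6)).astype(float)
        gm = make_gm(dos, chroms=["1"] * 6)
        with pytest.raises(ValueError):
            compute_grm(gm, exclude_chromosome="1")

    def test_monomorphic_only_raises(self):
        gm = make_gm(np.full((4, 3), 2.0))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(gm)

    def test_loco_matches_per_chromosome_construction(self, small_genotypes):
        _, gm = small_genotypes
        grms = loco_grms(gm)
        direct = compute_grm(gm, exclude_chromosome="3")
        np.testing.assert_allclose(grms["3"].K, direct.K, atol=1e-9)
        assert grms["3"].n_markers_used == direct.n_markers_used


class TestFitNull:
    def test_identity_grm_reduces_to_ols(self):
        n = 200
        y = rng.standard_normal(n) * 2.0 + 1.3
        grm = GRM(np.eye(n), np.array([f"ind{i}" for i in range(n)]))
        fit = fit_null(make_trait(y), grm)
        assert fit.mu == pytest.approx(y.mean(), abs=1e-6)
        # only the sum sigma2_g + sigma2_e is identified under K = I, w = 1
        assert fit.sigma2_g + fit.sigma2_e == pytest.approx(
            y.var(ddof=1), rel=0.01
        )

    def test_weight_scale_confounding(self):
        # draw y from the model itself so the REML optimum is interior
        n = 80
        r = np.random.default_rng(3)
        A = r.standard_normal((n, n))
        K = 0.5 * (A @ A.T / n + (A @ A.T / n).T)
        w = r.uniform(0.5, 2.0, n)
        V0 = 0.6 * K + 0.4 * np.diag(w)
        y = np.linalg.cholesky(V0 + 1e-9 * np.eye(n)) @ r.standard_normal(n)
        grm = GRM(K, np.array([f"ind{i}" for i in range(n)]))
        fit1 = fit_null(make_trait(y, w), grm)
        fit2 = fit_null(make_trait(y, 2.0 * w), grm)
        # V = K sg2 + (2W)(se2/2) is the same model: same mu, same V
        assert fit2.mu == pytest.approx(fit1.mu, rel=1e-4, abs=1e-8)
        assert fit2.sigma2_g == pytest.approx(fit1.sigma2_g, rel=1e-4)
        assert fit2.sigma2_e == pytest.approx(fit1.sigma2_e / 2.0, rel=1e-4)
        np.testing.assert_allclose(fit2.V, fit1.V, rtol=1e-4, atol=1e-7)

    def test_objective_trace_nondecreasing(self):
        fit, *_ = random_fit(80, seed=4)
        trace = np.array(fit.opt_trace)
        assert np.all(np.diff(trace) >= 0)

    def test_misaligned_ids_raise(self):
        grm = GRM(np.eye(3), np.array(["a", "b", "c"]))
        with pytest.raises(ValueError, match="absent"):
            fit_null(make_trait([1.0, 2.0, 3.0], ids=["a", "b", "z"]), grm)


class TestScoreTest:
    def test_identity_v_equals_ols_slope(self):
        n = 100
        y = rng.standard_normal(n)
        x = rng.binomial(2, 0.3, n).astype(float)
        grm = GRM(np.eye(n), np.array([f"ind{i}" for i in range(n)]))
        fit = fit_null(make_trait(y), grm)
        mt = score_test(x, fit)
        xc = x - x.mean()
        slope = xc @ (y - y.mean()) / (xc @ xc)
        assert mt.b == pytest.approx(slope, rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_gls_oracle(self, seed):
        n = int(np.random.default_rng(seed).integers(5, 50))
        fit, K, y, w = random_fit(n, seed=seed + 100)
        x = np.random.default_rng(seed + 200).binomial(2, 0.4, n).astype(float)
        if np.ptp(x) == 0:
            x[0] = 2.0 - x[0]
        mt = score_test(x, fit)
        Vi = np.linalg.inv(fit.V)
        xc = x - x.mean()
        ys = y - fit.mu
        b = (xc @ Vi @ ys) / (xc @ Vi @ xc)
        se = 1.0 / np.sqrt(xc @ Vi @ xc)
        assert mt.b == pytest.approx(b, rel=1e-10)
        assert mt.se == pytest.approx(se, rel=1e-10)
        assert mt.t == pytest.approx(b / se, rel=1e-10)

    def test_v_orthogonal_dosage_gives_zero_effect(self):
        n = 8
        y = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0])
        grm = GRM(np.eye(n), np.array([f"ind{i}" for i in range(n)]))
        fit = fit_null(make_trait(y), grm)
        # centred x orthogonal to centred y under V = c I
        x = np.array([0.0, 2.0, 0.0, 2.0, 0.0, 2.0, 0.0, 2.0])
        mt = score_test(x, fit)
        assert mt.b == pytest.approx(0.0, abs=1e-12)
        assert mt.t == pytest.approx(0.0, abs=1e-12)

    def test_constant_marker_flagged(self):
        fit, *_ = random_fit(20, seed=9)
        mt = score_test(np.ones(20), fit)
        assert mt.reason == "constant_marker"
        assert mt.p == 1.0 and mt.b == 0.0

    def test_missing_dosages_mean_imputed(self):
        fit, K, y, w = random_fit(40, seed=10)
        x = np.random.default_rng(1).binomial(2, 0.4, 40).astype(float)
        x_miss = x.copy()
        x_miss[3] = np.nan
        x_imp = x.copy()
        x_imp[3] = np.delete(x, 3).mean()
        a = score_test(x_miss, fit)
        b = score_test(x_imp, fit)
        assert a.t == pytest.approx(b.t, rel=1e-12)


class TestLocoScan:
    def test_loco_invariant_to_excluded_chromosome_content(self, small_genotypes):
        _, gm = small_genotypes
        sub = gm.take_samples(np.arange(120))
        y = np.random.default_rng(5).standard_normal(120)
        trait = make_trait(y, ids=sub.sample_ids)
        grms = loco_grms(sub)
        tab1 = gwa_loco(sub, trait, grms)

        # permute the dosage columns of chromosome 2 among themselves:
        # chromosome-2 statistics must not change (its markers are excluded
        # from its own fold's GRM either way)
        perm = sub.markers_on("2")
        shuffled = perm[np.random.default_rng(6).permutation(perm.size)]
        dos = sub.dosages.copy()
        dos[:, perm] = dos[:, shuffled]
        gm2 = type(sub)(dos, sub.sample_ids, sub.marker_map.copy())
        tab2 = gwa_loco(gm2, trait, loco_grms(gm2))

        a = tab1[tab1["chrom"] == "2"].set_index("marker_id")["t"]
        b = tab2[tab2["chrom"] == "2"].set_index("marker_id")["t"]
        # same multiset of statistics, matched per marker id after permutation
        mapping = dict(
            zip(
                sub.marker_map.loc[perm, "marker_id"],
                sub.marker_map.loc[shuffled, "marker_id"],
            )
        )
        for mid in a.index:
            assert b[mid] == pytest.approx(a[mapping[mid]], rel=1e-10)

    def test_missing_loco_fit_raises(self, small_genotypes):
        _, gm = small_genotypes
        sub = gm.take_samples(np.arange(60))
        trait = make_trait(
            np.random.default_rng(2).standard_normal(60), ids=sub.sample_ids
        )
        grms = loco_grms(sub)
        grms.pop("4")
        with pytest.raises(ValueError, match="chromosome 4"):
            gwa_loco(sub, trait, grms)


class TestConditionalScan:
    def _setup(self, n=150, seed=12):
        r = np.random.default_rng(seed)
        dos = r.binomial(2, r.uniform(0.2, 0.5, 30), size=(n, 30)).astype(float)
        gm = make_gm(dos, chroms=["1"] * 15 + ["2"] * 15)
        y = r.standard_normal(n) + 0.8 * (dos[:, 5] - dos[:, 5].mean())
        trait = make_trait(y, ids=gm.sample_ids)
        return gm, trait, loco_grms(gm)

    def test_matches_dense_projection_oracle(self):
        gm, trait, grms = self._setup()
        fixed = ["s20"]
        tab = conditional_scan(gm, trait, grms, fixed)
        # dense oracle for a chromosome-1 marker
        fit = fit_null(trait, grms["1"])
        Vi = np.linalg.inv(fit.V)
        F = np.column_stack(
            [np.ones(gm.n_samples), gm.dosages[:, 20] - gm.dosages[:, 20].mean()]
        )
        P = Vi - Vi @ F @ np.linalg.inv(F.T @ Vi @ F) @ F.T @ Vi
        x = gm.dosages[:, 5] - gm.dosages[:, 5].mean()
        b = (x @ P @ fit.y) / (x @ P @ x)
        t = b * np.sqrt(x @ P @ x)
        row = tab[tab["marker_id"] == "s5"].iloc[0]
        assert row["b"] == pytest.approx(b, rel=1e-8)
        assert row["t"] == pytest.approx(t, rel=1e-8)

    def test_conditioned_marker_flagged(self):
        gm, trait, grms = self._setup()
        tab = conditional_scan(gm, trait, grms, ["s5"])
        row = tab[tab["marker_id"] == "s5"].iloc[0]
        assert row["reason"] == "conditioned_marker"
        assert row["p"] == 1.0

    def test_duplicate_of_fixed_marker_flagged_collinear(self):
        gm, trait, grms = self._setup()
        gm.dosages[:, 7] = gm.dosages[:, 20]  # duplicate of the fixed marker
        tab = conditional_scan(gm, trait, grms, ["s20"])
        row = tab[tab["marker_id"] == "s7"].iloc[0]
        assert row["reason"] == "collinear_with_fixed"
        assert row["p"] == 1.0

    def test_orthogonal_conditioning_leaves_t_unchanged(self):
        # V = c I and exactly orthogonal covariate: conditional t equals the
        # unconditional score-test t
        n = 8
        y = np.array([0.1, 0.4, -0.2, 0.3, 1.2, 0.9, 1.4, 1.1])
        dos = np.column_stack(
            [
                np.array([0, 0, 2, 2, 0, 0, 2, 2], dtype=float),  # tested x
                np.array([0, 2, 0, 2, 0, 2, 0, 2], dtype=float),  # fixed f
            ]
        )
        gm = make_gm(dos, chroms=["1", "2"])
        trait = make_trait(y, ids=gm.sample_ids)
        eye = {
            c: GRM(np.eye(n), gm.sample_ids.copy(), c) for c in ("1", "2")
        }
        plain = gwa_loco(gm, trait, eye)
        cond = conditional_scan(gm, trait, eye, ["s1"])
        t0 = plain.loc[plain["marker_id"] == "s0", "t"].iloc[0]
        t1 = cond.loc[cond["marker_id"] == "s0", "t"].iloc[0]
        assert t1 == pytest.approx(t0, abs=1e-8)
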