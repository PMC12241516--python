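"""Weighted community statistics: oracle and property tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vpdtraits import stats as st


class TestIQR:
    def test_constant_vector_all_kept(self):
        assert st.flag_outliers_iqr(np.full(10, 3.3)).all()

    def test_hand_computed_example(self):
        # {1..9, 100}: Q1 = 3.25, Q3 = 7.75 (type-7), IQR = 4.5 → 100 flagged
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        mask = st.flag_outliers_iqr(values, k=1.5)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_permutation_invariance(self, rng):
        values = rng.normal(size=50)
        values[3] = 40.0
        mask = st.flag_outliers_iqr(values)
        perm = rng.permutation(50)
        np.testing.assert_array_equal(st.flag_outliers_iqr(values[perm]),
                                      mask[perm])

    def test_small_samples_kept_entirely(self):
        assert st.flag_outliers_iqr([1.0, 2.0, 400.0]).all()


class TestCWM:
    def test_equal_weights_reduce_to_ordinary_moments(self, rng):
        x = rng.normal(10, 2, 25)
        mean, se, n = st.cwm(x, np.full(25, 2.7))
        assert mean == pytest.approx(np.mean(x), rel=1e-12)
        assert se == pytest.approx(np.std(x, ddof=1) / np.sqrt(25), rel=1e-12)
        assert n == 25

    def test_weighted_arithmetic(self):
        mean, _, _ = st.cwm([10.0, 2.0], [3.0, 1.0])
        assert mean == pytest.approx(8.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 30))
            x = rng.normal(size=n)
            w = rng.uniform(0.1, 5, n)
            mean, se, _ = st.cwm(x, w)
            # independent accumulation of weighted moments
            sw = sum(w); m = sum(wi * xi for wi, xi in zip(w, x)) / sw
            n_eff = sw**2 / sum(wi**2 for wi in w)
            var = sum(wi * (xi - m) ** 2 for wi, xi in zip(w, x)) / sw
            var *= n_eff / (n_eff - 1)
            assert mean == pytest.approx(m, rel=1e-12)
            assert se == pytest.approx(np.sqrt(var / n_eff), rel=1e-12)

    def test_single_species_se_undefined(self):
        mean, se, n = st.cwm([5.0], [1.0])
        assert mean == 5.0 and np.isnan(se) and n == 1

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            st.cwm([1.0, 2.0], [1.0, 0.0])


def minimal_letter_cover(groups, significant):
    """Exhaustive oracle: minimum number of NS-cliques covering all NS pairs
    and all groups, with no clique containing a significant pair."""
    ns_pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]
                if not significant.get((a, b), False)]
    cliques = []
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            if all(not significant.get((a, b), False)
                   for a, b in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    for size in range(1, len(cliques) + 1):
        for chosen in itertools.combinations(cliques, size):
            if all(any({a, b} <= c for c in chosen) for a, b in ns_pairs) and \
               all(any(g in c for c in chosen) for g in groups):
                return size
    raise AssertionError("no cover found")


class TestLetters:
    def test_identical_groups_share_letter(self, rng):
        x = rng.normal(0, 1, 12)
        res = st.weighted_anova_tukey({"a": x, "b": x.copy()},
                                      {"a": np.ones(12), "b": np.ones(12)})
        assert res.letters["a"] == res.letters["b"]

    def test_three_separated_groups_three_letters(self, rng):
        groups = {g: rng.normal(mu, 0.1, 10) for g, mu in
                  zip("abc", (0.0, 10.0, 20.0))}
        weights = {g: np.ones(10) for g in groups}
        res = st.weighted_anova_tukey(groups, weights)
        letters = set(res.letters.values())
        assert len(letters) == 3 and all(len(s) == 1 for s in letters)
        assert res.p_value < 1e-6
        # oracle: direct studentized-range evaluation of one pair
        from scipy import stats as sps
        mse = 0.0
        for g in groups:
            mse += np.sum((groups[g] - groups[g].mean()) ** 2)
        mse /= (30 - 3)
        q = abs(groups["a"].mean() - groups["b"].mean()) / np.sqrt(mse / 10)
        assert res.pairwise_p.loc["a", "b"] == pytest.approx(
            float(sps.studentized_range.sf(q, 3, 27)), rel=1e-6)

    def test_letters_iff_property_and_minimality(self, rng):
        # random significance structures over up to 5 groups
        for trial in range(40):
            k = int(rng.integers(2, 6))
            groups = [f"g{i}" for i in range(k)]
            sig = {}
            for a, b in itertools.combinations(groups, 2):
                s = bool(rng.random() < 0.4)
                sig[(a, b)] = sig[(b, a)] = s
            letters = st.compact_letter_display(groups, sig)
            for a, b in itertools.combinations(groups, 2):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != sig[(a, b)], (trial, letters, sig)
            n_letters = len(set("".join(letters.values())))
            assert n_letters == minimal_letter_cover(groups, sig)

    def test_weighted_letters_use_effective_n(self, rng):
        # heavily down-weighted noisy observations should not mask separation
        a = np.concatenate([rng.normal(0, 0.1, 10), [50.0]])
        b = rng.normal(1.0, 0.1, 10)
        wa = np.concatenate([np.ones(10), [1e-6]])
        res = st.weighted_anova_tukey({"a": a, "b": b},
                                      {"a": wa, "b": np.ones(10)})
        assert not set(res.letters["a"]) & set(res.letters["b"])


class TestVarpart:
    def test_species_constant_trait(self):
        plots = ["p1", "p2", "p1", "p2", "p1", "p2"]
        species = ["s1", "s1", "s2", "s2", "s3", "s3"]
        values = {"s1": 1.0, "s2": 2.0, "s3": 5.0}
        y = [values[s] for s in species]
        r = st.varpart_two_factor(y, plots, species)
        assert r.frac_d == pytest.approx(0.0, abs=1e-12)
        assert r.frac_a == pytest.approx(0.0, abs=1e-12)
        assert r.frac_b > 0.9

    def test_pure_noise_residual_near_one(self, rng):
        n = 500
        plots = rng.choice(["p1", "p2", "p3", "p4"], n)
        species = rng.choice([f"s{i}" for i in range(8)], n)
        r = st.varpart_two_factor(rng.normal(size=n), plots, species)
        assert r.frac_d > 0.9

    def test_fractions_sum_to_one_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 80))
            plots = rng.choice(["p1", "p2", "p3"], n)
            species = rng.choice(["s1", "s2", "s3", "s4"], n)
            if len(set(plots)) < 2 or len(set(species)) < 2:
                continue
            y = rng.normal(size=n)
            r = st.varpart_two_factor(y, plots, species)
            total = r.frac_a + r.frac_b + r.frac_shared + r.frac_d
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_adjusted_mode_flagged(self, rng):
        n = 60
        r = st.varpart_two_factor(rng.normal(size=n),
                                  rng.choice(["p1", "p2"], n),
                                  rng.choice(["s1", "s2", "s3"], n),
                                  adjusted=True)
        assert r.adjusted


class TestSMA:
    def test_identity_line(self):
        x = np.linspace(0, 10, 20)
        fit = st.sma_fit(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_slope_limit_low_noise(self, rng):
        x = np.linspace(0, 10, 200)
        fit = st.sma_fit(x, 2 * x + rng.normal(0, 1e-8, 200))
        assert fit.slope == pytest.approx(2.0, rel=1e-6)

    def test_closed_form_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            x, y = rng.normal(size=n), rng.normal(size=n)
            fit = st.sma_fit(x, y)
            r = np.corrcoef(x, y)[0, 1]
            expected = np.sign(r) * np.std(y, ddof=1) / np.std(x, ddof=1)
            assert fit.slope == pytest.approx(expected, rel=1e-12)
            assert np.sign(fit.slope) == np.sign(fit.r) or fit.r == 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            st.sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPCA:
    def make_table(self, rng, n=20):
        z = rng.normal(size=n)
        return pd.DataFrame({
            "t1": z + rng.normal(0, 0.3, n),
            "t2": 2 * z + rng.normal(0, 0.3, n),
            "t3": rng.normal(0, 0.05, n),
        })

    def test_zero_variance_trait_zero_arrow(self, rng):
        table = self.make_table(rng)
        table["t3"] = 1.234
        res = st.pca_unscaled(table, log10_traits=())
        assert res.arrow_lengths["t3"] == pytest.approx(0.0, abs=1e-10)

    def test_perfectly_correlated_pair_rank_drop(self, rng):
        z = rng.normal(size=15)
        table = pd.DataFrame({"t1": z, "t2": 3 * z})
        res = st.pca_unscaled(table, log10_traits=())
        assert len(res.explained_variance) == 1
        assert "rank_deficient" in res.flags

    def test_reconstruction_identity(self, rng):
        table = self.make_table(rng)
        res = st.pca_unscaled(table, log10_traits=())
        centered = table.to_numpy() - table.to_numpy().mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.max(np.abs(recon - centered)) < 1e-10

    def test_log_transform_registry(self, rng):
        table = pd.DataFrame({"kp": np.exp(rng.normal(3, 0.4, 15)),
                              "chi": rng.uniform(0.6, 0.9, 15)})
        out = st.apply_transforms(table)
        np.testing.assert_allclose(out["kp"], np.log10(table["kp"]))
        np.testing.assert_allclose(out["chi"], table["chi"])

    def test_sign_convention_deterministic(self, rng):
        table = self.make_table(rng)
        r1 = st.pca_unscaled(table, log10_traits=())
        r2 = st.pca_unscaled(table, log10_traits=())
        pd.testing.assert_frame_equal(r1.loadings, r2.loadings)
        for col in r1.loadings.columns:
            j = r1.loadings[col].abs().idxmax()
            assert r1.loadings.loc[j, col] > 0
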