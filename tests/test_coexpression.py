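import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import two_block_config
from ttrnet.coexpression import (
    SoftThresholdScan,
    adjacency,
    detect_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    tom_from_adjacency,
    topological_overlap,
    _scale_free_r2,
)
from ttrnet.data import ValidationError
from ttrnet.simulate import generate_expression


def _adj(mat):
    idx = [f"n{i}" for i in range(len(mat))]
    return pd.DataFrame(np.asarray(mat, dtype=float), index=idx, columns=idx)


class TestTOM:
    def test_three_node_hand_evaluation(self):
        # a12 = a13 = 0.5, a23 = 0:
        # TOM23 = (a21*a13 + a23) / (min(k2, k3) + 1 - a23) = 0.25 / 1.5 = 1/6
        tom = tom_from_adjacency(_adj([[0, 0.5, 0.5], [0.5, 0, 0], [0.5, 0, 0]]))
        assert tom.iloc[1, 2] == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_neighbourhoods_with_full_link_give_one(self):
        # nodes 0,1 fully adjacent to each other and to the same third node
        tom = tom_from_adjacency(_adj([[0, 1, 1], [1, 0, 1], [1, 1, 0]]))
        assert tom.iloc[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_gives_zero(self):
        tom = tom_from_adjacency(_adj([[0, 0, 0.8], [0, 0, 0], [0.8, 0, 0]]))
        assert tom.iloc[0, 1] == pytest.approx(0.0)

    def test_bounds_symmetry_unit_diagonal_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            a = rng.uniform(size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_from_adjacency(_adj(a)).to_numpy()
            assert tom.min() >= 0.0 and tom.max() <= 1.0
            assert np.abs(tom - tom.T).max() < 1e-12
            assert np.allclose(np.diag(tom), 1.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            tom_from_adjacency(_adj([[0, np.nan], [np.nan, 0]]))


class TestSoftThreshold:
    def test_perfectly_correlated_blocks_stay_at_one_for_every_power(self):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=12)
        expr = pd.DataFrame([profile, profile * 2 + 1, -profile], index=list("abc"))
        for beta in (1, 3, 7):
            adj = adjacency(expr, beta)
            assert adj.loc["a", "b"] == pytest.approx(1.0)
            assert adj.loc["a", "c"] == pytest.approx(1.0)  # unsigned

    def test_chosen_power_matches_brute_force_scan(self):
        """Hub-structured data (seed 11): selection equals an independent scan."""
        rng = np.random.default_rng(11)
        n, s = 300, 20
        f = rng.normal(size=s)
        w = rng.pareto(2.0, size=n) + 0.05  # heavy-tailed loadings
        w = np.clip(w / w.max() * 1.5, 0, 1)
        expr = pd.DataFrame(
            np.outer(w, f) + rng.normal(0, np.sqrt(1 - (w * 0.9) ** 2)[:, None], (n, s)),
            index=[f"t{i}" for i in range(n)],
        )
        target = 0.8
        scan = pick_soft_threshold(expr, range(1, 13), r2_target=target)
        # independent oracle: recompute R^2 per power from the raw correlations
        cor = np.abs(np.corrcoef(expr.to_numpy()))
        np.fill_diagonal(cor, 0.0)
        chosen = None
        for beta in range(1, 13):
            if _oracle_r2((cor**beta).sum(axis=1)) >= target:
                chosen = beta
                break
        assert chosen is not None, "construction should reach the fit target"
        assert not scan.used_fallback
        assert scan.chosen_beta == chosen

    def test_uncorrelated_noise_falls_back_with_warning_flag(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(40, 9)))
        scan = pick_soft_threshold(expr, range(1, 6), r2_target=0.999, fallback=10)
        assert scan.used_fallback and scan.chosen_beta == 10

    def test_mean_connectivity_non_increasing_in_power(self, default_dataset):
        expr = default_dataset.matrix.log2p1().iloc[:150]
        scan = pick_soft_threshold(expr, range(1, 10))
        k = scan.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) <= 1e-9)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.eye(5)[:, :3])
        with pytest.raises(ValidationError):
            pick_soft_threshold(expr)


def _oracle_r2(k, nbins=10):
    """Binned log-log degree regression, written independently."""
    k = np.asarray(k, float)
    k = k[k > 0]
    edges = np.linspace(k.min(), k.max(), nbins + 1)
    mids, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (k >= lo) & (k < hi) if hi < edges[-1] else (k >= lo) & (k <= hi)
        if m.any():
            mids.append(k[m].mean())
            freqs.append(m.mean())
    x, y = np.log10(mids), np.log10(freqs)
    slope, icpt = np.polyfit(x, y, 1)
    yhat = slope * x + icpt
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def test_scale_free_r2_agrees_with_independent_regression():
    rng = np.random.default_rng(7)
    for _ in range(20):
        k = rng.pareto(1.5, size=200) + 0.1
        assert _scale_free_r2(k) == pytest.approx(_oracle_r2(k), abs=1e-9)


class TestModules:
    def test_two_planted_blocks_recovered(self):
        m, truth = generate_expression(two_block_config(3))
        tom = topological_overlap(m.log2p1(), 6)
        mods = detect_modules(tom, min_module_size=10, cut_height=0.9)
        assert len(mods.modules) == 2
        truth_labels = [truth.module_labels[t] for t in tom.index]
        assert adjusted_rand_score(truth_labels, list(mods.labels)) >= 0.9

    def test_pure_noise_is_mostly_grey(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(100, 9)), index=[f"t{i}" for i in range(100)])
        mods = detect_modules(topological_overlap(expr, 6), 10, 0.9)
        assert (mods.labels == "grey").mean() >= 0.9

    def test_single_block_gives_single_module(self):
        cfg = two_block_config(4).model_copy(update={"n_modules": 1})
        m, truth = generate_expression(cfg)
        tom = topological_overlap(m.log2p1(), 6)
        mods = detect_modules(tom, 10, 0.9)
        assert len(mods.modules) == 1
        members = set(mods.members(mods.modules[0]))
        assert set(truth.module_labels) <= members

    def test_empty_tom_rejected(self):
        with pytest.raises(ValidationError):
            detect_modules(pd.DataFrame(), 10, 0.9)


class TestEigengene:
    def _assignment(self, labels):
        from ttrnet.coexpression import ModuleAssignment

        return ModuleAssignment(pd.Series(labels))

    def test_identical_profiles_explain_all_variance(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=9)
        expr = pd.DataFrame([profile, 2 * profile + 3, profile - 1],
                            index=list("abc"), columns=[f"s{i}" for i in range(9)])
        eig = module_eigengene(expr, self._assignment({t: "blue" for t in "abc"}))
        assert eig.variance_explained["blue"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        me = eig.scores.loc["blue"].to_numpy()
        assert abs(np.corrcoef(me, z)[0, 1]) == pytest.approx(1.0)

    def test_sign_convention_follows_mean_profile(self):
        m, _ = generate_expression(two_block_config(5))
        expr = m.log2p1()
        mods = detect_modules(topological_overlap(expr, 6), 10, 0.9)
        eig = module_eigengene(expr, mods)
        for module in mods.modules:
            sub = expr.loc[mods.members(module)]
            z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
            assert np.dot(eig.scores.loc[module], z.mean(axis=0)) > 0

    def test_flipping_member_profiles_flips_the_eigengene(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(5, 9)))
        labels = self._assignment({i: "red" for i in range(5)})
        me = module_eigengene(expr, labels).scores.loc["red"]
        me_neg = module_eigengene(-expr, labels).scores.loc["red"]
        assert np.allclose(me.to_numpy(), -me_neg.to_numpy(), atol=1e-9)

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.normal(size=(3, 7)))
        labels = self._assignment({i: "green" for i in range(3)})
        me = module_eigengene(expr, labels).scores.loc["green"].to_numpy()
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1, ddof=1)).T.to_numpy()
        evals, evecs = np.linalg.eigh(z.T @ z)  # sample-space Gram matrix
        pc1 = evecs[:, -1]
        assert abs(np.dot(me, pc1)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_module_rejected(self):
        expr = pd.DataFrame(np.ones((2, 6)))
        with pytest.raises(ValidationError):
            module_eigengene(expr, self._assignment({0: "m", 1: "m"}))


class TestModuleTrait:
    def _traits(self):
        idx = [f"{g}_{i}" for g in ("LG", "HG", "HG_TTR") for i in (1, 2, 3)]
        glucose = pd.Series([0.0] * 3 + [1.0] * 6, index=idx)
        ttr = pd.Series([0.0] * 6 + [1.0] * 3, index=idx)
        return pd.DataFrame({"glucose": glucose, "ttr": ttr})

    def _eig(self, rows):
        from ttrnet.coexpression import Eigengenes

        scores = pd.DataFrame.from_dict(rows, orient="index")
        scores.columns = self._traits().index
        return Eigengenes(scores, pd.Series(1.0, index=scores.index))

    def test_trait_matching_eigengene_wins(self):
        traits = self._traits()
        rng = np.random.default_rng(0)
        eig = self._eig({"hit": traits["glucose"].to_numpy(),
                         "noise": rng.normal(size=9)})
        res = module_trait_correlation(eig, traits)
        assert res.correlations.loc["hit", ("glucose", "r")] == pytest.approx(1.0)
        assert res.hub_module == "hit"

    def test_orthogonal_eigengene_never_selected(self):
        traits = self._traits()
        ortho = np.array([1, -1, 0, 1, -1, 0, 1, -1, 0], dtype=float)
        eig = self._eig({"flat": ortho, "hit": traits["glucose"].to_numpy()})
        res = module_trait_correlation(eig, traits)
        assert abs(res.correlations.loc["flat", ("glucose", "r")]) < 1e-9
        assert res.hub_module == "hit"

    def test_constant_trait_rejected(self):
        traits = self._traits()
        traits["ttr"] = 1.0
        with pytest.raises(ValidationError):
            module_trait_correlation(self._eig({"m": np.arange(9.0)}), traits)

    def test_planted_trait_module_recovered_and_selected(self):
        cfg = two_block_config(5).model_copy(
            update={"n_coding": 200, "n_modules": 1, "module_trait_cor": 0.85}
        )
        m, truth = generate_expression(cfg)
        expr = m.log2p1()
        mods = detect_modules(topological_overlap(expr, 6), 10, 0.9)
        eig = module_eigengene(expr, mods)
        res = module_trait_correlation(eig, cfg.trait_table())
        r = res.correlations.loc[res.hub_module, ("glucose", "r")]
        assert abs(r) == pytest.approx(0.85, abs=0.1)
        planted = {t for t in truth.module_labels}
        hub_members = set(mods.members(res.hub_module))
        assert len(planted & hub_members) / len(planted) >= 0.9

    def test_permuting_samples_permutes_eigengenes_and_keeps_correlations(self):
        m, _ = generate_expression(two_block_config(6))
        expr = m.log2p1()
        mods = detect_modules(topological_overlap(expr, 6), 10, 0.9)
        traits = two_block_config(6).trait_table()
        perm = np.random.default_rng(1).permutation(expr.shape[1])
        expr_p = expr.iloc[:, perm]
        eig = module_eigengene(expr, mods)
        eig_p = module_eigengene(expr_p, mods)
        assert np.allclose(
            eig.scores.to_numpy()[:, perm], eig_p.scores.to_numpy(), atol=1e-9
        )
        r1 = module_trait_correlation(eig, traits).correlations
        r2 = module_trait_correlation(eig_p, traits.iloc[perm]).correlations
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)
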