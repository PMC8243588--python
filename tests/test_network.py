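"""Network construction: bicor, adjacency, soft threshold, TOM, detection,
eigengenes, kME, merging — each against independent oracles where derived."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexkit.network import (
    NetworkConfig,
    bicor,
    bicor_matrix,
    build_network,
    detect_modules,
    hub_mask,
    kme_table,
    merge_modules,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    tom_similarity,
)
from coexkit.types import InputError

from conftest import make_expression


# ---------------------------------------------------------------------------
# oracle: literal transcription of the biweight midcorrelation formula
# ---------------------------------------------------------------------------

def bicor_oracle(x, y):
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            # Pearson fallback on this vector
            a = v - np.mean(v)
            return a / np.sqrt(np.sum(a ** 2))
        u = (v - med) / (9 * mad)
        w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        a = (v - med) * w
        return a / np.sqrt(np.sum(a ** 2))

    return float(np.sum(weights(np.asarray(x, float)) * weights(np.asarray(y, float))))


class TestBicor:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=25)
        assert bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_affine_equivariance(self, rng):
        x = rng.normal(size=30)
        assert bicor(x, 2.5 * x + 1.0) == pytest.approx(1.0, abs=1e-12)
        assert bicor(x, -0.7 * x + 3.0) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_mad_zero_falls_back_to_pearson(self, rng):
        # majority-identical vector has MAD 0
        x = np.array([1.0] * 12 + [5.0, 7.0, 2.0, 8.0, 3.0, 9.0])
        y = rng.normal(size=len(x))
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_errors(self, rng):
        with pytest.raises(InputError):
            bicor([1, 2], [3, 4])
        with pytest.raises(InputError):
            bicor([1, 2, 3], [1, 2, 3, 4])
        with pytest.raises(InputError):
            bicor([1, 1, 1, 1], [1, 1, 1, 1])

    def test_matrix_agrees_with_pairwise(self, rng):
        X = rng.normal(size=(6, 40))
        C = bicor_matrix(X)
        for i in range(6):
            for j in range(6):
                assert C[i, j] == pytest.approx(bicor(X[i], X[j]), abs=1e-12)

    def test_reduces_to_pearson_on_gaussian(self):
        # median |bicor - pearson| < 0.05 at n=100 on clean Gaussian data
        rng = np.random.default_rng(7)
        diffs = []
        for _ in range(200):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            diffs.append(abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]))
        assert np.median(diffs) < 0.05


class TestSignedAdjacency:
    def test_endpoints(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(C, 5.5)[0, 1] == pytest.approx(1.0)
        C = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(C, 5.5)[0, 1] == pytest.approx(0.0)

    def test_zero_correlation_closed_form(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(C, 5.5)[0, 1] == pytest.approx(0.5 ** 5.5, abs=1e-15)

    def test_monotone_in_correlation(self):
        cs = np.linspace(-1, 1, 41)
        a = ((1 + cs) / 2) ** 5.5
        C = np.eye(len(cs))
        for i, c in enumerate(cs[:-1]):
            M = np.array([[1.0, cs[i]], [cs[i], 1.0]])
            N = np.array([[1.0, cs[i + 1]], [cs[i + 1], 1.0]])
            assert signed_adjacency(M, 5.5)[0, 1] <= signed_adjacency(N, 5.5)[0, 1]
        assert np.all(np.diff(a) >= 0)

    def test_rejects_asymmetric(self):
        C = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(InputError):
            signed_adjacency(C, 2.0)


class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_beta(self, rng):
        X = rng.normal(size=(60, 50))
        C = bicor_matrix(X)
        table = pick_soft_threshold(C, candidate_betas=[1, 2, 4, 8, 16])
        k = table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(k) < 0)

    def test_r2_matches_independent_regression_oracle(self):
        # oracle: same binning, two-pass least squares via np.polyfit
        rng = np.random.default_rng(3)
        k = rng.pareto(2.0, size=500) + 1.0
        r2, slope = scale_free_fit(k, n_bins=10)
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max(), 11)
        idx = np.clip(np.digitize(logk, edges) - 1, 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = idx == b
            if sel.any():
                xs.append(np.log10(np.mean(k[sel])))
                ys.append(np.log10(sel.sum() / k.size))
        coef, res = np.polyfit(xs, ys, 1), None
        yhat = np.polyval(coef, xs)
        ss_res = np.sum((np.array(ys) - yhat) ** 2)
        ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
        oracle_r2 = 1 - ss_res / ss_tot
        if coef[0] > 0:
            oracle_r2 = -oracle_r2
        assert r2 == pytest.approx(oracle_r2, abs=1e-10)
        assert slope == pytest.approx(coef[0], abs=1e-10)

    def test_power_law_degrees_fit_well(self):
        # exact power-law degree sample: p(k) ~ k^-2.5
        rng = np.random.default_rng(1)
        k = (rng.pareto(1.5, size=4000) + 1.0) * 3.0
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 >= 0.9
        assert slope < 0

    def test_degenerate_connectivity_reports_nan(self):
        r2, slope = scale_free_fit(np.full(100, 3.0))
        assert np.isnan(r2) and np.isnan(slope)


def tom_oracle(A):
    n = A.shape[0]
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            T[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return T


class TestTOM:
    def test_all_ones_adjacency(self):
        A = np.ones((3, 3))
        T = tom_similarity(A)
        assert T[0, 1] == pytest.approx(1.0)

    def test_identity_adjacency(self):
        T = tom_similarity(np.eye(4))
        off = T[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)

    def test_larger_oracle(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0, 1, size=(20, 20))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        assert np.allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)

    def test_rejects_out_of_range(self):
        A = np.full((3, 3), 1.5)
        with pytest.raises(InputError):
            tom_similarity(A)


def _two_block_expression(rng, block=50, n=100, rho=0.7):
    f1 = rng.normal(size=n)
    f2 = rng.normal(size=n)
    lam = np.sqrt(rho)
    sd = np.sqrt(1 - rho)
    rows = []
    for _ in range(block):
        rows.append(lam * f1 + sd * rng.normal(size=n))
    for _ in range(block):
        rows.append(lam * f2 + sd * rng.normal(size=n))
    return np.array(rows)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        X = _two_block_expression(rng)
        C = bicor_matrix(X)
        A = signed_adjacency(np.nan_to_num(C), 6.0)
        T = tom_similarity(A)
        labels = detect_modules(T, NetworkConfig(beta=6.0))
        assert set(labels) == {1, 2}
        # block purity
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1

    def test_noise_genes_unassigned(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 100))
        C = bicor_matrix(X)
        A = signed_adjacency(np.nan_to_num(C), 6.0)
        T = tom_similarity(A)
        labels = detect_modules(T, NetworkConfig(beta=6.0))
        assert np.all(labels == 0)

    def test_module_one_is_largest(self):
        rng = np.random.default_rng(8)
        n = 100
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        rows = [0.9 * f1 + 0.3 * rng.normal(size=n) for _ in range(70)]
        rows += [0.9 * f2 + 0.3 * rng.normal(size=n) for _ in range(40)]
        X = np.array(rows)
        T = tom_similarity(signed_adjacency(np.nan_to_num(bicor_matrix(X)), 6.0))
        labels = detect_modules(T, NetworkConfig(beta=6.0))
        sizes = pd.Series(labels[labels > 0]).value_counts()
        assert sizes.idxmax() == 1

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = _two_block_expression(rng, block=40, n=80)
        perm = rng.permutation(X.shape[0])
        T1 = tom_similarity(signed_adjacency(np.nan_to_num(bicor_matrix(X)), 6.0))
        T2 = tom_similarity(signed_adjacency(np.nan_to_num(bicor_matrix(X[perm])), 6.0))
        l1 = detect_modules(T1, NetworkConfig(beta=6.0))
        l2 = detect_modules(T2, NetworkConfig(beta=6.0))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(l1[perm], l2) == pytest.approx(1.0)

    def test_too_few_genes_all_unassigned(self):
        T = np.eye(5)
        with pytest.warns(UserWarning):
            labels = detect_modules(T, NetworkConfig(beta=6.0, min_module_size=10))
        assert np.all(labels == 0)


class TestModuleEigengene:
    def test_identical_genes(self, rng):
        profile = rng.normal(size=50)
        X = make_expression(np.tile(profile, (5, 1)))
        me, ve = module_eigengene(X, X.genes)
        std_profile = (profile - profile.mean()) / profile.std(ddof=1)
        assert ve == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(me, std_profile, atol=1e-9)

    def test_sign_convention(self, rng):
        X = make_expression(rng.normal(size=(20, 60)))
        me, _ = module_eigengene(X, X.genes)
        kme = kme_table(X, pd.DataFrame([me], index=[1], columns=X.samples))
        assert kme[1].mean() >= 0

    def test_unit_variance(self, rng):
        X = make_expression(rng.normal(size=(10, 40)))
        me, _ = module_eigengene(X, X.genes)
        assert me.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_planted_factor_recovery(self, small_cohort):
        from coexkit.preprocessing import log_transform

        _, expr, _, truths = small_cohort
        X = log_transform(expr)
        t = truths[0]
        me, _ = module_eigengene(X, t.gene_ids)
        r = abs(np.corrcoef(me, t.eigen_signal)[0, 1])
        assert r >= 0.9

    def test_constant_rows_dropped_with_warning(self, rng):
        V = rng.normal(size=(4, 30))
        V[2] = 1.0
        X = make_expression(V)
        with pytest.warns(UserWarning):
            me, _ = module_eigengene(X, X.genes)
        assert me.shape == (30,)

    def test_errors(self, rng):
        X = make_expression(rng.normal(size=(4, 30)))
        with pytest.raises(InputError):
            module_eigengene(X, ["g0"])
        with pytest.raises(InputError):
            module_eigengene(X, ["g0", "nope"])


class TestKME:
    def test_own_me_pseudo_gene(self, rng):
        X = make_expression(rng.normal(size=(8, 50)))
        me, _ = module_eigengene(X, X.genes)
        E = pd.DataFrame([me], index=[1], columns=X.samples)
        pseudo = make_expression(me[None, :], genes=["me_copy"], samples=X.samples)
        kme = kme_table(pseudo, E)
        assert kme.loc["me_copy", 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_corr_oracle(self, rng):
        X = make_expression(rng.normal(size=(12, 40)))
        me, _ = module_eigengene(X, X.genes)
        E = pd.DataFrame([me], index=[1], columns=X.samples)
        kme = kme_table(X, E)
        for g in X.genes:
            expected = np.corrcoef(X.data.loc[g], me)[0, 1]
            assert kme.loc[g, 1] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_is_missing(self, rng):
        V = rng.normal(size=(3, 30))
        V[1] = 2.0
        X = make_expression(V)
        me, _ = module_eigengene(X, ["g0", "g2"])
        E = pd.DataFrame([me], index=[1], columns=X.samples)
        kme = kme_table(X, E)
        assert np.isnan(kme.loc["g1", 1])

    def test_hub_predicate_rule(self):
        kme = pd.DataFrame(
            {1: [0.9, 0.69, 0.75, 0.8], 2: [0.3, 0.2, 0.8, 0.7]},
            index=["a", "b", "c", "d"],
        )
        assignment = pd.Series([1, 1, 1, 1], index=["a", "b", "c", "d"])
        hubs = hub_mask(kme, assignment, threshold=0.7)
        assert hubs["a"]          # 0.9 >= 0.7 and > 0.3
        assert not hubs["b"]      # below threshold
        assert not hubs["c"]      # not higher than other module (0.75 < 0.8)
        assert hubs["d"]          # 0.8 >= 0.7 and > 0.7


class TestMergeModules:
    def _expr_with_assignment(self, rng, shared_factor=True):
        n = 80
        f1 = rng.normal(size=n)
        f2 = f1 if shared_factor else rng.normal(size=n)
        rows = [0.9 * f1 + 0.2 * rng.normal(size=n) for _ in range(20)]
        rows += [0.9 * f2 + 0.2 * rng.normal(size=n) for _ in range(15)]
        X = make_expression(np.array(rows))
        assignment = pd.Series([1] * 20 + [2] * 15, index=X.genes)
        return X, assignment

    def test_same_latent_factor_merges(self, rng):
        X, assignment = self._expr_with_assignment(rng, shared_factor=True)
        merged = merge_modules(X, assignment, merge_height=0.25)
        assert merged.max() == 1

    def test_orthogonal_modules_unchanged(self, rng):
        X, assignment = self._expr_with_assignment(rng, shared_factor=False)
        merged = merge_modules(X, assignment, merge_height=0.25)
        assert merged.max() == 2
        assert (merged == assignment).all()

    def test_idempotent(self, rng):
        X, assignment = self._expr_with_assignment(rng, shared_factor=True)
        once = merge_modules(X, assignment, merge_height=0.25)
        twice = merge_modules(X, once, merge_height=0.25)
        assert (once == twice).all()


class TestBuildNetwork:
    def test_end_to_end_small(self, small_cohort):
        from coexkit.preprocessing import preprocess
        from coexkit.synthetic import truth_assignment
        from sklearn.metrics import adjusted_rand_score

        _, expr, _, truths = small_cohort
        cleaned, _ = preprocess(expr)
        model = build_network(cleaned, NetworkConfig(beta=6.0))
        truth = truth_assignment(truths, cleaned.genes)
        ari = adjusted_rand_score(truth.to_numpy(), model.assignment.to_numpy())
        assert ari >= 0.8
        assert np.all(np.abs(np.nan_to_num(model.kme.to_numpy())) <= 1 + 1e-9)
        for m in model.module_labels:
            assert (model.assignment == m).sum() >= 2

    def test_blockwise_matches_module_count(self, small_cohort):
        from coexkit.preprocessing import preprocess

        _, expr, _, _ = small_cohort
        cleaned, _ = preprocess(expr)
        whole = build_network(cleaned, NetworkConfig(beta=6.0))
        blocked = build_network(
            cleaned, NetworkConfig(beta=6.0, max_block_size=250)
        )
        # planted structure survives blockwise decomposition
        assert blocked.assignment.max() >= whole.assignment.max() - 1
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(whole.assignment.to_numpy(),
                                  blocked.assignment.to_numpy())
        assert ari >= 0.6
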