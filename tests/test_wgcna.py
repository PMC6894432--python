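import numpy as np
import pandas as pd
import pytest

from lncsponge.types import ClinicalTable, ExpressionMatrix, ValidationError
from lncsponge.wgcna import (
    UNASSIGNED,
    detect_modules,
    merge_close_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    significant_modules,
    topological_overlap,
)


def expr(values, role="lncRNA"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, index=[f"G{i}" for i in range(arr.shape[0])],
                      columns=[f"S{i}" for i in range(arr.shape[1])])
    return ExpressionMatrix(df, role=role, unit="log2CPM")


class TestSignedAdjacency:
    def test_endpoints(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(cor, 6)[0, 1] == 1.0
        cor = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(cor, 6)[0, 1] == 0.0

    def test_zero_correlation_value(self):
        cor = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(cor, 6)[0, 1] == pytest.approx(0.5 ** 6)

    def test_monotone_in_correlation_and_bounded(self):
        grid = np.linspace(-1, 1, 41)
        for beta in (1, 6, 12):
            vals = [signed_adjacency(np.array([[1, c], [c, 1.0]]), beta)[0, 1] for c in grid]
            assert all(0 <= v <= 1 for v in vals)
            assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_bad_inputs(self):
        with pytest.raises(ValidationError):
            signed_adjacency(np.array([[1.0, 0.2], [0.3, 1.0]]), 6)
        with pytest.raises(ValidationError):
            signed_adjacency(np.eye(2), 0)


class TestTOM:
    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_equal_weight_triangle_closed_form(self, a):
        """For the a-weighted triangle TOM_ij = (a^2 + a)/(a + 1) = a."""
        adj = np.full((3, 3), a)
        np.fill_diagonal(adj, 0.0)
        tom = topological_overlap(adj)
        off = tom[np.triu_indices(3, k=1)]
        assert off == pytest.approx(a, abs=1e-12)

    def test_isolated_nodes(self):
        tom = topological_overlap(np.zeros((2, 2)))
        assert tom[0, 1] == 0.0 and tom[0, 0] == 1.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.uniform(0, 1, size=(6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(a)
            k = a.sum(axis=1)
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(6)) + a[i, j]
                    den = min(k[i], k[j]) + 1 - a[i, j]
                    assert tom[i, j] == pytest.approx(num / den, abs=1e-12)
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_asymmetric_rejected(self):
        bad = np.array([[0, 0.2], [0.4, 0.0]])
        with pytest.raises(ValidationError):
            topological_overlap(bad)


class TestScaleFreeFit:
    def test_exact_power_law_scores_near_one(self):
        # ten distinct connectivity values equally spaced in log10(k) with
        # frequencies exactly proportional to k^-1.5
        ks = 10 ** (np.arange(10) * 0.3)
        counts = np.round(1e5 * ks ** -1.5).astype(int)
        k = np.repeat(ks, counts)
        assert scale_free_fit(k) > 0.99

    def test_uniform_degrees_do_not_score_high(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(5, 6, size=500)
        assert scale_free_fit(k) < 0.85


class TestPickSoftThreshold:
    def module_data(self, seed=0):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal(30)
        data = np.vstack([f + 0.5 * rng.standard_normal(30) for _ in range(20)]
                         + [rng.standard_normal(30) for _ in range(20)])
        return expr(data)

    def test_smallest_qualifying_power_chosen(self):
        scan = pick_soft_threshold(self.module_data(), powers=(2, 4, 6), r2_min=-1.0)
        # with an always-satisfied threshold, the smallest candidate wins
        assert scan.chosen_power == 2 and scan.satisfied

    def test_argmax_fallback_with_warning(self, caplog):
        scan = pick_soft_threshold(self.module_data(), powers=(2, 4), r2_min=0.999)
        assert not scan.satisfied
        assert scan.chosen_power == int(scan.table["signed_r2"].idxmax())
        assert any("falling back" in r.message for r in caplog.records)

    def test_fixed_fallback_power(self):
        scan = pick_soft_threshold(self.module_data(), powers=(2, 4, 6),
                                   r2_min=0.999, fallback=6)
        assert scan.chosen_power == 6 and not scan.satisfied

    def test_constant_gene_rejected(self):
        data = np.vstack([np.ones(10), np.random.default_rng(0).standard_normal(10)])
        with pytest.raises(ValidationError, match="G0"):
            pick_soft_threshold(expr(data), powers=(2,))


class TestDetectModules:
    def block_dissimilarity(self, sizes, within=0.0, between=1.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_perfect_blocks(self):
        d = self.block_dissimilarity([5, 4])
        ms = detect_modules(d, min_module_size=2, cut_height=0.5)
        assert sorted(ms.sizes()[ms.sizes().index != UNASSIGNED]) == [4, 5]
        assert UNASSIGNED not in set(ms.assignment)

    def test_all_distant_genes_unassigned(self):
        d = self.block_dissimilarity([1] * 6, between=1.0)
        ms = detect_modules(d, min_module_size=2, cut_height=0.5)
        assert set(ms.assignment) == {UNASSIGNED}

    def test_labels_deterministic_and_order_invariant(self):
        d = self.block_dissimilarity([6, 3])
        ids = [f"g{i}" for i in range(9)]
        ms = detect_modules(d, min_module_size=2, cut_height=0.5, gene_ids=ids)
        perm = np.array([3, 1, 7, 0, 8, 2, 5, 4, 6])
        ms2 = detect_modules(d[np.ix_(perm, perm)], min_module_size=2,
                             cut_height=0.5, gene_ids=[ids[i] for i in perm])
        assert ms.assignment.sort_index().equals(ms2.assignment.sort_index())
        # largest block gets M1
        assert (ms.assignment[[f"g{i}" for i in range(6)]] == "M1").all()


class TestEigengene:
    def test_identical_profiles_recovered(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        e = expr(np.vstack([2 * profile, profile + 7, -0.0 + 3 * profile]))
        eig = module_eigengene(e, ["G0", "G1", "G2"])
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), z, atol=1e-9)
        assert eig.std() == pytest.approx(1.0)  # unit sample variance

    def test_sign_convention_stable_under_global_flip(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 8))
        e = expr(data)
        e_flip = expr(-data)
        a = module_eigengene(e, e.gene_ids)
        b = module_eigengene(e_flip, e_flip.gene_ids)
        mean_a = ((e.data.T - e.data.mean(1)) / e.data.std(1)).T.mean()
        assert np.corrcoef(a, ((e.data.sub(e.data.mean(1), axis=0))
                               .div(e.data.std(1), axis=0)).mean())[0, 1] > 0
        assert np.corrcoef(b, ((e_flip.data.sub(e_flip.data.mean(1), axis=0))
                               .div(e_flip.data.std(1), axis=0)).mean())[0, 1] > 0

    def test_first_pc_optimality_on_toys(self):
        """The eigengene explains at least as much member variance as any
        direction from a dense brute-force search (4-gene toys)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            data = rng.standard_normal((4, 12))
            e = expr(data)
            eig = module_eigengene(e, e.gene_ids).to_numpy()
            z = (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True)

            def explained(direction):
                d = direction / np.linalg.norm(direction)
                return float(((z @ d) ** 2).sum())

            best_random = max(
                explained(rng.standard_normal(12)) for _ in range(3000)
            )
            assert explained(eig) >= best_random - 1e-9

    def test_too_few_members_rejected(self):
        e = expr(np.random.default_rng(0).standard_normal((3, 6)))
        with pytest.raises(ValidationError):
            module_eigengene(e, ["G0"])


def staged_clinical(stages, with_normals=True):
    n = len(stages)
    rows = {
        "sample_id": [f"P{i}-T" for i in range(n)],
        "patient_id": [f"P{i}" for i in range(n)],
        "condition": ["tumor"] * n,
        "pair_id": [None] * n,
        "tnm_stage": stages,
        "survival_time": [np.nan] * n,
        "event": [np.nan] * n,
    }
    return ClinicalTable(pd.DataFrame(rows))


class TestModuleTrait:
    def test_indicator_eigengene_gives_unit_correlation(self):
        stages = ["I", "II", "III", "I", "II", "III", "III", "I"]
        clin = staged_clinical(stages)
        ind = np.array([1.0 if s == "III" else 0.0 for s in stages])
        eig = pd.DataFrame([ind], index=["M1"], columns=clin.sample_ids)
        mt = module_trait_correlation(eig, clin)
        assert mt.loc["M1", ("TNM_III", "r")] == pytest.approx(1.0)
        assert mt.loc["M1", ("TNM_III", "p")] < 1e-6

    def test_null_calibration(self):
        """Independent eigengenes reject at ~ the nominal 5% rate."""
        rng = np.random.default_rng(3)
        stages = list(np.repeat(["I", "II", "III"], 10))
        clin = staged_clinical(stages)
        hits = trials = 0
        for _ in range(200):
            eig = pd.DataFrame(rng.standard_normal((1, 30)), index=["M1"],
                               columns=clin.sample_ids)
            mt = module_trait_correlation(eig, clin)
            ps = mt.xs("p", axis=1, level="stat").to_numpy().ravel()
            hits += (ps < 0.05).sum()
            trials += ps.size
        assert 0.03 <= hits / trials <= 0.07

    def test_significant_modules_strict_boundary(self):
        mt = pd.DataFrame(
            {("TNM_I", "r"): [0.5, 0.2], ("TNM_I", "p"): [0.004, 0.05]},
            index=["M1", "M2"],
        )
        mt.columns = pd.MultiIndex.from_tuples(mt.columns, names=["trait", "stat"])
        sig = significant_modules(mt, p_max=0.05)
        assert list(sig.index) == ["M1"]
        assert sig.loc["M1", "best_trait"] == "TNM_I"

    def test_all_insignificant_empty(self):
        mt = pd.DataFrame({("TNM_I", "r"): [0.1], ("TNM_I", "p"): [0.9]}, index=["M1"])
        mt.columns = pd.MultiIndex.from_tuples(mt.columns, names=["trait", "stat"])
        assert len(significant_modules(mt)) == 0


class TestMergeCloseModules:
    def test_correlated_modules_merge(self):
        rng = np.random.default_rng(5)
        f = rng.standard_normal(20)
        g = rng.standard_normal(20)
        data = np.vstack(
            [f + 0.1 * rng.standard_normal(20) for _ in range(4)]
            + [f + 0.1 * rng.standard_normal(20) for _ in range(4)]
            + [g + 0.1 * rng.standard_normal(20) for _ in range(4)]
        )
        e = expr(data)
        assignment = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=e.gene_ids)
        from lncsponge.wgcna import ModuleSet
        merged = merge_close_modules(e, ModuleSet(assignment=assignment),
                                     merge_diss_max=0.25)
        labels = set(merged.assignment)
        assert len(labels) == 2  # A and B collapse, C stays separate
        first8 = merged.assignment[e.gene_ids[:8]]
        assert first8.nunique() == 1
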