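import numpy as np
import pandas as pd
import pytest

from mdquant.lipidomics import (
    LipidTable,
    class_pool,
    log2_fold_change,
    pca,
    pi_normalize,
    protein_lipid_correlation,
)
from mdquant.simulate import LipidSimParams, generate_lipid_dataset


def make_table(amounts, pi, lipids=None, classes=None, samples=None):
    lipids = lipids or [f"L{i}" for i in range(np.shape(amounts)[1])]
    if samples is None:
        samples = [("wt", "control", i + 1) for i in range(np.shape(amounts)[0])]
    idx = pd.MultiIndex.from_tuples(samples, names=["strain", "condition", "replicate"])
    return LipidTable(
        amounts=pd.DataFrame(amounts, index=idx, columns=lipids, dtype=float),
        pi=pd.Series(pi, index=idx, name="pi", dtype=float),
        class_map=classes or {l: "C" for l in lipids},
    )


class TestPiNormalize:
    def test_simple_division(self):
        t = make_table([[10.0, 20.0]], [2.0])
        out = pi_normalize(t)
        assert out.amounts.iloc[0].tolist() == [5.0, 10.0]

    def test_scale_invariance(self):
        t1 = make_table([[10.0, 20.0], [3.0, 6.0]], [2.0, 1.5])
        t2 = make_table([[70.0, 140.0], [3.0, 6.0]], [14.0, 1.5])
        pd.testing.assert_frame_equal(pi_normalize(t1).amounts, pi_normalize(t2).amounts)

    def test_second_pass_is_identity(self):
        t = make_table([[10.0, 20.0]], [2.0])
        once = pi_normalize(t)
        twice = pi_normalize(once)
        pd.testing.assert_frame_equal(once.amounts, twice.amounts)

    def test_nonpositive_pi_rejected(self):
        with pytest.raises(ValueError, match="Pi"):
            make_table([[1.0]], [0.0])

    def test_missing_pi_names_sample(self):
        idx = pd.MultiIndex.from_tuples(
            [("wt", "control", 1)], names=["strain", "condition", "replicate"]
        )
        other = pd.MultiIndex.from_tuples(
            [("wt", "heat", 1)], names=["strain", "condition", "replicate"]
        )
        with pytest.raises(ValueError, match="missing Pi"):
            LipidTable(
                amounts=pd.DataFrame([[1.0]], index=idx, columns=["L0"]),
                pi=pd.Series([1.0], index=other),
                class_map={"L0": "C"},
            )


class TestLog2FoldChange:
    def test_simple_ratio(self):
        samples = [("wt", "control", 1), ("wt", "trt", 1)]
        t = make_table([[2.0], [8.0]], [1.0, 1.0], samples=samples)
        fc = log2_fold_change(t)
        assert fc.loc["L0", "wt:trt"] == pytest.approx(2.0)

    def test_control_vs_itself_is_zero(self):
        samples = [("wt", "control", 1), ("wt", "control", 2), ("wt", "trt", 1)]
        t = make_table([[4.0], [4.0], [4.0]], [1.0] * 3, samples=samples)
        fc = log2_fold_change(t)
        assert fc.loc["L0", "wt:trt"] == pytest.approx(0.0)

    def test_mutant_control_vs_reference_control(self):
        samples = [("wt", "control", 1), ("mut", "control", 1)]
        t = make_table([[2.0], [8.0]], [1.0, 1.0], samples=samples)
        fc = log2_fold_change(t, reference_strain="wt")
        assert fc.loc["L0", "mut:control"] == pytest.approx(2.0)

    def test_noiseless_generator_shift_recovered_exactly(self):
        params = LipidSimParams(
            noise_cv=0.0,
            condition_class_shifts={("heat", "IPC"): 1.5},
            seed=4,
        )
        table, _, _ = generate_lipid_dataset(params)
        fc = log2_fold_change(pi_normalize(table))
        for lipid, cls in table.class_map.items():
            expected = np.log2(1.5) if cls == "IPC" else 0.0
            assert fc.loc[lipid, "wt:heat"] == pytest.approx(expected, abs=1e-9)

    def test_no_control_raises(self):
        samples = [("wt", "trt", 1), ("wt", "trt", 2)]
        t = make_table([[1.0], [2.0]], [1.0, 1.0], samples=samples)
        with pytest.raises(ValueError, match="control"):
            log2_fold_change(t)


class TestClassPool:
    def test_sums_within_class(self):
        t = make_table(
            [[3.0, 4.0, 5.0]],
            [1.0],
            lipids=["IPC_1", "IPC_2", "Cer_1"],
            classes={"IPC_1": "IPC", "IPC_2": "IPC", "Cer_1": "Cer"},
        )
        pooled = class_pool(t)
        assert pooled.amounts.loc[:, "IPC"].iloc[0] == 7.0
        assert pooled.amounts.loc[:, "Cer"].iloc[0] == 5.0

    def test_single_lipid_class_identity(self):
        t = make_table([[3.0]], [1.0], lipids=["X"], classes={"X": "solo"})
        assert class_pool(t).amounts.iloc[0, 0] == 3.0

    def test_class_totals_partition_row_total(self, rng):
        amounts = rng.random((3, 6))
        classes = {f"L{i}": f"C{i % 3}" for i in range(6)}
        t = make_table(amounts, [1.0] * 3, classes=classes)
        pooled = class_pool(t)
        np.testing.assert_allclose(
            pooled.amounts.sum(axis=1), t.amounts.sum(axis=1)
        )

    def test_commutes_with_pi_normalize(self, rng):
        amounts = rng.random((4, 6)) + 0.1
        classes = {f"L{i}": f"C{i % 2}" for i in range(6)}
        t = make_table(amounts, rng.random(4) + 0.5, classes=classes)
        a = class_pool(pi_normalize(t)).amounts
        b = pi_normalize(class_pool(t)).amounts
        pd.testing.assert_frame_equal(a, b)


class TestPCA:
    def test_collinear_samples_single_component(self):
        base = np.array([1.0, 2.0, 3.0])
        amounts = np.outer([1, 2, 3, 4], base)
        t = make_table(
            amounts,
            [1.0] * 4,
            samples=[("wt", f"c{i}", 1) for i in range(4)],
        )
        res = pca(t, scaling="center")
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_sum_to_one(self, rng):
        t = make_table(
            rng.random((5, 4)),
            [1.0] * 5,
            samples=[("wt", f"c{i}", 1) for i in range(5)],
        )
        res = pca(t)
        assert res.explained_variance_fraction.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance_fraction) <= 1e-12).all()

    def test_contributions_sum_to_100(self, rng):
        t = make_table(
            rng.random((6, 5)),
            [1.0] * 6,
            samples=[("wt", f"c{i}", 1) for i in range(6)],
        )
        res = pca(t)
        np.testing.assert_allclose(res.contributions.sum(axis=0), 100.0)

    def test_matches_eigendecomposition_oracle(self):
        amounts = np.array(
            [[4.0, 2.0, 1.0], [2.0, 5.0, 7.0], [1.0, 1.0, 2.0], [6.0, 3.0, 2.0]]
        )
        t = make_table(
            amounts, [1.0] * 4, samples=[("wt", f"c{i}", 1) for i in range(4)]
        )
        res = pca(t, scaling="auto")
        # independent oracle: eigendecomposition of the correlation matrix
        x = (amounts - amounts.mean(0)) / amounts.std(0, ddof=1)
        cov = x.T @ x / (x.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.explained_variance_fraction, evals / evals.sum(), atol=1e-8
        )
        for k in range(evecs.shape[1]):
            v = evecs[:, k]
            w = res.loadings.iloc[:, k].to_numpy()
            # loadings match up to sign
            assert min(np.abs(w - v).max(), np.abs(w + v).max()) < 1e-8
            np.testing.assert_allclose(
                t_scores := res.scores.iloc[:, k].to_numpy(),
                s := x @ w,
                atol=1e-8,
            )

    def test_sign_convention(self, rng):
        t = make_table(
            rng.random((6, 5)),
            [1.0] * 6,
            samples=[("wt", f"c{i}", 1) for i in range(6)],
        )
        res = pca(t)
        for k in range(res.n_components):
            col = res.loadings.iloc[:, k]
            assert col.iloc[np.abs(col.to_numpy()).argmax()] > 0

    def test_constant_column_error_names_lipid(self):
        t = make_table(
            [[1.0, 5.0], [1.0, 6.0], [1.0, 7.0]],
            [1.0] * 3,
            lipids=["flat", "ok"],
            samples=[("wt", f"c{i}", 1) for i in range(3)],
        )
        with pytest.raises(ValueError, match="flat"):
            pca(t)


class TestProteinLipidCorrelation:
    def _table(self, lipid_values, conditions):
        samples = [("wt", c, 1) for c in conditions]
        return make_table(
            np.array(lipid_values)[:, None], [1.0] * len(conditions),
            lipids=["L0"], samples=samples,
        )

    def test_perfect_proportionality(self):
        conds = [f"c{i}" for i in range(6)]
        protein = pd.Series(np.arange(1.0, 7.0), index=conds)
        t = self._table(2.0 * np.arange(1.0, 7.0), conds)
        res = protein_lipid_correlation(protein, t)
        row = res.table.loc["L0"]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-6
        assert row.significant

    def test_constant_lipid_flagged(self):
        conds = ["a", "b", "c", "d"]
        protein = pd.Series([1.0, 2.0, 3.0, 4.0], index=conds)
        t = self._table([5.0, 5.0, 5.0, 5.0], conds)
        res = protein_lipid_correlation(protein, t)
        row = res.table.loc["L0"]
        assert np.isnan(row.r) and row.flag == "constant" and not row.significant

    def test_hand_computed_pairs(self):
        # oracle: r = 0.6 by hand; t = 0.6*sqrt(2/0.64) ~ 1.061, p ~ 0.40 (2 df)
        conds = ["a", "b", "c", "d"]
        protein = pd.Series([1.0, 2.0, 3.0, 4.0], index=conds)
        t = self._table([2.0, 1.0, 4.0, 3.0], conds)
        res = protein_lipid_correlation(protein, t)
        row = res.table.loc["L0"]
        assert row.r == pytest.approx(0.6, abs=1e-12)
        assert row.p == pytest.approx(0.4, abs=0.01)
        assert not row.significant

    def test_key_mismatch_lists_conditions(self):
        protein = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "zzz"])
        t = self._table([1.0, 2.0, 3.0], ["a", "b", "c"])
        with pytest.raises(ValueError, match="zzz"):
            protein_lipid_correlation(protein, t)

    def test_mu_r_over_significant_only(self):
        conds = [f"c{i}" for i in range(6)]
        protein = pd.Series(np.arange(6.0), index=conds)
        samples = [("wt", c, 1) for c in conds]
        amounts = np.column_stack(
            [2 * np.arange(6.0) + 1, [3.0, 1.0, 4.0, 1.0, 5.0, 2.0]]
        )
        t = make_table(amounts, [1.0] * 6, lipids=["good", "noise"], samples=samples)
        res = protein_lipid_correlation(protein, t)
        assert res.table.loc["good", "significant"]
        assert res.mu_r == pytest.approx(
            res.table.loc[res.table.significant, "r"].mean()
        )


class TestGeneratorRecovery:
    def test_seed_determinism(self):
        p = LipidSimParams(seed=9, noise_cv=0.2)
        t1, pr1, _ = generate_lipid_dataset(p)
        t2, pr2, _ = generate_lipid_dataset(p)
        pd.testing.assert_frame_equal(t1.amounts, t2.amounts)
        pd.testing.assert_frame_equal(pr1, pr2)

    def test_unknown_class_in_shifts(self):
        with pytest.raises(ValueError, match="unknown"):
            generate_lipid_dataset(
                LipidSimParams(condition_class_shifts={("heat", "NOPE"): 2.0})
            )

    def test_protein_correlation_sampling(self):
        # oracle: sampling distribution of r at n=8 conditions, rho=0.9
        rs = []
        for seed in range(200):
            p = LipidSimParams(
                conditions=tuple(["control"] + [f"c{i}" for i in range(7)]),
                protein_lipid_rho=0.9,
                noise_cv=0.1,
                seed=seed,
            )
            table, protein, truth = generate_lipid_dataset(p)
            norm = pi_normalize(table)
            cols = [l for l, c in table.class_map.items() if c == truth["protein_class"]]
            class_mean = (
                norm.amounts[cols].sum(axis=1).groupby(level="condition").mean()
            )
            class_mean = class_mean.reindex(protein["condition"])
            rs.append(np.corrcoef(protein["protein_amount"], class_mean)[0, 1])
        assert abs(np.mean(rs) - 0.9) < 0.15

    def test_noisy_fold_change_recovery(self):
        # at cv=0.1 with n=4 replicates the log2 error SD is ~0.10, so >=90%
        # of lipids land within 0.2 log2 units of the generator shift
        shifts = {("heat", "IPC"): 2.0, ("heat", "LCB"): 0.5}
        hits, total = 0, 0
        for seed in range(10):
            p = LipidSimParams(noise_cv=0.1, condition_class_shifts=shifts, seed=seed)
            table, _, _ = generate_lipid_dataset(p)
            fc = log2_fold_change(pi_normalize(table))
            for lipid, cls in table.class_map.items():
                expected = np.log2(shifts.get(("heat", cls), 1.0))
                hits += abs(fc.loc[lipid, "wt:heat"] - expected) <= 0.2
                total += 1
        assert hits / total >= 0.90
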