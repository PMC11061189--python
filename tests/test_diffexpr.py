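"""Quasi-Poisson DE: estimator correctness, calibration, model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pedcns import synthetic_data as sd
from pedcns.diffexpr import DEDesign, ModelComparison, compare_models, fit_gene_glm, run_de


def two_group_design(n_per_group, offset=None):
    group = np.repeat([False, True], n_per_group)
    off = offset if offset is not None else np.zeros(2 * n_per_group)
    return DEDesign(group=group, offset=off)


class TestFitGeneGLM:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(3.0, size=400)
        est, se, p, ok = fit_gene_glm(y, two_group_design(200))
        assert ok
        assert abs(est) < 0.2
        assert p > 0.05

    def test_poisson_closed_form_estimate(self):
        # with equal offsets the quasi-Poisson point estimate equals the
        # Poisson MLE: log of the ratio of group means
        rng = np.random.default_rng(1)
        y = np.concatenate([rng.poisson(2.0, 1500), rng.poisson(4.0, 1500)])
        est, se, p, ok = fit_gene_glm(y, two_group_design(1500))
        closed_form = np.log(y[1500:].mean() / y[:1500].mean())
        assert est == pytest.approx(closed_form, abs=1e-10)
        assert est == pytest.approx(np.log(2), abs=0.1)

    def test_quasi_poisson_se_is_poisson_se_scaled_by_dispersion(self):
        rng = np.random.default_rng(2)
        lam = rng.gamma(1.0, 3.0, size=600)
        y = rng.poisson(lam)
        design = two_group_design(300)
        est, se, p, ok = fit_gene_glm(y, design)
        X = np.column_stack([np.ones(600), design.group.astype(float)])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        phi = ref.pearson_chi2 / ref.df_resid
        assert est == pytest.approx(ref.params[1], abs=1e-6)
        assert se == pytest.approx(ref.bse[1] * np.sqrt(phi), rel=1e-6)

    def test_type_i_error_calibrated_under_overdispersion(self):
        # NB dispersion 1 null data: quasi-Poisson keeps alpha near 0.05
        # while a plain Poisson Wald test is badly anticonservative
        rng = np.random.default_rng(3)
        design = two_group_design(200)
        X = np.column_stack([np.ones(400), design.group.astype(float)])
        fp_quasi = fp_pois = 0
        n_genes = 500
        for _ in range(n_genes):
            y = rng.poisson(rng.gamma(1.0, 5.0, size=400))
            _, _, p, _ = fit_gene_glm(y, design)
            fp_quasi += p < 0.05
            res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            fp_pois += res.pvalues[1] < 0.05
        assert 0.03 <= fp_quasi / n_genes <= 0.07
        assert fp_pois / n_genes > 0.10

    def test_offset_invariance_to_depth_doubling(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(5.0, size=300)
        sf = rng.uniform(0.5, 2.0, size=300)
        d1 = DEDesign(group=np.arange(300) % 2 == 0, offset=np.log(sf))
        est1, *_ = fit_gene_glm(y, d1)
        d2 = DEDesign(group=d1.group, offset=np.log(2 * sf))
        est2, *_ = fit_gene_glm(2 * y, d2)
        assert est1 == pytest.approx(est2, abs=5e-3)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            fit_gene_glm(np.ones(5), DEDesign(group=np.array([True] * 4 + [False]), offset=np.zeros(5)))


class TestRunDE:
    def test_effect_recovery_and_confounding_contrast(self, confounded_data):
        dataset, truth = confounded_data
        X = dataset.counts.toarray()
        cells = pd.DataFrame(
            {
                "group": truth.cells["group"].to_numpy(),
                "cell_type": truth.cells["cell_type"].to_numpy(),
            },
            index=dataset.barcodes,
        )
        sf = X.sum(axis=1)
        adjusted = run_de(X, dataset.gene_names, cells, sf, adjust=True)
        unadjusted = run_de(X, dataset.gene_names, cells, sf, adjust=False)

        genes = truth.genes
        conf = genes.loc[genes["confounded_null"], "gene"]
        eff = genes.loc[genes["true_lnfc"] != 0, "gene"]
        bg = genes.loc[~genes["confounded_null"] & (genes["true_lnfc"] == 0), "gene"]

        adj = adjusted.set_index("gene")
        unadj = unadjusted.set_index("gene")
        # composition-driven nulls: flagged by the unadjusted model only
        assert unadj.loc[conf, "significant"].mean() >= 0.5
        assert adj.loc[conf, "significant"].mean() <= 0.10
        assert (
            unadj.loc[conf, "significant"].mean()
            >= 5 * max(adj.loc[conf, "significant"].mean(), 1e-9)
        )
        # programmed within-cell-type effects recovered without bias
        assert adj.loc[eff, "estimate"].mean() == pytest.approx(1.0, abs=0.15)
        assert adj.loc[eff, "significant"].mean() >= 0.8
        # flat background stays mostly unflagged in the adjusted model
        assert adj.loc[bg, "significant"].mean() <= 0.10

    def test_null_calibration_under_equal_composition(self):
        cfg = sd.SimConfig(
            n_samples_per_pool=2, n_nuclei_per_sample=400, doublet_rate=0.0,
            n_celltypes=2, n_genes=200, n_mito_genes=0,
            sample_groups=["non_tumor", "tumor"],
            composition_by_group={"non_tumor": [0.5, 0.5], "tumor": [0.5, 0.5]},
            seed=41,
        )
        dataset, truth = sd.simulate_confounded_expression(
            cfg, n_confounded=100, n_effect=0, n_background=100
        )
        # equal compositions: even "confounded" genes are marginally null
        X = dataset.counts.toarray()
        cells = pd.DataFrame(
            {
                "group": truth.cells["group"].to_numpy(),
                "cell_type": truth.cells["cell_type"].to_numpy(),
            },
            index=dataset.barcodes,
        )
        sf = X.sum(axis=1)
        for adjust in (True, False):
            res = run_de(X, dataset.gene_names, cells, sf, adjust=adjust)
            assert res["significant"].mean() <= 0.08

    def test_unknown_hvg_rejected(self, confounded_data):
        dataset, truth = confounded_data
        cells = pd.DataFrame(
            {
                "group": truth.cells["group"].to_numpy(),
                "cell_type": truth.cells["cell_type"].to_numpy(),
            },
            index=dataset.barcodes,
        )
        with pytest.raises(ValueError):
            run_de(
                dataset.counts, dataset.gene_names, cells,
                np.ones(len(dataset.barcodes)), hvg=["nope"],
            )


class TestCompareModels:
    def _table(self, rows, model):
        out = pd.DataFrame(rows, columns=["gene", "tumor_type", "estimate", "significant"])
        out["model"] = model
        return out

    def test_sign_discordant_examples_classified(self):
        # embryonal: -1.80 (adjusted) vs +0.42 (unadjusted), both significant;
        # schwannoma: +0.76 vs -0.52
        adjusted = self._table(
            [("FAT2", "EMB", -1.80, True), ("FGFR2", "SCH", 0.76, True)], "adjusted"
        )
        unadjusted = self._table(
            [("FAT2", "EMB", 0.42, True), ("FGFR2", "SCH", -0.52, True)], "unadjusted"
        )
        cmp = compare_models(adjusted, unadjusted)
        assert cmp.gene_table["sign_discordant"].all()
        assert (cmp.per_type["n_sign_discordant"] == 1).all()

    def test_identical_tables_have_empty_exclusive_sets(self):
        table = self._table(
            [("a", "T1", 0.5, True), ("b", "T1", -0.2, False)], "adjusted"
        )
        cmp = compare_models(table, table.assign(model="unadjusted"))
        row = cmp.per_type.iloc[0]
        assert row["n_adjusted_only"] == 0 and row["n_unadjusted_only"] == 0
        assert row["n_both"] == 1

    def test_exclusive_sets_disjoint(self):
        adjusted = self._table(
            [("a", "T1", 0.5, True), ("b", "T1", 0.3, False), ("c", "T1", 0.1, True)],
            "adjusted",
        )
        unadjusted = self._table(
            [("a", "T1", 0.6, True), ("b", "T1", 0.4, True), ("c", "T1", -0.1, False)],
            "unadjusted",
        )
        cmp = compare_models(adjusted, unadjusted)
        classes = cmp.gene_table.set_index("gene")["class"]
        assert classes["a"] == "both"
        assert classes["b"] == "unadjusted_only"
        assert classes["c"] == "adjusted_only"
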