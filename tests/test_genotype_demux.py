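"""Genotype deconvolution: likelihood arithmetic and posterior assignment.

The brute-force oracles recompute every hypothesis likelihood with scalar
arithmetic (math.comb / math.log), independent of the vectorized
implementation.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pedcns import synthetic_data as sd
from pedcns.genotype_demux import (
    UNASSIGNED,
    VariantRecord,
    assign_genotype,
    doublet_loglik,
    filter_variants,
    is_doublet_label,
    singlet_loglik,
)


def brute_binom_loglik(alt, depth, dosages, eps):
    """Scalar term-by-term binomial log-likelihood."""
    total = 0.0
    for a, d, g in zip(alt, depth, dosages):
        if d == 0 or g is None:
            continue
        mu = eps + (1 - 2 * eps) * g
        total += math.log(math.comb(int(d), int(a))) + a * math.log(mu) + (d - a) * math.log(1 - mu)
    return total


class TestFilterVariants:
    RECORDS = [
        VariantRecord("a", 9, 5),     # depth 9 < 10 -> dropped
        VariantRecord("b", 100, 5),   # af exactly 0.05, alt exactly 5 -> kept
        VariantRecord("c", 200, 5),   # af 0.025 < 0.05 -> dropped
        VariantRecord("d", 10, 4),    # alt 4 < 5 -> dropped
        VariantRecord("e", 10, 5),    # all at boundary -> kept
        VariantRecord("f", 1000, 999),  # comfortably kept
    ]

    def test_depth_rule(self):
        kept = filter_variants([VariantRecord("x", 9, 5)])
        assert kept == []

    def test_boundaries_inclusive(self):
        kept = filter_variants([VariantRecord("x", 100, 5)])
        assert len(kept) == 1

    def test_enumerated_truth_table(self):
        kept = {r.snp_id for r in filter_variants(self.RECORDS)}
        assert kept == {"b", "e", "f"}

    def test_dataframe_input(self):
        table = pd.DataFrame(
            {"depth": [r.depth for r in self.RECORDS], "alt_depth": [r.alt_depth for r in self.RECORDS]},
            index=[r.snp_id for r in self.RECORDS],
        )
        kept = filter_variants(table)
        assert set(kept.index) == {"b", "e", "f"}


class TestSingletLoglik:
    def test_hand_computed_value(self):
        # dosages (1, 0, 0.5), eps=0.01, alt/depth = (2/2, 0/2, 1/2):
        # 2 ln .99 + 2 ln .99 + ln(2 * .5 * .5) = -0.7333
        ll = singlet_loglik([2, 0, 1], [2, 2, 2], [1.0, 0.0, 0.5], eps=0.01)
        assert ll == pytest.approx(-0.7333, abs=5e-5)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        depth = rng.integers(0, 5, size=12)
        dosages = rng.choice([0.0, 0.5, 1.0], size=12)
        mu = 0.01 + 0.98 * dosages
        alt = rng.binomial(depth, mu)
        ours = singlet_loglik(alt, depth, dosages, eps=0.01)
        oracle = brute_binom_loglik(alt, depth, dosages, 0.01)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_perfect_homozygous_match_tends_to_zero(self):
        ll = singlet_loglik([3, 0], [3, 3], [1.0, 0.0], eps=1e-9)
        assert abs(ll) < 1e-6

    def test_missing_genotypes_skipped(self):
        full = singlet_loglik([1], [2], [0.5], eps=0.01)
        padded = singlet_loglik([1, 5], [2, 5], [0.5, np.nan], eps=0.01)
        assert padded == pytest.approx(full)

    def test_no_coverage_returns_zero(self):
        assert singlet_loglik([0, 0], [0, 0], [1.0, 0.0], eps=0.01) == 0.0

    def test_correct_donor_argmax_three_donor_toy(self):
        rng = np.random.default_rng(1)
        donors = {
            "d0": np.array([1.0, 1.0, 0.0, 0.0, 0.5]),
            "d1": np.array([0.0, 0.0, 1.0, 1.0, 0.5]),
            "d2": np.array([0.5, 0.5, 0.5, 0.5, 0.0]),
        }
        for true_name, dosages in donors.items():
            depth = np.full(5, 6)
            alt = rng.binomial(depth, 0.01 + 0.98 * dosages)
            scores = {n: singlet_loglik(alt, depth, d, 0.01) for n, d in donors.items()}
            brute = {n: brute_binom_loglik(alt, depth, d, 0.01) for n, d in donors.items()}
            assert max(scores, key=scores.get) == true_name
            assert max(brute, key=brute.get) == true_name


class TestDoubletLoglik:
    def test_identical_pair_degenerates_to_singlet(self):
        g = np.array([1.0, 0.0, 0.5])
        assert doublet_loglik([1, 0, 1], [2, 1, 2], g, g) == pytest.approx(
            singlet_loglik([1, 0, 1], [2, 1, 2], g)
        )

    def test_symmetric_in_pair_order(self):
        gi = np.array([1.0, 0.0])
        gj = np.array([0.0, 1.0])
        a, d = [1, 1], [2, 2]
        assert doublet_loglik(a, d, gi, gj) == doublet_loglik(a, d, gj, gi)

    def test_doublet_beats_both_singlets_on_mixed_cell(self):
        n_snps = 20
        gi = np.ones(n_snps)
        gj = np.zeros(n_snps)
        rng = np.random.default_rng(3)
        depth = np.full(n_snps, 4)
        alt = rng.binomial(depth, 0.5)
        ll_i = singlet_loglik(alt, depth, gi)
        ll_j = singlet_loglik(alt, depth, gj)
        ll_d = doublet_loglik(alt, depth, gi, gj)
        # cross-check with the scalar oracle likelihood table
        assert ll_d == pytest.approx(brute_binom_loglik(alt, depth, (gi + gj) / 2, 0.01), abs=1e-10)
        assert ll_d > max(ll_i, ll_j)


class TestAssignGenotype:
    def _brute_posteriors(self, alt, depth, genotypes, eps, delta):
        donors = list(genotypes.index)
        hyps, priors = [], []
        for d in donors:
            hyps.append(genotypes.loc[d].to_numpy())
            priors.append((1 - delta) / len(donors))
        pairs = list(itertools.combinations(donors, 2))
        for a, b in pairs:
            hyps.append((genotypes.loc[a].to_numpy() + genotypes.loc[b].to_numpy()) / 2)
            priors.append(delta / len(pairs))
        weights = [
            p * math.exp(brute_binom_loglik(alt, depth, h, eps))
            for p, h in zip(priors, hyps)
        ]
        total = sum(weights)
        return np.array([w / total for w in weights])

    def test_posteriors_match_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        genotypes = pd.DataFrame(
            rng.choice([0.0, 0.5, 1.0], size=(4, 8)),
            index=[f"sample_{i}" for i in range(4)],
            columns=[f"snp_{j}" for j in range(8)],
        )
        genotypes.iloc[0, 0], genotypes.iloc[1, 0] = 0.0, 1.0  # ensure distinct
        rows = []
        for c in range(6):
            for j in range(8):
                d = int(rng.integers(0, 4))
                if d:
                    a = int(rng.binomial(d, 0.5))
                    rows.append({"cell": f"c{c}", "snp": f"snp_{j}", "ref_count": d - a, "alt_count": a})
        cells = pd.DataFrame(rows)
        calls = assign_genotype(cells, genotypes, eps=0.01, delta=0.05, tau=0.9)
        post_cols = [c for c in calls.columns if c.startswith("post_")]
        for cell_id, group in cells.groupby("cell"):
            alt = np.zeros(8)
            depth = np.zeros(8)
            for _, r in group.iterrows():
                j = int(r["snp"].split("_")[1])
                alt[j] += r["alt_count"]
                depth[j] += r["alt_count"] + r["ref_count"]
            brute = self._brute_posteriors(alt, depth, genotypes, 0.01, 0.05)
            ours = calls.loc[cell_id, post_cols].to_numpy(dtype=float)
            assert np.allclose(ours, brute, atol=1e-10)

    def test_posteriors_sum_to_one(self, small_pool):
        _, genotypes, dataset, _ = small_pool
        calls = assign_genotype(dataset.allele_counts, genotypes)
        post = calls[[c for c in calls.columns if c.startswith("post_")]].to_numpy()
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_no_coverage_cell_unassigned_with_flat_posterior(self):
        genotypes = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["sample_0", "sample_1"],
            columns=["snp_0", "snp_1"],
        )
        cells = pd.DataFrame(
            [{"cell": "c0", "snp": "snp_0", "ref_count": 0, "alt_count": 0}]
        )
        calls = assign_genotype(cells, genotypes)
        assert calls.loc["c0", "label"] == UNASSIGNED
        post = calls.loc["c0", [c for c in calls.columns if c.startswith("post_")]]
        assert np.allclose(post.to_numpy(dtype=float), 1.0 / 3.0)

    def test_two_donor_single_snp_hand_table(self):
        genotypes = pd.DataFrame(
            [[1.0], [0.0]], index=["sample_0", "sample_1"], columns=["snp_0"]
        )
        cells = pd.DataFrame(
            [{"cell": "c0", "snp": "snp_0", "ref_count": 0, "alt_count": 2}]
        )
        calls = assign_genotype(cells, genotypes, eps=0.01, delta=0.05, tau=0.5)
        brute = self._brute_posteriors([2], [2], genotypes, 0.01, 0.05)
        post = calls.loc["c0", [c for c in calls.columns if c.startswith("post_")]]
        assert np.allclose(post.to_numpy(dtype=float), brute, atol=1e-10)
        assert calls.loc["c0", "label"] == "sample_0"

    def test_recovery_on_simulated_pool(self):
        # 50 SNPs at mean depth 2, eps 0.01, delta 0.05, 4 donors, 4000 cells
        cfg = sd.SimConfig(
            n_samples_per_pool=4, n_nuclei_per_sample=1000, doublet_rate=0.05,
            n_snps=50, snp_depth_mean=2.0, allele_error=0.01,
            n_genes=60, program_size=10, n_mito_genes=5, seed=13,
        )
        genotypes = sd.simulate_genotypes(cfg)
        dataset, truth = sd.simulate_pool(cfg, genotypes)
        calls = assign_genotype(dataset.allele_counts, genotypes).reindex(dataset.barcodes)
        calls["label"] = calls["label"].fillna(UNASSIGNED)
        tr = truth.cells.set_index("barcode")
        singlet_calls = calls[calls["label"].isin(cfg.sample_names)]
        true_singlets = ~tr.loc[singlet_calls.index, "is_doublet"]
        accuracy = (
            singlet_calls["label"][true_singlets.to_numpy()]
            == tr.loc[singlet_calls.index, "sample_of_origin"][true_singlets.to_numpy()]
        ).mean()
        assert accuracy >= 0.95
        doublets = calls[tr["is_doublet"].to_numpy()]
        assert doublets["label"].map(is_doublet_label).mean() >= 0.5

    def test_accuracy_monotone_in_depth(self):
        accs = []
        for depth in (0.3, 1.0, 4.0):
            cfg = sd.SimConfig(
                n_samples_per_pool=3, n_nuclei_per_sample=300, doublet_rate=0.0,
                n_snps=30, snp_depth_mean=depth,
                n_genes=60, program_size=10, n_mito_genes=5, seed=17,
            )
            genotypes = sd.simulate_genotypes(cfg)
            dataset, truth = sd.simulate_pool(cfg, genotypes)
            calls = assign_genotype(dataset.allele_counts, genotypes, tau=0.0).reindex(dataset.barcodes)
            tr = truth.cells.set_index("barcode")
            ok = (calls["label"] == tr["sample_of_origin"]).mean()
            accs.append(ok)
        assert accs[0] < accs[1] < accs[2]
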