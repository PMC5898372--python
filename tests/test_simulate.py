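"""Synthetic cohort generator: genotypes, response model, tree sampling."""

import numpy as np
import pandas as pd
import pytest

import dicohort as dc
from dicohort.simulate import (
    TreeModel,
    assemble_cohort,
    random_tree_model,
    sample_genotypes,
    sample_response,
    sample_tree_cohort,
    study_default_config,
)


class TestSampleGenotypes:
    def test_complete_inbreeding_removes_heterozygotes(self):
        col = sample_genotypes(0.3, 2000, F=1.0, seed=1, alleles=("A", "C"))
        assert "A/C" not in set(col)

    def test_het_fraction_matches_hwe_expectation(self):
        # maf 0.5, F = 0: heterozygote probability is exactly 0.5
        n = 10_000
        col = sample_genotypes(0.5, n, seed=2, alleles=("A", "C"))
        het = np.mean(col == "A/C")
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * se

    def test_call_rate_matches_target(self):
        n = 10_000
        col = sample_genotypes(0.3, n, call_rate=0.85, seed=3)
        observed = np.mean(col != "NA")
        se = np.sqrt(0.85 * 0.15 / n)
        assert abs(observed - 0.85) < 3 * se

    @pytest.mark.parametrize(
        "kwargs", [{"maf": 0.0}, {"maf": 1.0}, {"F": -0.1}, {"F": 1.5},
                   {"call_rate": 0.0}]
    )
    def test_parameter_validation(self, kwargs):
        args = {"maf": 0.3, "n": 10, "F": 0.0, "call_rate": 1.0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            sample_genotypes(args["maf"], args["n"], F=args["F"],
                             call_rate=args["call_rate"])

    def test_hwe_calibration_of_conforming_columns(self):
        """Columns generated with F = 0 pass the HWE test at alpha = 0.05 in
        roughly 95% of seeds."""
        from dicohort import GenotypeCounts, hwe_test

        passes = 0
        n_seeds = 200
        for seed in range(n_seeds):
            col = sample_genotypes(0.35, 495, seed=seed, alleles=("A", "C"))
            counts = GenotypeCounts(
                int(np.sum(col == "A/A")), int(np.sum(col == "A/C")),
                int(np.sum(col == "C/C")),
            )
            passes += hwe_test(counts)[1] > 0.05
        rate = passes / n_seeds
        se = np.sqrt(0.95 * 0.05 / n_seeds)
        assert abs(rate - 0.95) < 3.5 * se


class TestSampleResponse:
    def test_null_model_is_balanced(self):
        n = 10_000
        cols = pd.DataFrame({"x": ["a"] * n})
        resp = sample_response(cols, [], intercept=0.0, seed=4)
        frac = np.mean(resp == "Res")
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_dangling_reference_raises(self):
        cols = pd.DataFrame({"x": ["a", "b"]})
        with pytest.raises(KeyError):
            sample_response(cols, [("nope", "a", 1.0)], 0.0, seed=0)
        schema = [dc.VariableSchema("x", "categorical", ("a", "b"))]
        with pytest.raises(KeyError):
            sample_response(cols, [("x", "zz", 1.0)], 0.0, seed=0, schema=schema)

    def test_planted_or_is_recovered_with_nominal_coverage(self):
        """A heterozygote effect of OR 1.33 planted at n = 5000: the Woolf
        95% CI covers the true value in >= 90 of 100 seeds."""
        from dicohort import ContingencyTable2x2, odds_ratio_ci

        target = 1.33
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(40_000 + seed)
            geno = sample_genotypes(0.39, 5000, seed=rng, alleles=("A", "C"))
            cols = pd.DataFrame({"snp": geno})
            resp = sample_response(
                cols, [("snp", "A/C", float(np.log(target)))], -1.0, seed=rng
            )
            het = cols["snp"] == "A/C"
            res = resp == "Res"
            t = ContingencyTable2x2(
                int(np.sum(het & res)), int(np.sum(het & ~res)),
                int(np.sum(~het & res)), int(np.sum(~het & ~res)),
            )
            _, lo, hi, _ = odds_ratio_ci(t)
            covered += lo <= target <= hi
        assert covered >= 90

    def test_strong_planted_or_reaches_bonferroni_significance(self):
        """OR 4 at n = 5000 is flagged after Bonferroni correction in
        >= 95% of seeds."""
        from dicohort import ContingencyTable2x2, bonferroni, chi_square_2x2

        flagged = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(50_000 + seed)
            geno = sample_genotypes(0.39, 5000, seed=rng, alleles=("A", "C"))
            cols = pd.DataFrame({"snp": geno})
            resp = sample_response(
                cols, [("snp", "A/C", float(np.log(4.0)))], -1.5, seed=rng
            )
            het = cols["snp"] == "A/C"
            res = resp == "Res"
            t = ContingencyTable2x2(
                int(np.sum(het & res)), int(np.sum(het & ~res)),
                int(np.sum(~het & res)), int(np.sum(~het & ~res)),
            )
            p = chi_square_2x2(t)[1]
            flagged += bonferroni(p, 36) < 0.05  # 9 SNPs x 4 models
        assert flagged >= round(0.95 * n_seeds)


def chain_model(L=6, q=3, strength=0.5) -> TreeModel:
    names = [f"V{i}" for i in range(L)]
    edges = [(names[i], names[i + 1]) for i in range(L - 1)]
    table = (1 - strength) / q * np.ones((q, q)) + strength * np.eye(q)
    return TreeModel(
        names=names,
        alphabets={n: tuple(f"s{k}" for k in range(q)) for n in names},
        edges=edges, root=names[0], root_marginal=np.full(q, 1 / q),
        conditionals={e: table.copy() for e in edges},
    )


class TestTreeCohort:
    def test_identity_couplings_copy_root_everywhere(self):
        model = chain_model(strength=1.0)
        cohort = sample_tree_cohort(model, 200, seed=5)
        codes = cohort.codes()
        assert (codes == codes[:, [0]]).all()

    def test_uniform_couplings_give_independence(self):
        model = chain_model(strength=0.0)
        cohort = sample_tree_cohort(model, 20_000, seed=6)
        codes = cohort.codes()
        # empirical MI between adjacent variables shrinks to the O(q^2/2N) bias
        for i in range(5):
            joint = np.zeros((3, 3))
            np.add.at(joint, (codes[:, i], codes[:, i + 1]), 1.0)
            joint /= joint.sum()
            fa, fb = joint.sum(1), joint.sum(0)
            mask = joint > 0
            mi = np.sum(joint[mask] * np.log(joint[mask] / np.outer(fa, fb)[mask]))
            assert mi < 5e-4

    def test_chain_pair_marginals_match_exact_marginalization(self):
        """Empirical adjacent-pair joints at n = 5000 sit within 3 SE of the
        analytic tree marginals (computed by direct matrix propagation)."""
        s = 0.5
        model = chain_model(strength=s)
        n = 5000
        cohort = sample_tree_cohort(model, n, seed=7)
        codes = cohort.codes()
        T = (1 - s) / 3 * np.ones((3, 3)) + s * np.eye(3)
        marginal = np.full(3, 1 / 3)
        for i in range(5):
            exact = marginal[:, None] * T  # P(V_i, V_{i+1})
            emp = np.zeros((3, 3))
            np.add.at(emp, (codes[:, i], codes[:, i + 1]), 1.0)
            emp /= n
            se = np.sqrt(exact * (1 - exact) / n)
            assert np.all(np.abs(emp - exact) <= 3.2 * se)
            marginal = marginal @ T

    def test_cyclic_edge_set_rejected(self):
        names = ["A", "B", "C"]
        q = 2
        table = np.full((2, 2), 0.5)
        with pytest.raises(ValueError, match="tree"):
            TreeModel(
                names=names,
                alphabets={n: ("s0", "s1") for n in names},
                edges=[("A", "B"), ("B", "C"), ("C", "A")],
                root="A", root_marginal=np.full(q, 0.5),
                conditionals={("A", "B"): table, ("B", "C"): table,
                              ("C", "A"): table},
            )

    def test_random_tree_model_is_reproducible(self):
        m1 = random_tree_model(8, 3, 0.4, seed=9)
        m2 = random_tree_model(8, 3, 0.4, seed=9)
        assert m1.edges == m2.edges


class TestAssembleCohort:
    def test_default_dimensions(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort.n_patients == 495
        assert len(cohort.variables_of_kind("genotype")) == 14
        assert len(cohort.variables_of_kind("drug")) == 21
        assert cohort.response_variable.name == "response"

    def test_same_seed_reproduces_identical_cohort(self):
        c1, t1 = assemble_cohort(seed=42)
        c2, t2 = assemble_cohort(seed=42)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_frame_equal(c1.raw, c2.raw)
        assert t1.intercept == t2.intercept

    def test_prevalence_tracks_target(self):
        fracs = []
        for seed in range(10):
            cohort, truth = assemble_cohort(seed=100 + seed)
            fracs.append(float((cohort.data["response"] == "Res").mean()))
        assert abs(np.mean(fracs) - 0.287) < 0.03

    def test_hba1c_is_consistent_with_response_label(self, default_cohort):
        cohort, _ = default_cohort
        hba1c = cohort.raw["hba1c"]
        resp = cohort.data["response"]
        assert (hba1c[resp == "Res"] <= 7.0).all()
        assert (hba1c[resp == "NonRes"] > 7.0).all()

    def test_nine_snps_survive_qc_in_typical_draws(self):
        """The default generator plants 9 QC-conforming SNPs among 14; the
        surviving count is 9 in the majority (and the mode) of 50 seeds."""
        from collections import Counter

        from dicohort import apply_qc

        counts = Counter()
        for seed in range(50):
            cohort, _ = assemble_cohort(seed=seed)
            report, _ = apply_qc(cohort)
            counts[len(report.surviving)] += 1
        assert counts[9] > 25
        assert counts.most_common(1)[0][0] == 9

    def test_ground_truth_records_all_snps(self, default_cohort):
        _, truth = default_cohort
        assert len(truth.snp_params) == 14
        conforming = [n for n, p in truth.snp_params.items() if p["conforming"]]
        assert len(conforming) == 9
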