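"""Mean-field coupling inference and direct information.

The key oracle: for any pair, the two-site model and its DI can be computed
independently of the package's fixed-point iteration by solving the
marginal-matching equations with a generic root finder and enumerating the
q_i x q_j grid directly.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import dicohort as dc
from dicohort.dca import (
    DEFAULT_PSEUDOCOUNT,
    correlation_matrix,
    direct_information,
    empirical_frequencies,
    mean_field_couplings,
    two_site_distribution,
)

from conftest import build_cohort


def random_cohort(rng, n, specs):
    """specs: list of (name, states, probs) for independent columns."""
    cols = {}
    for name, states, probs in specs:
        cols[name] = (states, rng.choice(states, size=n, p=probs))
    return build_cohort(cols)


def coupled_pair_cohort(rng, n, copy_prob=0.7, q=3):
    states = tuple(f"s{k}" for k in range(q))
    x = rng.choice(states, size=n)
    noise = rng.random(n) >= copy_prob
    y = np.where(noise, rng.choice(states, size=n), x)
    return build_cohort({"X": (states, x), "Y": (states, y)})


# -- independent oracle ----------------------------------------------------


def oracle_two_site_di(e_block, fi, fj):
    """Solve the marginal-matching problem independently — BFGS on the
    convex dual (logsumexp(e + h_i + h_j) - fi.h_i - fj.h_j, whose gradient
    is the marginal mismatch) — then enumerate the grid to get DI.  Shares
    no code with the package's fitting path."""
    from scipy.special import logsumexp

    qi, qj = e_block.shape

    def obj(fields):
        hi, hj = fields[:qi], fields[qi:]
        return logsumexp(e_block + hi[:, None] + hj[None, :]) - fi @ hi - fj @ hj

    sol = optimize.minimize(
        obj, np.zeros(qi + qj), method="BFGS",
        options={"gtol": 1e-12, "maxiter": 20_000},
    )
    hi, hj = sol.x[:qi], sol.x[qi:]
    M = e_block + hi[:, None] + hj[None, :]
    P = np.exp(M - M.max())
    P /= P.sum()
    assert max(np.max(np.abs(P.sum(1) - fi)), np.max(np.abs(P.sum(0) - fj))) < 1e-7
    di = 0.0
    for a in range(qi):
        for b in range(qj):
            if P[a, b] > 0:
                di += P[a, b] * np.log(P[a, b] / (fi[a] * fj[b]))
    return max(di, 0.0)


def oracle_pair_frequencies(cohort, lam):
    """Regularized pair/single frequencies recomputed via pandas crosstab."""
    (va, vb) = cohort.schema
    ct = pd.crosstab(cohort.data[va.name], cohort.data[vb.name])
    ct = ct.reindex(index=list(va.states), columns=list(vb.states), fill_value=0)
    n = cohort.n_patients
    fij = (1 - lam) * ct.to_numpy() / n + lam / (va.q * vb.q)
    fa = fij.sum(axis=1)
    fb = fij.sum(axis=0)
    return fij, fa, fb


# -- frequencies -----------------------------------------------------------


class TestFrequencies:
    def test_full_regularization_is_uniform(self, rng):
        cohort = coupled_pair_cohort(rng, 50)
        freqs = empirical_frequencies(cohort, lam=1.0)
        for f in freqs.fi:
            assert np.allclose(f, 1.0 / len(f))

    def test_zero_regularization_matches_raw_counts(self, rng):
        cohort = coupled_pair_cohort(rng, 200)
        freqs = empirical_frequencies(cohort, lam=0.0)
        counts = cohort.data["X"].value_counts()
        for k, s in enumerate(cohort.schema[0].states):
            assert freqs.fi[0][k] == pytest.approx(counts.get(s, 0) / 200)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 0.5, 0.9])
    def test_marginalization_and_symmetry_invariants(self, rng, lam):
        specs = [
            ("A", ("x", "y"), (0.3, 0.7)),
            ("B", ("x", "y", "z"), (0.2, 0.3, 0.5)),
            ("C", ("u", "v", "w", "t"), (0.25,) * 4),
        ]
        cohort = random_cohort(rng, 120, specs)
        freqs = empirical_frequencies(cohort, lam=lam)
        freqs.validate()  # sums to 1, marginal consistency at 1e-12
        blk = freqs.pair(0, 1)
        assert np.allclose(blk, freqs.pair(1, 0).T)

    def test_single_state_variable_rejected_at_lam_zero(self):
        cohort = build_cohort(
            {"A": (("x", "y"), ["x"] * 20), "B": (("u", "v"), ["u", "v"] * 10)}
        )
        with pytest.raises(ValueError, match="lam"):
            empirical_frequencies(cohort, lam=0.0)


class TestCorrelationMatrix:
    def test_independent_pair_has_zero_offdiag_block(self):
        # deterministic balanced cohort: X and Y independent by construction
        x = ["a", "a", "b", "b"] * 25
        y = ["u", "v"] * 50
        cohort = build_cohort({"X": (("a", "b"), x), "Y": (("u", "v"), y)})
        freqs = empirical_frequencies(cohort, lam=0.0)
        C = correlation_matrix(freqs)
        assert C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        cohort = coupled_pair_cohort(rng, 150, q=4)
        C = correlation_matrix(empirical_frequencies(cohort, lam=0.2))
        assert np.array_equal(C, C.T)

    def test_perfectly_matched_binary_pair_entry(self):
        # P(both = first state) = P(both = second) = 0.5: C_XY = 0.5 - 0.25
        x = ["a", "b"] * 50
        cohort = build_cohort({"X": (("a", "b"), x), "Y": (("a", "b"), x)})
        C = correlation_matrix(empirical_frequencies(cohort, lam=0.0))
        assert C[0, 1] == pytest.approx(0.25)


class TestMeanFieldCouplings:
    def test_independent_columns_give_near_zero_couplings(self, rng):
        specs = [
            ("A", ("x", "y"), (0.5, 0.5)),
            ("B", ("u", "v"), (0.5, 0.5)),
            ("C", ("p", "q"), (0.5, 0.5)),
        ]
        cohort = random_cohort(rng, 4000, specs)
        _, model = dc.fit_couplings(cohort, lam=0.01)
        for (i, j), blk in model.blocks.items():
            assert np.max(np.abs(blk)) < 0.25  # O(1/sqrt(N)) noise scale

    def test_coupling_blocks_are_symmetric_partners(self, rng):
        cohort = random_cohort(
            rng, 300,
            [("A", ("x", "y", "z"), (0.2, 0.3, 0.5)),
             ("B", ("u", "v"), (0.6, 0.4)),
             ("C", ("p", "q"), (0.3, 0.7))],
        )
        _, model = dc.fit_couplings(cohort, lam=0.1)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert np.array_equal(model.coupling(i, j), model.coupling(j, i).T)

    def test_gauge_rows_and_columns_are_zero(self, rng):
        cohort = coupled_pair_cohort(rng, 200, q=3)
        _, model = dc.fit_couplings(cohort, lam=0.1)
        e = model.blocks[(0, 1)]
        assert np.all(e[-1, :] == 0) and np.all(e[:, -1] == 0)

    def test_singular_matrix_error_advises_pseudocount(self):
        # two perfectly identical columns at lam=0 make C singular
        x = ["a", "b", "a", "b"] * 30
        cohort = build_cohort({"X": (("a", "b"), x), "Y": (("a", "b"), x)})
        freqs = empirical_frequencies(cohort, lam=0.0)
        C = correlation_matrix(freqs)
        with pytest.raises(np.linalg.LinAlgError, match="pseudocount"):
            mean_field_couplings(C, freqs)


class TestTwoSiteModel:
    def test_zero_coupling_fixed_point_is_product(self):
        fi = np.array([0.2, 0.3, 0.5])
        fj = np.array([0.1, 0.2, 0.3, 0.4])
        ts = two_site_distribution(np.zeros((3, 4)), fi, fj)
        assert ts.converged and ts.iterations <= 2
        assert np.allclose(ts.P, np.outer(fi, fj), atol=1e-12)

    def test_marginal_residual_postcondition(self, rng):
        for _ in range(10):
            e = rng.normal(0, 1.0, size=(3, 3))
            e[-1, :] = e[:, -1] = 0
            fi = rng.dirichlet(np.ones(3))
            fj = rng.dirichlet(np.ones(3))
            ts = two_site_distribution(e, fi, fj)
            assert ts.converged
            assert ts.residual < 1e-6

    def test_positive_diagonal_coupling_concentrates_mass(self):
        fi = fj = np.array([0.5, 0.5])
        e = np.array([[2.0, 0.0], [0.0, 0.0]])
        ts = two_site_distribution(e, fi, fj)
        product_diag = 0.5
        assert ts.P[0, 0] + ts.P[1, 1] > product_diag

    def test_matches_root_finder_oracle(self, rng):
        for _ in range(5):
            e = rng.normal(0, 0.8, size=(3, 4))
            e[-1, :] = 0
            e[:, -1] = 0
            fi = rng.dirichlet(np.ones(3) * 3)
            fj = rng.dirichlet(np.ones(4) * 3)
            ts = two_site_distribution(e, fi, fj)
            di_pkg = direct_information(ts, fi, fj)
            di_oracle = oracle_two_site_di(e, fi, fj)
            assert di_pkg == pytest.approx(di_oracle, abs=1e-6)


class TestDirectInformation:
    def test_zero_coupling_gives_zero_di(self):
        fi = np.array([0.4, 0.6])
        fj = np.array([0.3, 0.7])
        ts = two_site_distribution(np.zeros((2, 2)), fi, fj)
        assert direct_information(ts, fi, fj) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_coupled_binary_pair_matches_enumeration(self, rng):
        """Two identical binary columns at N = 10^4, lam = 0.05: the whole
        pipeline agrees with the exhaustive 2x2 oracle to 1e-6."""
        x = rng.choice(["a", "b"], size=10_000)
        cohort = build_cohort({"X": (("a", "b"), x), "Y": (("a", "b"), x)})
        lam = 0.05
        di = dc.di_matrix(cohort, lam=lam)
        freqs, model = dc.fit_couplings(cohort, lam=lam)
        di_oracle = oracle_two_site_di(model.blocks[(0, 1)], freqs.fi[0], freqs.fi[1])
        assert di.values[0, 1] == pytest.approx(di_oracle, abs=1e-6)

    def test_symmetric_and_nonnegative(self, rng):
        cohort = random_cohort(
            rng, 400,
            [("A", ("x", "y", "z"), (0.3, 0.3, 0.4)),
             ("B", ("u", "v"), (0.5, 0.5)),
             ("C", ("p", "q", "r"), (0.2, 0.4, 0.4))],
        )
        di = dc.di_matrix(cohort, lam=0.1)
        assert np.allclose(di.values, di.values.T)
        assert (di.values >= 0).all()


class TestDIMatrixPipeline:
    def test_two_variable_matrix_is_single_pairwise_value(self, rng):
        cohort = coupled_pair_cohort(rng, 500)
        di = dc.di_matrix(cohort, lam=0.1)
        freqs, model = dc.fit_couplings(cohort, lam=0.1)
        ts = two_site_distribution(model.blocks[(0, 1)], freqs.fi[0], freqs.fi[1])
        assert di.values[0, 1] == pytest.approx(
            direct_information(ts, freqs.fi[0], freqs.fi[1])
        )

    def test_patient_order_is_irrelevant(self, rng):
        cohort = random_cohort(
            rng, 200,
            [("A", ("x", "y"), (0.4, 0.6)),
             ("B", ("u", "v", "w"), (0.3, 0.3, 0.4)),
             ("C", ("p", "q"), (0.5, 0.5))],
        )
        perm = rng.permutation(cohort.data.index)
        shuffled = cohort.subset_patients(list(perm))
        d1 = dc.di_matrix(cohort, lam=0.2)
        d2 = dc.di_matrix(shuffled, lam=0.2)
        assert np.allclose(d1.values, d2.values, atol=1e-12)

    def test_planted_pair_dominates_independent_background(self, rng):
        """Monotone-signal property: the coupled pair ranks top in >= 19/20
        seeds on cohorts of independent variables plus one planted pair."""
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(9000 + seed)
            n = 5000
            cols = {
                f"N{k}": (("a", "b", "c"), r.choice(["a", "b", "c"], size=n))
                for k in range(5)
            }
            x = r.choice(["a", "b", "c"], size=n)
            noise = r.random(n) >= 0.5
            y = np.where(noise, r.choice(["a", "b", "c"], size=n), x)
            cols["P1"] = (("a", "b", "c"), x)
            cols["P2"] = (("a", "b", "c"), y)
            cohort = build_cohort(cols)
            di = dc.di_matrix(cohort, lam=0.05)
            v = di.values.copy()
            np.fill_diagonal(v, -np.inf)
            i, j = np.unravel_index(np.argmax(v), v.shape)
            hits += {di.names[i], di.names[j]} == {"P1", "P2"}
        assert hits >= 19

    def test_gauge_independence_of_di(self, rng):
        cohort = random_cohort(
            rng, 300,
            [("A", ("x", "y", "z"), (0.2, 0.3, 0.5)),
             ("B", ("u", "v"), (0.6, 0.4)),
             ("C", ("p", "q", "r"), (0.4, 0.3, 0.3))],
        )
        d_last = dc.di_matrix(cohort, lam=0.1)
        d_first = dc.di_matrix(cohort, lam=0.1, ref_states=[0, 0, 0])
        assert np.allclose(d_last.values, d_first.values, atol=1e-8)

    def test_invariant_under_state_relabeling(self, rng):
        x = rng.choice(["a", "b", "c"], size=400)
        noise = rng.random(400) >= 0.6
        y = np.where(noise, rng.choice(["u", "v"], size=400), np.where(x == "a", "u", "v"))
        cohort = build_cohort({"X": (("a", "b", "c"), x), "Y": (("u", "v"), y)})
        relabel = {"a": "zz", "b": "aa", "c": "mm"}
        cohort2 = build_cohort(
            {
                "X": (tuple(relabel[s] for s in ("a", "b", "c")),
                      np.array([relabel[s] for s in x])),
                "Y": (("u", "v"), y),
            }
        )
        d1 = dc.di_matrix(cohort, lam=0.1)
        d2 = dc.di_matrix(cohort2, lam=0.1)
        assert d1.values[0, 1] == pytest.approx(d2.values[0, 1], abs=1e-12)
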