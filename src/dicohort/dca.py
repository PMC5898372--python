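"""Mean-field direct coupling analysis over heterogeneous categorical variables.

The cohort is modeled by a Boltzmann-like (Potts) joint distribution

    P(x_1 .. x_L) = (1/Z) exp( sum_{i<j} e_ij(x_i, x_j) + sum_i h_i(x_i) )

whose pairwise couplings ``e_ij`` are estimated by the mean-field
approximation: the negative inverse of the pseudocount-regularized connected
correlation matrix, computed on reduced state spaces (one reference state per
variable is gauged to zero).  Variables may have different alphabet sizes
q_i, so all linear algebra is done on a block matrix of dimension
sum_i (q_i - 1) with an explicit offset map.

Direct information (DI) for a pair (i, j) is the Kullback-Leibler divergence
between the pair's two-site model distribution — built from e_ij with
auxiliary fields fitted so its marginals match the empirical single-site
frequencies — and the product of those single-site frequencies.  DI is
reported in nats and is invariant to the gauge (reference-state) choice.

The normalization constant Z is never computed; it is unnecessary for the
mean-field couplings and for DI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DiscreteCohort, VariableSchema

__all__ = [
    "FrequencyModel",
    "CouplingModel",
    "TwoSiteModel",
    "DIMatrix",
    "empirical_frequencies",
    "correlation_matrix",
    "mean_field_couplings",
    "two_site_distribution",
    "direct_information",
    "di_matrix",
    "fit_couplings",
]

DEFAULT_PSEUDOCOUNT = 0.5
TWO_SITE_TOL = 1e-6
TWO_SITE_MAX_ITER = 500

_MARGINAL_ATOL = 1e-12


@dataclass
class FrequencyModel:
    """Pseudocount-regularized single-site and pairwise frequencies.

    ``fi[i]`` has length q_i; ``fij[(i, j)]`` (stored for i < j) has shape
    (q_i, q_j).  The mixing convention is

        f_i(x)    = (1 - lam) fhat_i(x)    + lam / q_i
        f_ij(x,y) = (1 - lam) fhat_ij(x,y) + lam / (q_i q_j)    (i != j)

    and the same-site "joint" is diagonal: f_ii(x,y) = delta_xy f_i(x).
    """

    names: list[str]
    qs: list[int]
    fi: list[np.ndarray]
    fij: dict[tuple[int, int], np.ndarray]
    lam: float
    n_samples: int

    @property
    def n_variables(self) -> int:
        return len(self.qs)

    def pair(self, i: int, j: int) -> np.ndarray:
        """Joint frequency block for any (i, j), handling order and i == j."""
        if i == j:
            return np.diag(self.fi[i])
        if i < j:
            return self.fij[(i, j)]
        return self.fij[(j, i)].T

    def validate(self, atol: float = _MARGINAL_ATOL) -> None:
        """Check normalization and marginal-consistency invariants."""
        for i, f in enumerate(self.fi):
            if abs(f.sum() - 1.0) > atol:
                raise AssertionError(f"f_{i} does not sum to 1")
        for (i, j), blk in self.fij.items():
            if abs(blk.sum() - 1.0) > atol:
                raise AssertionError(f"f_({i},{j}) does not sum to 1")
            if np.max(np.abs(blk.sum(axis=1) - self.fi[i])) > atol:
                raise AssertionError(f"row marginal of f_({i},{j}) != f_{i}")
            if np.max(np.abs(blk.sum(axis=0) - self.fi[j])) > atol:
                raise AssertionError(f"col marginal of f_({i},{j}) != f_{j}")


def _one_hot(codes: np.ndarray, qs: list[int]) -> np.ndarray:
    """Dense one-hot expansion of an integer state matrix, (N, sum q_i)."""
    n, L = codes.shape
    D = sum(qs)
    X = np.zeros((n, D), dtype=np.float64)
    offset = 0
    rows = np.arange(n)
    for j, q in enumerate(qs):
        X[rows, offset + codes[:, j]] = 1.0
        offset += q
    return X


def _frequencies_from_gram(
    gram: np.ndarray,
    n: int,
    names: list[str],
    qs: list[int],
    lam: float,
) -> FrequencyModel:
    offsets = np.concatenate([[0], np.cumsum(qs)])
    fi = []
    for i, q in enumerate(qs):
        raw = np.diag(gram)[offsets[i] : offsets[i] + q] / n
        fi.append((1.0 - lam) * raw + lam / q)
    fij = {}
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            raw = gram[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]] / n
            fij[(i, j)] = (1.0 - lam) * raw + lam / (qs[i] * qs[j])
    return FrequencyModel(names=list(names), qs=list(qs), fi=fi, fij=fij,
                          lam=lam, n_samples=n)


def empirical_frequencies(
    cohort: DiscreteCohort, lam: float = DEFAULT_PSEUDOCOUNT
) -> FrequencyModel:
    """Count single-site and pairwise state frequencies, pseudocount-mixed.

    ``lam`` in [0, 1] mixes the raw count frequencies with the uniform
    distribution; ``lam > 0`` guarantees an invertible correlation matrix.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"pseudocount weight must be in [0, 1], got {lam}")
    if cohort.n_patients < 2:
        raise ValueError("need at least two patients to estimate frequencies")
    codes = cohort.codes()
    qs = [v.q for v in cohort.schema]
    if lam == 0.0:
        for j, var in enumerate(cohort.schema):
            if len(np.unique(codes[:, j])) < 2:
                raise ValueError(
                    f"variable {var.name!r} shows a single state and lam=0; "
                    "use lam > 0 to regularize"
                )
    X = _one_hot(codes, qs)
    gram = X.T @ X
    return _frequencies_from_gram(
        gram, cohort.n_patients, cohort.variable_names, qs, lam
    )


# -- correlation matrix and mean-field inversion ---------------------------


def _reduced_index(
    qs: list[int], ref: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Offsets of each variable's reduced block and the kept state indices."""
    red_sizes = [q - 1 for q in qs]
    red_offsets = np.concatenate([[0], np.cumsum(red_sizes)])
    keep = [np.array([x for x in range(q) if x != r]) for q, r in zip(qs, ref)]
    return red_offsets, keep


def correlation_matrix(
    freqs: FrequencyModel, ref_states: list[int] | None = None
) -> np.ndarray:
    """Connected correlation block matrix on reduced state spaces.

    ``C_ij(x, y) = f_ij(x, y) - f_i(x) f_j(y)`` for all ordered pairs
    including i == j, with each variable's reference state (default: the
    last) removed, giving a symmetric matrix of dimension sum_i (q_i - 1).
    """
    L = freqs.n_variables
    ref = ref_states if ref_states is not None else [q - 1 for q in freqs.qs]
    red_offsets, keep = _reduced_index(freqs.qs, ref)
    D = red_offsets[-1]
    C = np.zeros((D, D))
    for i in range(L):
        for j in range(i, L):
            block = freqs.pair(i, j) - np.outer(freqs.fi[i], freqs.fi[j])
            sub = block[np.ix_(keep[i], keep[j])]
            C[red_offsets[i] : red_offsets[i + 1], red_offsets[j] : red_offsets[j + 1]] = sub
            if i != j:
                C[red_offsets[j] : red_offsets[j + 1], red_offsets[i] : red_offsets[i + 1]] = sub.T
    return C


@dataclass
class CouplingModel:
    """Mean-field couplings and fields of the Boltzmann-like cohort model.

    ``blocks[(i, j)]`` (i < j) is the full (q_i, q_j) coupling block with the
    reference row and column gauged to zero.  ``fields[i]`` is h_i under the
    same gauge (h_i(ref) = 0), recovered from the mean-field consistency
    relation.  Z is symbolic — never computed.
    """

    names: list[str]
    qs: list[int]
    blocks: dict[tuple[int, int], np.ndarray]
    fields: list[np.ndarray]
    ref_states: list[int]
    lam: float
    n_samples: int

    def coupling(self, i: int, j: int) -> np.ndarray:
        if i == j:
            raise ValueError("self-couplings are not defined")
        return self.blocks[(i, j)] if i < j else self.blocks[(j, i)].T

    def index(self, name: str) -> int:
        return self.names.index(name)


def mean_field_couplings(
    C: np.ndarray,
    freqs: FrequencyModel,
    ref_states: list[int] | None = None,
) -> CouplingModel:
    """Invert the correlation matrix: e_ij(x, y) = -(C^-1)_ij(x, y).

    Off-diagonal blocks of the negative inverse are the coupling estimates on
    reduced states; they are embedded into full (q_i, q_j) blocks with zeros
    at the reference states.  Fields h_i are recovered from the mean-field
    self-consistency  h_i(x) = ln f_i(x)/f_i(ref) - sum_j e_ij(x, .) f_j.
    """
    ref = ref_states if ref_states is not None else [q - 1 for q in freqs.qs]
    red_offsets, keep = _reduced_index(freqs.qs, ref)
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; re-run with a pseudocount lam > 0"
        ) from exc
    L = freqs.n_variables
    blocks: dict[tuple[int, int], np.ndarray] = {}
    for i in range(L):
        for j in range(i + 1, L):
            e = np.zeros((freqs.qs[i], freqs.qs[j]))
            sub = -invC[
                red_offsets[i] : red_offsets[i + 1], red_offsets[j] : red_offsets[j + 1]
            ]
            e[np.ix_(keep[i], keep[j])] = sub
            blocks[(i, j)] = e
    model = CouplingModel(
        names=list(freqs.names), qs=list(freqs.qs), blocks=blocks,
        fields=[], ref_states=list(ref), lam=freqs.lam, n_samples=freqs.n_samples,
    )
    fields = []
    for i in range(L):
        fi = freqs.fi[i]
        h = np.log(fi / fi[ref[i]])
        for j in range(L):
            if j == i:
                continue
            h = h - model.coupling(i, j) @ freqs.fi[j]
        fields.append(h - h[ref[i]])
    model.fields = fields
    return model


@dataclass
class TwoSiteModel:
    """Pair distribution P_ij under the inferred coupling block.

    P_ij(x, y) is proportional to exp(e_ij(x, y) + ht_i(x) + ht_j(y)) with
    the auxiliary fields ht fitted by alternating marginal matching until the
    worst marginal residual falls below tolerance.
    """

    pair: tuple[int, int]
    P: np.ndarray
    h_i: np.ndarray
    h_j: np.ndarray
    iterations: int
    residual: float
    converged: bool


def two_site_distribution(
    e_block: np.ndarray,
    fi: np.ndarray,
    fj: np.ndarray,
    tol: float = TWO_SITE_TOL,
    max_iter: int = TWO_SITE_MAX_ITER,
    pair: tuple[int, int] = (-1, -1),
) -> TwoSiteModel:
    """Fit the two-site model for one pair by alternating marginal matching.

    The fixed-point iteration updates the two auxiliary field vectors so the
    row/column marginals of P match ``fi`` / ``fj``; with e_ij == 0 the exact
    fixed point is the product distribution.  The alternating scaling can
    stall (sublinear rate) on near-degenerate blocks with extreme couplings;
    if it misses tolerance within the iteration budget, a damped Newton
    refinement of the convex dual finishes the job.  Residual convergence is
    always reported, never silent.
    """
    W = np.exp(e_block)
    mu_i = np.full(len(fi), 1.0 / len(fi))
    mu_j = np.full(len(fj), 1.0 / len(fj))
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu_i = fi / (W @ mu_j)
        mu_i /= mu_i.sum()
        mu_j = fj / (W.T @ mu_i)
        mu_j /= mu_j.sum()
        P = mu_i[:, None] * W * mu_j[None, :]
        P /= P.sum()
        residual = max(
            np.max(np.abs(P.sum(axis=1) - fi)), np.max(np.abs(P.sum(axis=0) - fj))
        )
        if residual < tol:
            break
    h_i, h_j = np.log(mu_i), np.log(mu_j)
    if residual >= tol:
        h_i, h_j, residual = _newton_fields(e_block, fi, fj, h_i, h_j, tol)
    M = e_block + h_i[:, None] + h_j[None, :]
    P = np.exp(M - M.max())
    P /= P.sum()
    return TwoSiteModel(
        pair=pair, P=P, h_i=h_i, h_j=h_j,
        iterations=it, residual=float(residual), converged=residual < tol,
    )


def _newton_fields(e_block, fi, fj, h_i, h_j, tol, max_iter=100):
    """Damped Newton on the dual of the marginal-matching problem.

    Minimizes logsumexp(e + h_i + h_j) - fi.h_i - fj.h_j, whose gradient is
    exactly the marginal residual; the (gauge-singular) Hessian step is
    solved by least squares.
    """
    qi, qj = e_block.shape

    def state(hi, hj):
        M = e_block + hi[:, None] + hj[None, :]
        Mmax = M.max()
        P = np.exp(M - Mmax)
        Z = P.sum()
        P /= Z
        obj = np.log(Z) + Mmax - fi @ hi - fj @ hj
        grad = np.concatenate([P.sum(1) - fi, P.sum(0) - fj])
        return P, obj, grad

    P, obj, grad = state(h_i, h_j)
    residual = np.max(np.abs(grad))
    for _ in range(max_iter):
        if residual < tol * 1e-3:
            break
        pi, pj = P.sum(1), P.sum(0)
        H = np.zeros((qi + qj, qi + qj))
        H[:qi, :qi] = np.diag(pi) - np.outer(pi, pi)
        H[qi:, qi:] = np.diag(pj) - np.outer(pj, pj)
        H[:qi, qi:] = P - np.outer(pi, pj)
        H[qi:, :qi] = H[:qi, qi:].T
        step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        t = 1.0
        for _ in range(40):  # backtracking line search
            hi_new = h_i + t * step[:qi]
            hj_new = h_j + t * step[qi:]
            P_new, obj_new, grad_new = state(hi_new, hj_new)
            if obj_new <= obj - 1e-4 * t * float(grad @ -step):
                break
            t *= 0.5
        h_i, h_j = hi_new, hj_new
        P, obj, grad = P_new, obj_new, grad_new
        residual = np.max(np.abs(grad))
    return h_i, h_j, float(residual)


def direct_information(
    pair_model: TwoSiteModel, fi: np.ndarray, fj: np.ndarray
) -> float:
    """KL divergence of the two-site distribution from the product model.

    DI = sum_{x,y} P_ij(x,y) ln [ P_ij(x,y) / (f_i(x) f_j(y)) ], in nats,
    with the 0 ln 0 = 0 convention; tiny negative rounding is clipped to 0.
    """
    P = pair_model.P
    prod = np.outer(fi, fj)
    mask = P > 0
    di = float(np.sum(P[mask] * np.log(P[mask] / prod[mask])))
    if di < 0:
        if di < -1e-10:
            raise FloatingPointError(f"direct information {di} below rounding floor")
        di = 0.0
    return di


@dataclass
class DIMatrix:
    """Symmetric L x L matrix of pairwise direct information (nats)."""

    names: list[str]
    values: np.ndarray
    lam: float
    non_converged: list[tuple[int, int]] = field(default_factory=list)

    def di(self, a: str, b: str) -> float:
        return float(self.values[self.names.index(a), self.names.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        L = len(self.names)
        for i in range(L):
            for j in range(i + 1, L):
                rows.append(
                    {"var_i": self.names[i], "var_j": self.names[j],
                     "di": float(self.values[i, j])}
                )
        return pd.DataFrame(rows)


def fit_couplings(
    cohort: DiscreteCohort,
    lam: float = DEFAULT_PSEUDOCOUNT,
    ref_states: list[int] | None = None,
) -> tuple[FrequencyModel, CouplingModel]:
    """Frequencies -> correlation matrix -> mean-field couplings, in one call."""
    freqs = empirical_frequencies(cohort, lam=lam)
    C = correlation_matrix(freqs, ref_states=ref_states)
    return freqs, mean_field_couplings(C, freqs, ref_states=ref_states)


def di_matrix(
    cohort: DiscreteCohort,
    lam: float = DEFAULT_PSEUDOCOUNT,
    ref_states: list[int] | None = None,
) -> DIMatrix:
    """Direct information for every variable pair of a cohort.

    Runs the full mean-field pipeline once, then fits a two-site model per
    pair.  Pairs whose marginal-matching iteration does not converge are
    recorded in ``non_converged``.
    """
    if cohort.n_variables < 2:
        raise ValueError("direct information needs at least two variables")
    freqs, model = fit_couplings(cohort, lam=lam, ref_states=ref_states)
    L = freqs.n_variables
    values = np.zeros((L, L))
    non_conv = []
    for i in range(L):
        for j in range(i + 1, L):
            ts = two_site_distribution(
                model.coupling(i, j), freqs.fi[i], freqs.fi[j], pair=(i, j)
            )
            if not ts.converged:
                non_conv.append((i, j))
            d = direct_information(ts, freqs.fi[i], freqs.fi[j])
            values[i, j] = values[j, i] = d
    return DIMatrix(names=list(freqs.names), values=values, lam=lam,
                    non_converged=non_conv)
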