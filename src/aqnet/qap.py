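"""QAP: matrix permutation tests for association between networks.

Networks over the same node set are compared cell-by-cell after
dropping the (undefined) diagonal.  The observed statistic is an
ordinary OLS fit of the vectorized dependent matrix on the vectorized
predictors (or a Pearson correlation for the two-matrix case).  The
reference distribution is built by permuting the *node labels* of the
dependent matrix — rows and columns jointly, so the dyadic structure is
preserved — and recomputing the statistic; this respects the
row/column dependence that invalidates conventional standard errors
for relational data.

Monte-Carlo p-values use the (count + 1) / (B + 1) convention and are
never exactly 0; for small networks an exhaustive mode enumerates all
n! permutations (identity included, p = count / n!).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "QAPConfig",
    "QAPFit",
    "vectorize_offdiag",
    "QAPRegression",
    "qap_regression",
    "qap_correlation",
]

TAILS = ("one_sided_as_extreme", "two_sided")


@dataclass(frozen=True)
class QAPConfig:
    n_permutations: int = 5000
    seed: int = 0
    tail: str = "one_sided_as_extreme"
    exhaustive: bool = False
    method: str = "y_permutation"  # or "dsp" (double semi-partialing)

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.method not in ("y_permutation", "dsp"):
            raise ValueError("method must be 'y_permutation' or 'dsp'")


@dataclass
class QAPFit:
    """Observed estimates with permutation p-values."""

    predictors: list[str]
    coefficients: dict[str, dict]  # name -> {"estimate", "p_value"}
    intercept: dict
    r_squared: float
    adj_r_squared: float
    r_squared_p: float
    n_permutations: int


def vectorize_offdiag(m: np.ndarray) -> np.ndarray:
    """Row-major vector of all off-diagonal entries (length n^2 - n)."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    return m[~np.eye(m.shape[0], dtype=bool)]


def _check_square(mats: list[np.ndarray]) -> int:
    n = None
    for m in mats:
        m = np.asarray(m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("all matrices must be square")
        if n is None:
            n = m.shape[0]
        elif m.shape[0] != n:
            raise ValueError("matrix dimension mismatch")
    return int(n)


def _permute(m: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Apply one node permutation to rows and columns jointly."""
    return m[np.ix_(pi, pi)]


def _tail_count(perm: np.ndarray, obs: float, tail: str) -> int:
    if tail == "two_sided":
        return int(np.sum(np.abs(perm) >= abs(obs) - 1e-12))
    # as-or-more extreme in the observed direction
    if obs >= 0:
        return int(np.sum(perm >= obs - 1e-12))
    return int(np.sum(perm <= obs + 1e-12))


def _permutations(n: int, cfg: QAPConfig):
    if cfg.exhaustive:
        if math.factorial(n) > 50000:
            raise ValueError("exhaustive mode only practical for n <= 7")
        return [np.array(p) for p in itertools.permutations(range(n))], True
    rng = np.random.default_rng(cfg.seed)
    return [rng.permutation(n) for _ in range(cfg.n_permutations)], False


class QAPRegression(BaseEstimator):
    """Multi-matrix QAP regression with permutation inference.

    Fits ``vec(Y) ~ 1 + vec(X_1) + ... + vec(X_k)`` on the off-diagonal
    cells, then permutes the node labels of Y (``n_permutations`` times,
    rows and columns together) and refits to obtain p-values for every
    coefficient and for R^2.

    Parameters
    ----------
    n_permutations : int
        Permutation draws (default 5000; ignored in exhaustive mode).
    random_state : int
        Seed for the permutation stream.
    tail : {"one_sided_as_extreme", "two_sided"}
        "one_sided_as_extreme" counts permutation statistics as or more
        extreme *in the observed direction*.
    exhaustive : bool
        Enumerate all n! node permutations (small n only).
    method : {"y_permutation", "dsp"}
        Plain dependent-matrix permutation, or Dekker's double
        semi-partialing (permute the residual of Y on the other
        predictors; more robust under collinear predictors).

    Attributes
    ----------
    coef_ : ndarray of predictor coefficients.
    intercept_ : float.
    pvalues_ : ndarray of permutation p-values (matches coef_).
    intercept_pvalue_, r_squared_, adj_r_squared_, r_squared_p_ : float.
    fit_result_ : QAPFit.
    """

    def __init__(
        self,
        n_permutations: int = 5000,
        random_state: int = 0,
        tail: str = "one_sided_as_extreme",
        exhaustive: bool = False,
        method: str = "y_permutation",
    ):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.tail = tail
        self.exhaustive = exhaustive
        self.method = method

    def _config(self) -> QAPConfig:
        return QAPConfig(
            n_permutations=self.n_permutations,
            seed=self.random_state,
            tail=self.tail,
            exhaustive=self.exhaustive,
            method=self.method,
        )

    def fit(self, X, y, predictor_names: list[str] | None = None):
        """Fit the matrix regression.

        ``X`` is a list (or 3-D stack) of k square matrices; ``y`` a
        square matrix of the same dimension (>= 4 nodes).
        """
        cfg = self._config()
        xs = [np.asarray(m, dtype=float) for m in X]
        if not xs:
            raise ValueError("need at least one predictor matrix")
        y = np.asarray(y, dtype=float)
        n = _check_square(xs + [y])
        if n < 4:
            raise ValueError("matrices must be at least 4 x 4")
        names = predictor_names or [f"x{i + 1}" for i in range(len(xs))]
        if len(names) != len(xs):
            raise ValueError("predictor_names length mismatch")

        Z = np.column_stack([np.ones(n * n - n)] + [vectorize_offdiag(m) for m in xs])
        rank = np.linalg.matrix_rank(Z)
        if rank < Z.shape[1]:
            raise ValueError(
                f"collinear predictors after vectorization: {names} "
                "(design matrix is rank deficient)"
            )
        yv = vectorize_offdiag(y)
        pinv = np.linalg.pinv(Z)
        beta = pinv @ yv
        resid = yv - Z @ beta
        sst = float(np.sum((yv - yv.mean()) ** 2))
        if sst <= 0:
            raise ValueError("dependent matrix has zero off-diagonal variance")
        sse = float(resid @ resid)
        r2 = 1.0 - sse / sst
        n_obs, k = Z.shape[0], len(xs)
        adj_r2 = 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - k - 1)

        perms, is_exhaustive = _permutations(n, cfg)
        B = len(perms)
        perm_beta = np.empty((B, k + 1))
        perm_r2 = np.empty(B)
        if cfg.method == "dsp":
            resid_mats = self._dsp_residual_matrices(xs, y, n)
        for b, pi in enumerate(perms):
            ypv = vectorize_offdiag(_permute(y, pi))
            bb = pinv @ ypv
            perm_beta[b] = bb
            ss = ypv - Z @ bb
            perm_r2[b] = 1.0 - float(ss @ ss) / float(
                np.sum((ypv - ypv.mean()) ** 2)
            )
        if cfg.method == "dsp":
            for j in range(k):
                ej = resid_mats[j]
                for b, pi in enumerate(perms):
                    epv = vectorize_offdiag(_permute(ej, pi))
                    perm_beta[b, j + 1] = (pinv @ epv)[j + 1]

        def pval(perm_stats: np.ndarray, obs: float) -> float:
            c = _tail_count(perm_stats, obs, cfg.tail)
            if is_exhaustive:
                return c / B
            return (c + 1) / (B + 1)

        coeffs = {
            name: {
                "estimate": float(beta[j + 1]),
                "p_value": pval(perm_beta[:, j + 1], beta[j + 1]),
            }
            for j, name in enumerate(names)
        }
        intercept = {
            "estimate": float(beta[0]),
            "p_value": pval(perm_beta[:, 0], beta[0]),
        }
        r2_p = (
            _tail_count(perm_r2, r2, "one_sided_as_extreme") / B
            if is_exhaustive
            else (_tail_count(perm_r2, r2, "one_sided_as_extreme") + 1) / (B + 1)
        )

        self.coef_ = beta[1:].copy()
        self.intercept_ = float(beta[0])
        self.pvalues_ = np.array([coeffs[nm]["p_value"] for nm in names])
        self.intercept_pvalue_ = intercept["p_value"]
        self.r_squared_ = r2
        self.adj_r_squared_ = adj_r2
        self.r_squared_p_ = r2_p
        self.predictor_names_ = names
        self.fit_result_ = QAPFit(
            predictors=names,
            coefficients=coeffs,
            intercept=intercept,
            r_squared=r2,
            adj_r_squared=adj_r2,
            r_squared_p=r2_p,
            n_permutations=B,
        )
        return self

    @staticmethod
    def _dsp_residual_matrices(
        xs: list[np.ndarray], y: np.ndarray, n: int
    ) -> list[np.ndarray]:
        """Residual matrix of Y on all predictors except j, per j."""
        yv = vectorize_offdiag(y)
        mask = ~np.eye(n, dtype=bool)
        out = []
        for j in range(len(xs)):
            others = [np.ones(n * n - n)] + [
                vectorize_offdiag(m) for i, m in enumerate(xs) if i != j
            ]
            Zo = np.column_stack(others)
            e = yv - Zo @ (np.linalg.pinv(Zo) @ yv)
            em = np.zeros((n, n))
            em[mask] = e
            out.append(em)
        return out


def qap_regression(
    y: np.ndarray,
    xs: list[np.ndarray],
    cfg: QAPConfig | None = None,
    predictor_names: list[str] | None = None,
) -> QAPFit:
    """Functional wrapper over :class:`QAPRegression`."""
    cfg = cfg or QAPConfig()
    est = QAPRegression(
        n_permutations=cfg.n_permutations,
        random_state=cfg.seed,
        tail=cfg.tail,
        exhaustive=cfg.exhaustive,
        method=cfg.method,
    ).fit(xs, y, predictor_names=predictor_names)
    return est.fit_result_


def qap_correlation(
    a: np.ndarray, b: np.ndarray, cfg: QAPConfig | None = None
) -> dict:
    """Pearson correlation of two networks with a QAP permutation p.

    Correlates the off-diagonal cells of ``a`` and ``b``; the null
    distribution jointly permutes the rows and columns of ``b``.
    """
    cfg = cfg or QAPConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = _check_square([a, b])
    av = vectorize_offdiag(a)
    bv = vectorize_offdiag(b)
    if av.std() < 1e-15 or bv.std() < 1e-15:
        raise ValueError("zero-variance matrix: correlation undefined")
    r_obs = float(np.corrcoef(av, bv)[0, 1])
    perms, is_exhaustive = _permutations(n, cfg)
    perm_r = np.array(
        [np.corrcoef(av, vectorize_offdiag(_permute(b, pi)))[0, 1] for pi in perms]
    )
    c = _tail_count(perm_r, r_obs, cfg.tail)
    p = c / len(perms) if is_exhaustive else (c + 1) / (len(perms) + 1)
    return {"r": r_obs, "p_value": p, "n_permutations": len(perms)}
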