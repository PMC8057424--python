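"""Multivariate adaptive regression splines (additive form).

A compact MARS estimator: the forward pass greedily adds reflected pairs of
hinge functions max(x_j - k, 0) / max(k - x_j, 0) at candidate knots placed
on marginal quantiles, scored by residual-sum-of-squares reduction; the
backward pass prunes terms by generalized cross-validation,

    GCV(M) = RSS / n / (1 - C(M)/n)^2,   C(M) = M + penalty * (M - 1) / 2,

with the conventional additive-model penalty of 2.  Interactions between
hinge terms are not constructed (degree-1 model), which is the form used
for imputation regressions on a modest number of baseline covariates.
"""

from __future__ import annotations

import numpy as np


class MarsRegressor:
    """Additive MARS with forward hinge selection and GCV pruning.

    Parameters
    ----------
    max_terms : maximum number of basis functions including the intercept.
    n_knots : candidate knots per variable (marginal quantiles).
    penalty : GCV cost per knot beyond the intercept.
    min_rss_decrease : forward pass stops when the relative RSS reduction
        of the best candidate falls below this.
    """

    def __init__(self, max_terms: int = 15, n_knots: int = 10,
                 penalty: float = 2.0, min_rss_decrease: float = 1e-8):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.penalty = penalty
        self.min_rss_decrease = min_rss_decrease

    # each basis term is (var_index, knot, direction) with direction +1 for
    # max(x-k, 0) and -1 for max(k-x, 0); the intercept is implicit.

    def _basis_column(self, X: np.ndarray, term) -> np.ndarray:
        j, knot, direction = term
        return np.maximum(direction * (X[:, j] - knot), 0.0)

    def _design(self, X: np.ndarray, terms) -> np.ndarray:
        cols = [np.ones(len(X))]
        cols.extend(self._basis_column(X, t) for t in terms)
        return np.column_stack(cols)

    def _gcv(self, rss: float, n: int, n_terms: int) -> float:
        c = n_terms + self.penalty * (n_terms - 1) / 2.0
        if c >= n:
            return np.inf
        return rss / n / (1.0 - c / n) ** 2

    def fit(self, X, y) -> "MarsRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        # candidate knots on interior quantiles of each variable
        qs = np.linspace(0.05, 0.95, self.n_knots)
        candidates: list[tuple[int, float]] = []
        for j in range(p):
            knots = np.unique(np.quantile(X[:, j], qs))
            lo, hi = X[:, j].min(), X[:, j].max()
            candidates.extend((j, float(k)) for k in knots if lo < k < hi)

        terms: list[tuple[int, float, int]] = []
        Q = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of current model
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        y_ss = max(rss, 1e-30)

        while len(terms) + 1 < self.max_terms and candidates:
            best = None
            for j, knot in candidates:
                pair = np.column_stack([
                    np.maximum(X[:, j] - knot, 0.0),
                    np.maximum(knot - X[:, j], 0.0)])
                A = pair - Q @ (Q.T @ pair)
                G = A.T @ A
                b = A.T @ resid
                # ridge-guard the 2x2 solve against collinear hinges
                G[np.diag_indices_from(G)] += 1e-10 * max(G[0, 0], G[1, 1], 1e-30)
                try:
                    coef = np.linalg.solve(G, b)
                except np.linalg.LinAlgError:
                    continue
                drop = float(b @ coef)
                if best is None or drop > best[0]:
                    best = (drop, j, knot, A)
            if best is None or best[0] < self.min_rss_decrease * y_ss:
                break
            drop, j, knot, A = best
            if len(terms) + 3 > self.max_terms:
                break
            for col in A.T:
                col = col - Q @ (Q.T @ col)
                nrm = np.linalg.norm(col)
                if nrm > 1e-10:
                    Q = np.column_stack([Q, col / nrm])
            terms.append((j, knot, +1))
            terms.append((j, knot, -1))
            resid = y - Q @ (Q.T @ y)
            rss = float(resid @ resid)

        # backward pruning by GCV
        def rss_of(subset) -> float:
            B = self._design(X, subset)
            coef, *_ = np.linalg.lstsq(B, y, rcond=None)
            r = y - B @ coef
            return float(r @ r)

        current = list(terms)
        best_subset = list(current)
        best_gcv = self._gcv(rss_of(current), n, len(current) + 1)
        while current:
            trial_best = None
            for i in range(len(current)):
                subset = current[:i] + current[i + 1:]
                g = self._gcv(rss_of(subset), n, len(subset) + 1)
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, subset)
            current = trial_best[1]
            if trial_best[0] <= best_gcv:
                best_gcv, best_subset = trial_best[0], list(current)

        self.terms_ = best_subset
        B = self._design(X, best_subset)
        self.coef_, *_ = np.linalg.lstsq(B, y, rcond=None)
        self.gcv_ = best_gcv
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._design(X, self.terms_) @ self.coef_
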