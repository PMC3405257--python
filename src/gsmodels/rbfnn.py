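"""Gaussian radial basis function network with OLS forward center selection.

The fitted function is

    f(x) = w0 + sum_m w_m exp(-h ||x - c_m||^2)

where the centers c_m are rows of the training covariate matrix chosen by
the orthogonal-least-squares (OLS) forward procedure of the Chen style:
candidate basis columns are orthogonalized (modified Gram-Schmidt) against
the span of the already-selected columns and the candidate with the largest
error-reduction ratio

    err = (q' y)^2 / ((q' q) (y' y))

is added, until 1 - sum(err) falls below a tolerance rho, or the neuron
budget M_max (or M = n) is reached.  Distances are raw (unstandardized)
Euclidean norms on the covariate scale fed in.  The output-layer weights
are ordinary least squares (no regularization by default); the bandwidth h
and the neuron count M are chosen on an inner 80/20 validation split of the
training data, then the network is refitted on the full training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RBFNNConfig",
    "RBFNetwork",
    "RBFNetworkResults",
    "rbf_design",
    "rbf_bandwidth_scale",
    "ols_select_centers",
]


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d2 = (
        np.einsum("ij,ij->i", A, A)[:, None]
        + np.einsum("ij,ij->i", B, B)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def rbf_design(X, centers, h: float) -> np.ndarray:
    """Basis matrix z[i, m] = exp(-h ||x_i - c_m||^2)."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {C.shape[1]}")
    return np.exp(-h * _sqdist(X, C))


def rbf_bandwidth_scale(X) -> float:
    """Median off-diagonal raw squared Euclidean distance of the rows.

    Serves the same role for the RBFNN that q05 plays for the RKHS kernels:
    it puts the bandwidth grid on the scale of the data.
    """
    X = np.asarray(X, dtype=float)
    d2 = _sqdist(X, X)
    iu = np.triu_indices(X.shape[0], k=1)
    return float(np.median(d2[iu]))


@dataclass(frozen=True)
class RBFNNConfig:
    """Tuning controls for the RBF network.

    ``gamma_grid`` lists dimensionless bandwidth multipliers; the actual
    grid is gamma / median(off-diagonal squared distance) of the training
    covariates, mirroring the bandwidth span used by the RKHS kernels.
    """

    max_neurons: int = 200
    rho: float = 0.01  # stop when unexplained variance share < rho
    gamma_grid: tuple = (5.0, 1.0, 0.2)
    val_fraction: float = 0.2
    n_val_splits: int = 3  # inner splits averaged when choosing (h, M)
    ridge: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie strictly between 0 and 1")
        if not self.gamma_grid or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("gamma_grid must be non-empty and positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.n_val_splits < 1:
            raise ValueError("need at least one inner validation split")


def _ols_path(Z, y, rho, m_max, Zval=None):
    """Greedy OLS forward selection on candidate basis columns.

    Z is n x C (one column per candidate center); y must already be
    centered.  Returns (selected, err, gamma, val_pred_path) where
    ``gamma`` are the regression coefficients on the orthogonalized columns
    and ``val_pred_path`` (if Zval given) stacks the incremental validation
    predictions after each selection step.
    """
    Q = np.array(Z, dtype=float)  # working copy, orthogonalized in place
    Qv = np.array(Zval, dtype=float) if Zval is not None else None
    n, C = Q.shape
    yty = float(y @ y)
    if yty <= 0:
        return [], [], [], (np.zeros((0, Qv.shape[0])) if Qv is not None else None)
    tol = 1e-12 * max(float((Q * Q).sum(axis=0).max()), 1.0)
    alive = np.ones(C, dtype=bool)
    selected, err, gamma = [], [], []
    val_path = [] if Qv is not None else None
    m_max = min(m_max, n, C)
    for _ in range(m_max):
        qn = np.einsum("ij,ij->j", Q, Q)
        dead = qn <= tol
        alive &= ~dead
        if not alive.any():
            warnings.warn(
                "all remaining candidate columns are numerically zero after "
                "orthogonalization; stopping selection early",
                stacklevel=2,
            )
            break
        qy = Q.T @ y
        ratio = np.where(alive, qy**2 / (np.where(qn > 0, qn, 1.0) * yty), -np.inf)
        pick = int(np.argmax(ratio))
        q = Q[:, pick].copy()
        qq = qn[pick]
        g = qy[pick] / qq
        selected.append(pick)
        err.append(float(ratio[pick]))
        gamma.append(float(g))
        alive[pick] = False
        if Qv is not None:
            qv = Qv[:, pick].copy()
            prev = val_path[-1] if val_path else np.zeros(Qv.shape[0])
            val_path.append(prev + g * qv)
        # modified Gram-Schmidt sweep against the newly selected column
        coef = (q @ Q) / qq
        coef[pick] = 0.0
        Q -= np.outer(q, coef)
        if Qv is not None:
            Qv -= np.outer(qv, coef)
        if 1.0 - sum(err) < rho:
            break
    val_pred = np.array(val_path) if val_path is not None else None
    return selected, err, gamma, val_pred


def ols_select_centers(y, X, h: float, cfg: RBFNNConfig):
    """Select RBF centers among all training rows for a fixed bandwidth.

    Returns (center indices, error-reduction ratios).  ``y`` is centered
    internally against the intercept.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = rbf_design(X, X, h)
    yc = y - y.mean()
    selected, err, _, _ = _ols_path(Z, yc, cfg.rho, cfg.max_neurons)
    return selected, err


def fit_output_layer(y, X, center_idx, h: float, ridge: float = 0.0):
    """Ordinary least squares for (w0, w) given centers and bandwidth.

    Uses lstsq (minimum-norm on rank deficiency, which is logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = rbf_design(X, X[center_idx], h)
    D = np.column_stack([np.ones(len(y)), Z])
    if ridge > 0:
        A = D.T @ D + ridge * np.eye(D.shape[1])
        A[0, 0] -= ridge  # never penalize the intercept
        coefs = np.linalg.solve(A, D.T @ y)
    else:
        coefs, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
        if rank < D.shape[1]:
            warnings.warn(
                f"output-layer design is rank deficient ({rank}/{D.shape[1]}); "
                "minimum-norm solution used",
                stacklevel=2,
            )
    return float(coefs[0]), coefs[1:]


class RBFNetwork:
    """Model object: response vs. covariates through Gaussian RBF neurons."""

    def __init__(self, endog, exog, config: RBFNNConfig | None = None):
        y = endog.ybar if hasattr(endog, "ybar") else endog
        self.y = np.asarray(y, dtype=float)
        X = exog.values if hasattr(exog, "values") else np.asarray(exog)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("exog must be 2-D with one row per response")
        self.config = config or RBFNNConfig()

    @property
    def n(self) -> int:
        return self.y.size

    def fit(self) -> "RBFNetworkResults":
        """Inner-validated bandwidth / neuron-count choice, then a full refit.

        The (h, M) pair minimizes the validation PMSE averaged over
        ``n_val_splits`` seeded inner splits, which stabilizes the choice
        against the noise of any single split.
        """
        cfg = self.config
        n = self.n
        scale = rbf_bandwidth_scale(self.X)
        if scale <= 0:
            raise ValueError("all covariate rows identical; no bandwidth scale")
        grid = [g / scale for g in cfg.gamma_grid]

        rng = np.random.default_rng(cfg.seed)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        d2_full = _sqdist(self.X, self.X)
        # per h: summed PMSE paths across splits (truncated to common length)
        paths = {h: [] for h in grid}
        for _ in range(cfg.n_val_splits):
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            y_tr, y_val = self.y[tr_idx], self.y[val_idx]
            ybar_tr = y_tr.mean()
            inner_m_max = min(cfg.max_neurons, tr_idx.size)
            d2_tr = d2_full[np.ix_(tr_idx, tr_idx)]
            d2_val = d2_full[np.ix_(val_idx, tr_idx)]
            for h in grid:
                Z = np.exp(-h * d2_tr)
                Zval = np.exp(-h * d2_val)
                _, err, _, val_pred = _ols_path(
                    Z, y_tr - ybar_tr, cfg.rho, inner_m_max, Zval
                )
                if err:
                    pmse = ((val_pred + ybar_tr - y_val[None, :]) ** 2).mean(axis=1)
                    paths[h].append(pmse)

        best = None  # (mean pmse, h, M)
        for h in grid:
            if len(paths[h]) < cfg.n_val_splits:
                continue
            m_common = min(p.size for p in paths[h])
            mean_path = np.mean([p[:m_common] for p in paths[h]], axis=0)
            m_best = int(np.argmin(mean_path)) + 1
            pmse = float(mean_path[m_best - 1])
            if best is None or pmse < best[0]:
                best = (pmse, h, m_best)
        if best is None:
            # response constant within tolerance: intercept-only network
            return RBFNetworkResults(
                model=self, h=grid[0], center_indices=np.array([], dtype=int),
                w0=float(self.y.mean()), w=np.array([]), err_path=[],
                inner_pmse=float(np.var(self.y)), rho=cfg.rho,
            )
        pmse, h, m_star = best

        # refit on the full training data with the chosen (h, M)
        Z_full = np.exp(-h * d2_full)
        yc = self.y - self.y.mean()
        selected, err, _, _ = _ols_path(Z_full, yc, 0.0, m_star)
        center_idx = np.asarray(selected, dtype=int)
        w0, w = fit_output_layer(self.y, self.X, center_idx, h, cfg.ridge)
        return RBFNetworkResults(
            model=self, h=h, center_indices=center_idx, w0=w0, w=w,
            err_path=err, inner_pmse=pmse, rho=cfg.rho,
        )


@dataclass
class RBFNetworkResults:
    """A fitted RBF network: centers, bandwidth and output-layer weights."""

    model: RBFNetwork
    h: float
    center_indices: np.ndarray
    w0: float
    w: np.ndarray
    err_path: list = field(default_factory=list)
    inner_pmse: float = np.nan
    rho: float = np.nan

    @property
    def centers(self) -> np.ndarray:
        return self.model.X[self.center_indices]

    @property
    def n_neurons(self) -> int:
        return self.center_indices.size

    def predict(self, exog) -> np.ndarray:
        X = exog.values if hasattr(exog, "values") else np.asarray(exog)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"exog must have {self.model.X.shape[1]} columns, got {X.shape[1]}"
            )
        if self.n_neurons == 0:
            return np.full(X.shape[0], self.w0)
        return self.w0 + rbf_design(X, self.centers, self.h) @ self.w

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    def summary(self) -> str:
        explained = float(sum(self.err_path))
        return "\n".join(
            [
                "Gaussian RBF network (OLS center selection)",
                f"  lines: {self.model.n}   neurons: {self.n_neurons}",
                f"  bandwidth h = {self.h:.6g}   stopping rho = {self.rho}",
                f"  inner-validation PMSE = {self.inner_pmse:.4f}",
                f"  training variance explained by selection = {explained:.3f}",
            ]
        )
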