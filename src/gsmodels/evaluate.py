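"""Repeated-partition model comparison: correlation, PMSE and win counts.

The protocol draws 50 independent random partitions of the lines into 90%
training / 10% testing (shared by all models), fits every model on each
training fold, and scores test-fold predictions by Pearson correlation and
predictive mean squared error PMSE = mean((ybar - yhat)^2).  Win counts use
strict ">" on the per-partition correlations; ties are reported separately.

Phenotypes are standardized once on the full data set before partitioning
(the protocol this harness mirrors); a leakage-safe per-fold variant is
available behind ``standardize_per_fold`` for sensitivity checks.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayesian_lasso import BayesianLasso, BLHyperparams
from .data import DegenerateInputError
from .kernels import (
    DEFAULT_BANDWIDTHS,
    build_kernels,
    cross_distance,
    cross_kernels,
    distance_matrix,
)
from .rbfnn import RBFNetwork, RBFNNConfig
from .rkhs import KernelAverageRKHS, RKHSHyperparams

__all__ = [
    "PartitionPlan",
    "EvalResult",
    "ModelSpec",
    "make_partitions",
    "score",
    "run_comparison",
    "derive_seed",
]


@dataclass
class PartitionPlan:
    """A list of shared train/test splits of n lines."""

    n: int
    train_fraction: float
    partitions: list  # list of (train_idx, test_idx) arrays
    seed: int

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)


def make_partitions(
    n: int, n_partitions: int = 50, train_fraction: float = 0.9, seed: int = 0
) -> PartitionPlan:
    """Seeded random 90/10 partitions; each test set has round(0.1 n) lines."""
    if n < 10:
        raise ValueError("need at least 10 lines to partition")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    n_test = int(round((1.0 - train_fraction) * n))
    if n_test < 1 or n_test >= n:
        raise ValueError(f"train fraction {train_fraction} leaves no usable test set")
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_partitions):
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        parts.append((train, test))
    return PartitionPlan(n=n, train_fraction=train_fraction, partitions=parts, seed=seed)


def score(y_test, y_pred):
    """(Pearson correlation, PMSE) of predictions against observations."""
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_test.shape != y_pred.shape:
        raise ValueError("y_test and y_pred must have equal length")
    if y_test.size < 3:
        raise ValueError("need at least 3 test observations")
    if np.ptp(y_test) == 0:
        raise DegenerateInputError("y_test is constant; correlation undefined")
    pmse = float(np.mean((y_test - y_pred) ** 2))
    if np.ptp(y_pred) == 0:
        return 0.0, pmse  # constant prediction carries no ranking information
    r = float(stats.pearsonr(y_test, y_pred).statistic)
    return r, pmse


def derive_seed(master: int, *parts) -> int:
    """Deterministic per-(partition, model) seed below 2^31."""
    ints = [int(master) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(p) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31 - 1))


@dataclass
class ModelSpec:
    """One model entry for the comparison harness.

    kind is "bl", "rkhs" or "rbfnn"; ``options`` overrides chain controls
    (n_iter, burn_in, thin) or RBFNN config fields (max_neurons, rho, ...);
    ``bandwidths`` applies to the RKHS kernels.
    """

    name: str
    kind: str
    options: dict = field(default_factory=dict)
    bandwidths: tuple = DEFAULT_BANDWIDTHS

    def __post_init__(self):
        if self.kind not in ("bl", "rkhs", "rbfnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")


def _fit_predict(spec: ModelSpec, y_tr, X_tr, X_te, seed: int):
    if spec.kind == "bl":
        opts = {k: v for k, v in spec.options.items() if k != "store_beta_chain"}
        hp = BLHyperparams(seed=seed, **opts)
        res = BayesianLasso(y_tr, X_tr).fit(hp, store_beta_chain=False)
        return res.predict(X_te)
    if spec.kind == "rkhs":
        dist = distance_matrix(X_tr)
        ks = build_kernels(dist, spec.bandwidths)
        hp = RKHSHyperparams(seed=seed, **spec.options)
        res = KernelAverageRKHS(y_tr, ks).fit(hp)
        blocks = cross_kernels(cross_distance(X_te, X_tr, dist), ks)
        return res.predict(blocks)
    cfg = RBFNNConfig(seed=seed, **spec.options)
    res = RBFNetwork(y_tr, X_tr, cfg).fit()
    return res.predict(X_te)


@dataclass
class EvalResult:
    """Per-partition scores, per-model means, and pairwise win counts."""

    per_partition: pd.DataFrame  # columns: partition, model, corr, pmse
    model_names: list
    n_partitions: int
    failed_partitions: list = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.failed_partitions)

    def mean_correlation(self, model: str) -> float:
        sub = self.per_partition[self.per_partition["model"] == model]
        return float(sub["corr"].mean())

    def mean_pmse(self, model: str) -> float:
        sub = self.per_partition[self.per_partition["model"] == model]
        return float(sub["pmse"].mean())

    def wins(self, model_a: str, model_b: str, metric: str = "corr"):
        """(strict wins of a over b, strict wins of b over a, ties)."""
        wide = self.per_partition.pivot(index="partition", columns="model", values=metric)
        a, b = wide[model_a].to_numpy(), wide[model_b].to_numpy()
        better = a > b if metric == "corr" else a < b
        worse = b > a if metric == "corr" else b < a
        return int(better.sum()), int(worse.sum()), int((a == b).sum())

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.model_names:
            rows.append(
                {
                    "model": m,
                    "mean_corr": self.mean_correlation(m),
                    "mean_pmse": self.mean_pmse(m),
                }
            )
        return pd.DataFrame(rows)

    def wins_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations(self.model_names, 2):
            wa, wb, ties = self.wins(a, b)
            rows.append({"pair": f"{a}>{b}", "wins": wa, "losses": wb, "ties": ties})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Model comparison over {self.n_partitions} partitions "
            f"({len(self.failed_partitions)} failed)",
            self.summary_frame().to_string(index=False),
            self.wins_frame().to_string(index=False),
        ]
        return "\n\n".join(lines)

    def plot_correlations(self, model_x: str, model_y: str, path=None):
        """Scatter of per-partition correlations of two models (45-degree line)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        wide = self.per_partition.pivot(index="partition", columns="model", values="corr")
        fig, ax = plt.subplots(figsize=(5, 5))
        x, y = wide[model_x], wide[model_y]
        ax.scatter(x, y, facecolors=np.where(y > x, "white", "black"), edgecolors="black")
        lo = min(x.min(), y.min()) - 0.05
        hi = max(x.max(), y.max()) + 0.05
        ax.plot([lo, hi], [lo, hi], "k-", lw=0.8)
        ax.set_xlabel(f"correlation, {model_x}")
        ax.set_ylabel(f"correlation, {model_y}")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def run_comparison(
    y,
    X,
    models,
    plan: PartitionPlan,
    master_seed: int | None = None,
    standardize_per_fold: bool = False,
) -> EvalResult:
    """Fit every model on every shared training fold and score the test folds.

    ``y`` is the (already standardized) response vector; ``X`` the covariate
    matrix shared by all models.  MCMC/selection seeds are derived
    deterministically from (master seed, partition index, model name).  A
    model failure on a partition excludes that partition from all models'
    summaries and flags the run.
    """
    y = np.asarray(y.ybar if hasattr(y, "ybar") else y, dtype=float)
    X = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    if master_seed is None:
        master_seed = plan.seed
    rows, failed = [], []
    for k, (tr, te) in enumerate(plan.partitions):
        y_tr, y_te = y[tr], y[te]
        if standardize_per_fold:
            sd = y_tr.std(ddof=1)
            y_tr, y_te = y_tr / sd, y_te / sd
        part_rows, ok = [], True
        for spec in models:
            seed = derive_seed(master_seed, k, spec.name)
            try:
                pred = _fit_predict(spec, y_tr, X[tr], X[te], seed)
                r, pmse = score(y_te, pred)
            except Exception as exc:  # noqa: BLE001 - recorded, partition dropped
                warnings.warn(f"partition {k}, model {spec.name}: {exc}", stacklevel=2)
                failed.append((k, spec.name, str(exc)))
                ok = False
                break
            part_rows.append({"partition": k, "model": spec.name, "corr": r, "pmse": pmse})
        if ok:
            rows.extend(part_rows)
    per_partition = pd.DataFrame(rows, columns=["partition", "model", "corr", "pmse"])
    return EvalResult(
        per_partition=per_partition,
        model_names=[m.name for m in models],
        n_partitions=plan.n_partitions,
        failed_partitions=failed,
    )
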