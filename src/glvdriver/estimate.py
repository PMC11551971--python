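"""gLV parameter estimation by regularized gradient matching.

Dividing the gLV equation by the abundance turns it into a regression that
is linear in the unknown parameters:

.. math::

    f_j'(t) / f_j(t) = \\alpha_j + \\sum_k \\beta_{jk} f_k(t),

so, given estimated curves ``fhat`` and derivatives ``fhat'`` evaluated at
the observed time points (pooled over subjects), each taxon's growth rate
and interaction row can be estimated by penalized least squares — ridge,
lasso or elastic net — without ever integrating the ODE during fitting.

Two design constructions are provided: the spline design (responses and
predictors from the NB smoothing-spline fits) and a difference-based
baseline (log-difference responses with pseudo-count 1, interval-midpoint
predictors from raw counts).  Penalty strength is chosen per taxon by
subject-grouped k-fold cross-validation; the intercept (growth rate) is
never penalized and predictors are standardized internally, with
coefficients reported on the original scale.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import GroupKFold

from .glv import CommunityModel
from .preprocess import SmoothedTrajectory, smooth_dataset
from .simulate import TimeSeriesDataset

__all__ = [
    "RegressionDesign",
    "FitResult",
    "build_spline_design",
    "build_difference_design",
    "fit_regularized",
    "estimate_model",
    "DEFAULT_LAMBDA_GRIDS",
]

logger = logging.getLogger(__name__)

METHODS = ("ridge", "lasso", "elastic_net")
ELASTIC_NET_MIXING = 0.5

DEFAULT_LAMBDA_GRIDS: dict[str, np.ndarray] = {
    "ridge": np.logspace(-4, 4, 17),
    "lasso": np.logspace(-8, -1, 15),
    "elastic_net": np.logspace(-8, -1, 15),
}


@dataclasses.dataclass
class RegressionDesign:
    """Pooled gradient-matching regression arrays.

    ``predictors`` is the shared ``N x p`` matrix of abundance values;
    ``responses[:, j]`` is taxon ``j``'s per-capita growth-rate response.
    ``groups`` carries the subject label of each row for grouped CV.
    ``response_mask[:, j]`` marks the rows that are valid observations of
    taxon ``j``'s per-capita rate — the rate ``f'_j / f_j`` is a 0/0
    degeneracy while the taxon is effectively absent, so such rows are
    excluded from regression ``j`` (they remain predictors for the others).
    """

    predictors: np.ndarray
    responses: np.ndarray
    groups: np.ndarray
    taxa: list[str]
    tag: str = "spline"
    response_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.predictors, dtype=float)
        Y = np.asarray(self.responses, dtype=float)
        if X.ndim != 2 or Y.shape != X.shape or X.shape[1] != len(self.taxa):
            raise ValueError("inconsistent design dimensions")
        if len(self.groups) != X.shape[0]:
            raise ValueError("group labels must match row count")
        if self.response_mask is None:
            self.response_mask = np.ones(X.shape, dtype=bool)
        else:
            self.response_mask = np.asarray(self.response_mask, dtype=bool)
            if self.response_mask.shape != X.shape:
                raise ValueError("response_mask must match design shape")
        if not np.all(np.isfinite(X)):
            raise ValueError("design contains non-finite predictors")
        if not np.all(np.isfinite(Y[self.response_mask])):
            raise ValueError("design contains non-finite responses")
        self.predictors, self.responses = X, Y
        self.groups = np.asarray(self.groups)


@dataclasses.dataclass
class FitResult:
    """Estimated community model with its provenance."""

    model: CommunityModel
    lambdas: np.ndarray  # per-taxon selected penalty
    method: str
    design_tag: str
    settings: dict = dataclasses.field(default_factory=dict)


def build_spline_design(
    smoothed: Mapping[tuple[str, str], SmoothedTrajectory],
    eval_times: Mapping[str, Sequence[float]],
    taxa: Sequence[str],
    min_abundance: float = 1.0,
) -> RegressionDesign:
    """Evaluate smoothed curves/derivatives on each subject's grid.

    Response for taxon ``j`` is ``fhat'_j / fhat_j`` and the predictors are
    all taxa's ``fhat`` at the same (subject, time).  Rows where a taxon's
    fitted abundance falls below ``min_abundance`` (roughly one organism —
    the taxon is effectively absent, so its per-capita rate is a 0/0
    degeneracy) or that lie outside the span of the taxon's positive
    observations (where the curve extrapolates through zeros) are masked
    out of that taxon's own regression; degenerate all-zero fits are masked
    entirely.
    """
    taxa = list(taxa)
    rows_x, rows_y, rows_m, groups = [], [], [], []
    for subject, times in eval_times.items():
        times = np.asarray(times, dtype=float)
        fhat = np.empty((times.size, len(taxa)))
        fprime = np.empty_like(fhat)
        mask = np.ones_like(fhat, dtype=bool)
        for k, taxon in enumerate(taxa):
            try:
                traj = smoothed[(subject, taxon)]
            except KeyError:
                raise ValueError(
                    f"missing smoothed trajectory for subject {subject!r}, "
                    f"taxon {taxon!r}"
                ) from None
            fhat[:, k] = traj.curve(times)
            fprime[:, k] = traj.derivative(times)
            if traj.degenerate:
                mask[:, k] = False
            else:
                mask[:, k] = fhat[:, k] >= min_abundance
                if traj.support is not None:
                    lo, hi = traj.support
                    mask[:, k] &= (times >= lo) & (times <= hi)
        rows_x.append(fhat)
        rows_y.append(fprime / fhat)
        rows_m.append(mask)
        groups.extend([subject] * times.size)
    return RegressionDesign(
        predictors=np.vstack(rows_x), responses=np.vstack(rows_y),
        groups=np.asarray(groups), taxa=taxa, tag="spline",
        response_mask=np.vstack(rows_m),
    )


def build_difference_design(dataset: TimeSeriesDataset) -> RegressionDesign:
    """Difference-based baseline design from raw counts.

    For each within-subject interval ``(s, s+1)`` the response is
    ``(ln(Y_{s+1} + 1) - ln(Y_s + 1)) / (t_{s+1} - t_s)`` and the predictors
    are the arithmetic means of the two counts per taxon.
    """
    rows_x, rows_y, groups = [], [], []
    for subj in dataset.subjects:
        if subj.times.size < 2:
            raise ValueError(f"subject {subj.subject!r} needs >= 2 time points")
        y = subj.counts.astype(float)
        dt = np.diff(subj.times)[:, None]
        rows_y.append(np.diff(np.log1p(y), axis=0) / dt)
        rows_x.append(0.5 * (y[1:] + y[:-1]))
        groups.extend([subj.subject] * (subj.times.size - 1))
    return RegressionDesign(
        predictors=np.vstack(rows_x), responses=np.vstack(rows_y),
        groups=np.asarray(groups), taxa=list(dataset.taxa), tag="difference",
    )


def _make_estimator(method: str, lam: float):
    if lam == 0:
        return LinearRegression()
    if method == "ridge":
        return Ridge(alpha=lam)
    if method == "lasso":
        return Lasso(alpha=lam, max_iter=50_000)
    if method == "elastic_net":
        return ElasticNet(alpha=lam, l1_ratio=ELASTIC_NET_MIXING, max_iter=50_000)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def fit_regularized(
    design: RegressionDesign,
    method: str = "ridge",
    lambda_grid: Sequence[float] | None = None,
    cv_folds: int = 5,
) -> FitResult:
    """Estimate alpha and beta by penalized least squares per target taxon.

    The penalty strength is chosen per taxon by subject-grouped k-fold
    cross-validation minimizing mean squared error; the intercept (alpha) is
    unpenalized and predictors are standardized internally (coefficients are
    returned on the original abundance scale).  Constant predictor columns
    receive coefficient 0 with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    grid = np.asarray(
        DEFAULT_LAMBDA_GRIDS[method] if lambda_grid is None else lambda_grid,
        dtype=float,
    )
    X, Y = design.predictors, design.responses
    n_rows, p = X.shape

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    const = std == 0
    if const.any():
        bad = [design.taxa[k] for k in np.flatnonzero(const)]
        warnings.warn(f"constant predictor columns get coefficient 0: {bad}",
                      stacklevel=2)
        std = np.where(const, 1.0, std)
    Xs = (X - mean) / std

    groups = design.groups
    n_groups = len(np.unique(groups))
    k = min(cv_folds, n_groups)
    if k < cv_folds:
        warnings.warn(
            f"only {n_groups} subjects; reducing CV folds from {cv_folds} to {k}",
            stacklevel=2,
        )

    mask = design.response_mask
    splits = (
        list(GroupKFold(n_splits=k).split(Xs, groups=groups))
        if k >= 2 and len(grid) > 1
        else []
    )

    alpha_hat = np.zeros(p)
    beta_hat = np.zeros((p, p))
    lambdas = np.full(p, np.nan)
    for j in range(p):
        use = mask[:, j]
        if use.sum() <= 1:
            warnings.warn(
                f"taxon {design.taxa[j]!r} has no usable response rows; "
                "its parameters are set to 0",
                stacklevel=2,
            )
            continue
        yj = Y[:, j]
        if splits:
            sse = np.zeros(len(grid))
            counts = 0
            for a, lam in enumerate(grid):
                for train, test in splits:
                    tr, te = train[use[train]], test[use[test]]
                    if tr.size < 2 or te.size == 0:
                        continue
                    est = _make_estimator(method, lam)
                    est.fit(Xs[tr], yj[tr])
                    sse[a] += ((est.predict(Xs[te]) - yj[te]) ** 2).sum()
                    counts += te.size
            lambdas[j] = grid[int(np.argmin(sse))] if counts else grid[0]
        else:
            lambdas[j] = grid[0]
        est = _make_estimator(method, float(lambdas[j]))
        est.fit(Xs[use], yj[use])
        coef = np.where(const, 0.0, np.ravel(est.coef_)) / std
        beta_hat[j] = coef
        alpha_hat[j] = float(est.intercept_) - float(coef @ mean)

    model = CommunityModel(tuple(design.taxa), alpha_hat, beta_hat)
    return FitResult(
        model=model, lambdas=np.asarray(lambdas, dtype=float), method=method,
        design_tag=design.tag,
        settings={"cv_folds": k, "n_rows": int(n_rows),
                  "lambda_grid": grid.tolist()},
    )


def estimate_model(
    dataset: TimeSeriesDataset,
    design_type: str = "spline",
    method: str = "ridge",
    cv_folds: int = 5,
    basis_size: int | None = None,
    spline_lambda_grid: Sequence[float] | None = None,
    lambda_grid: Sequence[float] | None = None,
) -> FitResult:
    """End-to-end estimation: (smoothing ->) design -> penalized fit.

    ``design_type='spline'`` runs the NB smoothing-spline denoiser on every
    (subject, taxon) series and evaluates the regression on the observed
    grids; ``'difference'`` uses the raw-count difference baseline.  The
    whole path is deterministic for a fixed dataset and options.
    """
    if design_type == "spline":
        smoothed = smooth_dataset(
            dataset, basis_size=basis_size, lambda_grid=spline_lambda_grid
        )
        eval_times = {s.subject: s.times for s in dataset.subjects}
        design = build_spline_design(smoothed, eval_times, dataset.taxa)
    elif design_type == "difference":
        design = build_difference_design(dataset)
    else:
        raise ValueError(
            f"unknown design_type {design_type!r}; expected 'spline' or 'difference'"
        )
    result = fit_regularized(
        design, method=method, lambda_grid=lambda_grid, cv_folds=cv_folds
    )
    result.settings.update(
        {"design_type": design_type, "method": method,
         "basis_size": basis_size, "n_subjects": dataset.n, "p": dataset.p}
    )
    return result
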