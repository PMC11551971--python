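"""Abundance-table preparation and negative-binomial smoothing splines.

Two concerns live here:

1. **Table preparation** for real data: converting relative abundances to
   absolute values with per-sample biomass, a prevalence filter (keep taxa
   detected in strictly more than a given fraction of samples), and
   selection of the most abundant taxa.

2. **Denoising** of each (subject, taxon) count series with a penalized
   B-spline fit under a negative-binomial likelihood with log link
   (``Y_s ~ NB(mu_s, phi)``, ``mu_s = exp(eta(t_s))``, ``eta`` a cubic
   B-spline).  The penalty is a second-order difference penalty on the
   spline coefficients, with the smoothing parameter chosen per series by a
   deviance-based GCV criterion.  The fit yields a strictly positive
   abundance curve ``fhat(t) = exp(eta(t))`` and its analytic derivative
   ``fhat'(t) = fhat(t) * eta'(t)`` — exactly the two ingredients the
   gradient-matching regression consumes.

Dispersion handling: the observation model indexes dispersion by species, so
:func:`smooth_dataset` first estimates each species' ``phi_j`` from
trend-corrected pseudo-residuals pooled across subjects (fit-free and robust
to both overfitting and lack-of-fit), then fits every series at its
species' dispersion.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = [
    "AbundanceTable",
    "SmoothedTrajectory",
    "to_absolute",
    "filter_prevalence",
    "select_top_abundant",
    "fit_nb_spline",
    "smooth_dataset",
    "evaluate_curve",
    "evaluate_derivative",
    "smoothed_to_frame",
]

logger = logging.getLogger(__name__)

#: abundance floor used for degenerate (all-zero) series
ZERO_SERIES_FLOOR = 0.5
#: working dispersion for the first-pass fits (near-Poisson weights)
INIT_DISPERSION = 1e4
#: dispersion cap when residuals show no overdispersion
MAX_DISPERSION = 1e8
#: dispersion floor; below this the NB likelihood carries almost no
#: information and penalized fits become numerically unstable
MIN_DISPERSION = 0.01
DEFAULT_LAMBDA_GRID = np.logspace(-4, 8, 13)
#: GCV degrees-of-freedom inflation guarding against undersmoothing
GCV_GAMMA = 1.4
_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AbundanceTable:
    """Taxa x samples value matrix with per-sample (subject, time) metadata.

    ``values`` is a DataFrame indexed by taxon with one column per sample;
    ``meta`` is indexed by sample id with columns ``subject`` and ``time``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate taxon labels in abundance table")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample labels in abundance table")
        missing = [s for s in self.values.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")
        meta = self.meta.loc[self.values.columns, ["subject", "time"]].copy()
        meta.index.name = "sample_id"
        dup = meta.duplicated(subset=["subject", "time"])
        if dup.any():
            raise ValueError(
                f"duplicate (subject, time) pairs: {meta.index[dup].tolist()}"
            )
        self.meta = meta

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def to_absolute(
    relative: AbundanceTable, biomass: Mapping[str, float] | pd.Series
) -> AbundanceTable:
    """Scale each sample column of a relative table by its biomass."""
    biomass = pd.Series(biomass, dtype=float)
    missing = [s for s in relative.samples if s not in biomass.index]
    if missing:
        raise ValueError(f"biomass missing for samples: {missing}")
    colsum = relative.values.sum(axis=0)
    if (colsum > 1.0 + 1e-6).any():
        bad = colsum.index[colsum > 1.0 + 1e-6].tolist()
        raise ValueError(f"relative-abundance columns sum above 1: {bad}")
    scaled = relative.values * biomass[relative.samples]
    return AbundanceTable(values=scaled, meta=relative.meta)


def filter_prevalence(table: AbundanceTable, threshold: float = 0.8) -> AbundanceTable:
    """Keep taxa nonzero in strictly more than ``threshold`` of samples."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    prevalence = (table.values > 0).mean(axis=1)
    keep = prevalence > threshold
    if not keep.any():
        warnings.warn("prevalence filter removed every taxon", stacklevel=2)
    return AbundanceTable(values=table.values.loc[keep], meta=table.meta)


def select_top_abundant(table: AbundanceTable, k: int = 10) -> AbundanceTable:
    """Keep the ``k`` taxa with the largest total abundance across samples.

    Ties at the boundary are broken by taxon label (ascending), so selection
    is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(table.taxa):
        if k > len(table.taxa):
            warnings.warn(
                f"k={k} exceeds taxon count {len(table.taxa)}; keeping all",
                stacklevel=2,
            )
        return table
    totals = table.values.sum(axis=1)
    order = sorted(table.taxa, key=lambda t: (-totals[t], t))
    keep = sorted(order[:k], key=table.taxa.index)  # preserve original order
    return AbundanceTable(values=table.values.loc[keep], meta=table.meta)


# ---------------------------------------------------------------------------
# NB smoothing splines
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SmoothedTrajectory:
    """Fitted abundance curve of one (subject, taxon) series.

    The spline lives on the log-mean (link) scale: ``fhat(t) = exp(eta(t))``
    with ``eta`` the stored B-spline, hence the curve is positive on its
    whole domain and the derivative follows by the chain rule.
    """

    subject: str
    taxon: str
    spline: BSpline  # linear predictor eta(t)
    phi: float
    t_min: float
    t_max: float
    lambda_: float
    edf: float
    degenerate: bool = False  # all-zero series pinned at a small floor
    #: time span bracketed by positive observations; outside it the curve is
    #: extrapolating through zeros and its derivative is not data-supported
    support: tuple[float, float] | None = None

    def _check_domain(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        eps = 1e-9 * max(1.0, abs(self.t_max))
        if np.any(t < self.t_min - eps) or np.any(t > self.t_max + eps):
            raise ValueError(
                f"time outside fitted domain [{self.t_min}, {self.t_max}]"
            )
        return np.clip(t, self.t_min, self.t_max)

    def curve(self, t):
        """Fitted abundance ``fhat(t) = exp(eta(t))``; refuses extrapolation."""
        t = self._check_domain(t)
        return np.exp(np.clip(self.spline(t), -_ETA_CLIP, _ETA_CLIP))

    def derivative(self, t):
        """Fitted rate ``fhat'(t) = fhat(t) * eta'(t)`` (analytic)."""
        t = self._check_domain(t)
        if self.degenerate:
            return np.zeros_like(np.asarray(t, dtype=float))
        return self.curve(t) * self.spline.derivative()(t)


def evaluate_curve(traj: SmoothedTrajectory, t):
    """Evaluate the fitted abundance curve at time(s) ``t``."""
    return traj.curve(t)


def evaluate_derivative(traj: SmoothedTrajectory, t):
    """Evaluate the fitted abundance derivative at time(s) ``t``."""
    return traj.derivative(t)


def _bspline_basis(times: np.ndarray, n_basis: int) -> tuple[np.ndarray, np.ndarray, int]:
    """B-spline design matrix with knots at quantiles of the observed times."""
    degree = min(3, n_basis - 1)
    n_interior = n_basis - degree - 1
    lo, hi = times[0], times[-1]
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(times, probs)
        # keep interior knots strictly inside and distinct
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
    else:
        interior = np.empty(0)
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    design = BSpline.design_matrix(times, knots, degree, extrapolate=False).toarray()
    return design, knots, degree


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    term2 = (y + phi) * np.log((y + phi) / (mu + phi))
    return float(2.0 * np.sum(term - term2))


def _pirls(
    design: np.ndarray,
    y: np.ndarray,
    phi: float,
    lam: float,
    penalty: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, float]:
    """Penalized IRLS for the NB log-link spline; returns (coef, dev, edf)."""
    mu = np.maximum(y.astype(float), 0.5)
    eta = np.log(mu)
    dev = np.inf
    coef = np.zeros(design.shape[1])
    for _ in range(max_iter):
        w = mu / (1.0 + mu / phi)
        z = eta + (y - mu) / mu
        bw = design * w[:, None]
        lhs = bw.T @ design + lam * penalty
        rhs = bw.T @ z
        try:
            coef = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        eta = np.clip(design @ coef, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = _nb_deviance(y, mu, phi)
        if np.isfinite(dev) and abs(dev - dev_new) <= tol * (abs(dev) + 1e-10):
            dev = dev_new
            break
        dev = dev_new
    w = mu / (1.0 + mu / phi)
    bw = design * w[:, None]
    lhs = bw.T @ design + lam * penalty
    try:
        edf = float(np.trace(np.linalg.solve(lhs, bw.T @ design)))
    except np.linalg.LinAlgError:
        edf = float(design.shape[1])
    return coef, dev, edf


def _degenerate_trajectory(
    subject: str, taxon: str, times: np.ndarray, phi: float
) -> SmoothedTrajectory:
    degree = 1
    knots = np.array([times[0], times[0], times[-1], times[-1]], dtype=float)
    coef = np.full(2, np.log(ZERO_SERIES_FLOOR))
    return SmoothedTrajectory(
        subject=subject, taxon=taxon,
        spline=BSpline(knots, coef, degree),
        phi=phi, t_min=float(times[0]), t_max=float(times[-1]),
        lambda_=np.nan, edf=0.0, degenerate=True,
    )


def fit_nb_spline(
    times: Sequence[float],
    counts: Sequence[float],
    phi: float | None = None,
    basis_size: int | None = None,
    lambda_grid: Sequence[float] | None = None,
    penalty_order: int = 1,
    subject: str = "",
    taxon: str = "",
) -> SmoothedTrajectory:
    """Fit one subject-taxon count series with an NB penalized spline.

    Parameters
    ----------
    phi
        NB dispersion. If ``None``, the series is fit with a near-Poisson
        working dispersion and ``phi`` is then re-estimated from Pearson
        residuals of that fit, followed by one refit.
    basis_size
        Number of B-spline basis functions; default ``min(10, m - 1)``.
    lambda_grid
        Candidate smoothing parameters; the minimizer of the deviance-based
        GCV criterion ``m * dev / (m - gamma * edf)^2`` (``gamma = 1.4``
        guarding against undersmoothing) is selected.
    penalty_order
        Order of the coefficient difference penalty.  The default 1
        penalizes first differences, whose null space is the constant
        curve: with no temporal signal the fit collapses to the NB mean
        rather than to an arbitrary noise-fitted linear trend.

    An all-zero series cannot inform a positive curve; it is returned as a
    degenerate flat fit at a small floor with zero derivative and flagged
    via ``degenerate=True`` so downstream stages can exclude the taxon.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if times.ndim != 1 or y.shape != times.shape:
        raise ValueError("times and counts must be 1-d arrays of equal length")
    if times.size < 4:
        raise ValueError("need at least 4 observations to fit a spline")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("counts must be finite and nonnegative")

    if not np.any(y > 0):
        return _degenerate_trajectory(subject, taxon, times, phi or np.nan)

    m = times.size
    n_basis = basis_size if basis_size is not None else min(10, m - 1)
    n_basis = int(max(2, min(n_basis, m)))
    grid = np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float
    )

    design, knots, degree = _bspline_basis(times, n_basis)
    diff_order = min(penalty_order, n_basis - 1)
    d_mat = np.diff(np.eye(n_basis), diff_order, axis=0)
    penalty = d_mat.T @ d_mat

    def _fit_at(phi_work: float) -> tuple[np.ndarray, float, float]:
        best = None
        for lam in grid:
            coef, dev, edf = _pirls(design, y, phi_work, lam, penalty)
            denom = max(m - GCV_GAMMA * edf, 1e-3)
            gcv = m * max(dev, 0.0) / denom**2
            if not np.isfinite(gcv):
                continue
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef, edf)
        if best is None:  # every candidate failed numerically
            coef, _, edf = _pirls(design, y, phi_work, grid[-1], penalty)
            best = (np.inf, grid[-1], coef, edf)
        return best[2], best[1], best[3]

    phi_work = phi if phi is not None else INIT_DISPERSION
    coef, lam, edf = _fit_at(phi_work)
    if phi is None:
        mu = np.exp(np.clip(design @ coef, -_ETA_CLIP, _ETA_CLIP))
        phi_work = estimate_dispersion([(y, mu, edf)])
        coef, lam, edf = _fit_at(phi_work)

    positive = times[y > 0]
    return SmoothedTrajectory(
        subject=subject, taxon=taxon,
        spline=BSpline(knots, coef, degree),
        phi=float(phi_work), t_min=float(times[0]), t_max=float(times[-1]),
        lambda_=float(lam), edf=float(edf),
        support=(float(positive[0]), float(positive[-1])),
    )


def estimate_dispersion(fits: list[tuple[np.ndarray, np.ndarray, float]]) -> float:
    """Method-of-moments dispersion from pooled Pearson residuals.

    Solves ``sum (y - mu)^2 / (mu + mu^2/phi) = sum (m_i - edf_i)`` for
    ``phi`` over the pooled fits; capped at :data:`MAX_DISPERSION` when the
    residuals show no overdispersion relative to Poisson.
    """
    ys = np.concatenate([np.asarray(y, float) for y, _, _ in fits])
    mus = np.concatenate([np.asarray(mu, float) for _, mu, _ in fits])
    df = sum(len(y) - edf for y, _, edf in fits)
    keep = mus > 1e-8
    ys, mus = ys[keep], mus[keep]
    if ys.size == 0 or df <= 0:
        return MAX_DISPERSION
    resid2 = (ys - mus) ** 2

    def pearson_gap(inv_phi: float) -> float:
        return float(np.sum(resid2 / (mus * (1.0 + mus * inv_phi))) - df)

    if pearson_gap(1.0 / MAX_DISPERSION) <= 0:
        return MAX_DISPERSION  # at or below Poisson variability
    hi = 1.0 / MIN_DISPERSION
    if pearson_gap(hi) > 0:
        return MIN_DISPERSION
    inv_phi = brentq(pearson_gap, 1.0 / MAX_DISPERSION, hi, xtol=1e-12, rtol=1e-10)
    return float(1.0 / inv_phi)


def smooth_dataset(
    dataset,
    basis_size: int | None = None,
    lambda_grid: Sequence[float] | None = None,
    phi: float | Mapping[str, float] | None = None,
    refine_dispersion: bool = True,
) -> dict[tuple[str, str], SmoothedTrajectory]:
    """Fit NB smoothing splines for every (subject, taxon) series.

    Each series is fit independently.  Unless ``phi`` is given, species-level
    dispersions are first estimated from adjacent-observation pairs pooled
    across subjects (see :func:`estimate_dataset_dispersions`), and every
    series is then fit at its species' dispersion.

    Returns a dict keyed by ``(subject_id, taxon)``.
    """
    def fit_all(phi_map: Mapping[str, float]):
        out = {}
        for subj in dataset.subjects:
            for j, taxon in enumerate(dataset.taxa):
                out[(subj.subject, taxon)] = fit_nb_spline(
                    subj.times, subj.counts[:, j], phi=phi_map[taxon],
                    basis_size=basis_size, lambda_grid=lambda_grid,
                    subject=subj.subject, taxon=taxon,
                )
        return out

    if phi is not None:
        if isinstance(phi, Mapping):
            return fit_all(dict(phi))
        return fit_all({t: float(phi) for t in dataset.taxa})

    if not refine_dispersion:
        return fit_all({t: INIT_DISPERSION for t in dataset.taxa})
    phi_map = estimate_dataset_dispersions(dataset)
    logger.info("pooled species dispersions: %s",
                {k: round(v, 3) for k, v in phi_map.items()})
    return fit_all(phi_map)


#: median of the chi-squared distribution with one degree of freedom
_CHI2_1_MEDIAN = 0.4549364231195728


def estimate_dataset_dispersions(dataset) -> dict[str, float]:
    """Species-level NB dispersions from trend-corrected pseudo-residuals.

    At each interior time point the count is compared with the linear
    interpolation of its two neighbours — a pseudo-residual that
    annihilates any locally linear trend, leaving (a known multiple of)
    pure observation noise.  Under the NB model the standardized squared
    pseudo-residual ``r^2 / (c (mu + mu^2/phi))`` is approximately
    chi-squared(1), so ``phi_j`` is solved by matching the *median* of the
    statistic over all of species ``j``'s interior points (pooled across
    subjects) to the chi-squared(1) median.  The median makes the estimate
    robust to the minority of points straddling genuinely fast dynamics,
    and being fit-free the estimate can be neither deflated by an overfit
    smooth nor inflated by smoother lack-of-fit.
    """
    phi_map: dict[str, float] = {}
    for j, taxon in enumerate(dataset.taxa):
        resid, scale, mean = [], [], []
        for subj in dataset.subjects:
            y = subj.counts[:, j].astype(float)
            t = subj.times
            for k in range(1, y.size - 1):
                w = (t[k] - t[k - 1]) / (t[k + 1] - t[k - 1])
                mbar = (y[k - 1] + y[k] + y[k + 1]) / 3.0
                if mbar <= 0:
                    continue
                resid.append(y[k] - ((1 - w) * y[k - 1] + w * y[k + 1]))
                scale.append(1.0 + (1 - w) ** 2 + w**2)
                mean.append(mbar)
        r = np.asarray(resid)
        c = np.asarray(scale)
        mbar = np.asarray(mean)
        if r.size < 5:
            phi_map[taxon] = MAX_DISPERSION
            continue

        def gap(log_phi: float) -> float:
            phi_c = 10.0**log_phi
            stat = r**2 / (c * (mbar + mbar**2 / phi_c))
            return float(np.median(stat) - _CHI2_1_MEDIAN)

        lo, hi = np.log10(MIN_DISPERSION), np.log10(MAX_DISPERSION)
        if gap(hi) < 0:
            phi_map[taxon] = MAX_DISPERSION  # Poisson variability suffices
        elif gap(lo) > 0:
            phi_map[taxon] = MIN_DISPERSION
        else:
            phi_map[taxon] = float(10.0 ** brentq(gap, lo, hi, xtol=1e-8))
    return phi_map


def smoothed_to_frame(
    smoothed: Mapping[tuple[str, str], SmoothedTrajectory],
    eval_times: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Long-format table (subject, taxon, time, fhat, fhat_prime)."""
    rows = []
    for (subject, taxon), traj in smoothed.items():
        for t in np.asarray(eval_times[subject], dtype=float):
            rows.append(
                {"subject": subject, "taxon": taxon, "time": t,
                 "fhat": float(traj.curve(t)), "fhat_prime": float(traj.derivative(t))}
            )
    return pd.DataFrame(rows, columns=["subject", "taxon", "time", "fhat", "fhat_prime"])
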