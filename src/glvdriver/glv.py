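"""Generalized Lotka-Volterra (gLV) community dynamics.

The gLV model describes the joint dynamics of ``p`` interacting taxa through
coupled ordinary differential equations

.. math::

    f_j'(t) = \\alpha_j f_j(t) + \\sum_{k=1}^{p} \\beta_{jk} f_j(t) f_k(t),

where ``alpha[j]`` is the intrinsic per-capita growth rate of taxon ``j``
(units 1/time) and ``beta[j, k]`` the interaction intensity exerted by taxon
``k`` on taxon ``j`` (units 1/(abundance*time)).  A community with an
invertible interaction matrix has the algebraic steady state
``f* = -beta^{-1} alpha``, the quantity that downstream driver scoring
perturbs and compares.

This module provides the :class:`CommunityModel` container, the right-hand
side of the ODE system, trajectory simulation with a stiff-capable adaptive
solver, and steady-state computation with explicit singularity and
feasibility flags.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CommunityModel",
    "SteadyState",
    "IntegrationFailure",
    "glv_rhs",
    "simulate_trajectory",
    "steady_state",
    "CONDITION_NUMBER_LIMIT",
]

#: condition number above which the interaction matrix is treated as singular
CONDITION_NUMBER_LIMIT = 1e12


class IntegrationFailure(RuntimeError):
    """Raised when the ODE solver diverges or produces non-finite state."""


@dataclasses.dataclass(frozen=True)
class CommunityModel:
    """Growth rates and interaction matrix of a ``p``-taxon community.

    Parameters
    ----------
    taxa
        Ordered taxon identifiers; defines the meaning of vector/matrix axes.
    alpha
        Length-``p`` vector of intrinsic growth rates (1/time).
    beta
        ``p x p`` interaction matrix; ``beta[j, k]`` is the effect of taxon
        ``k`` on taxon ``j`` (1/(abundance*time)).
    """

    taxa: tuple[str, ...]
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxa)
        alpha = np.asarray(self.alpha, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        p = len(taxa)
        if len(set(taxa)) != p:
            raise ValueError("duplicate taxon labels")
        if alpha.shape != (p,):
            raise ValueError(f"alpha has shape {alpha.shape}, expected ({p},)")
        if beta.shape != (p, p):
            raise ValueError(f"beta has shape {beta.shape}, expected ({p}, {p})")
        if not np.all(np.isfinite(alpha)) or not np.all(np.isfinite(beta)):
            raise ValueError("alpha and beta must be finite")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)

    @property
    def p(self) -> int:
        """Number of taxa."""
        return len(self.taxa)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        return cls(tuple(d["taxa"]), np.asarray(d["alpha"]), np.asarray(d["beta"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_tsvs(self, alpha_path: str | Path, beta_path: str | Path) -> None:
        """Write the growth-rate vector and interaction matrix as TSVs."""
        import pandas as pd

        pd.Series(self.alpha, index=list(self.taxa), name="alpha").to_csv(
            alpha_path, sep="\t"
        )
        pd.DataFrame(self.beta, index=list(self.taxa), columns=list(self.taxa)).to_csv(
            beta_path, sep="\t"
        )


@dataclasses.dataclass(frozen=True)
class SteadyState:
    """Algebraic steady state ``f* = -beta^{-1} alpha`` of a community.

    ``feasible`` is true iff all components are strictly positive; ``singular``
    is true iff the interaction matrix was numerically non-invertible, in
    which case ``abundance`` is all-NaN.
    """

    abundance: np.ndarray
    feasible: bool
    singular: bool


def _check_state(model: CommunityModel, f: Sequence[float]) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (model.p,):
        raise ValueError(f"state has shape {f.shape}, expected ({model.p},)")
    if not np.all(np.isfinite(f)):
        raise ValueError("state vector must be finite")
    return f


def glv_rhs(model: CommunityModel, f: Sequence[float]) -> np.ndarray:
    """Instantaneous rate of change ``f'`` at abundance state ``f``.

    Component ``j`` equals ``alpha_j f_j + sum_k beta_jk f_j f_k``.
    """
    f = _check_state(model, f)
    return f * (model.alpha + model.beta @ f)


def simulate_trajectory(
    model: CommunityModel,
    f0: Sequence[float],
    times: Sequence[float],
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> np.ndarray:
    """Integrate the gLV system and return abundances at ``times``.

    Parameters
    ----------
    f0
        Strictly positive initial abundances at ``times[0]``.
    times
        Strictly increasing evaluation times; the first row of the returned
        ``len(times) x p`` matrix equals ``f0``.

    Small negative solver excursions are clipped to zero on output, since
    abundances are non-negative quantities.

    Raises
    ------
    IntegrationFailure
        If the solver fails or any state component becomes non-finite
        (typical for parameter draws with finite-time blow-up).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a strictly increasing 1-d array")
    f0 = _check_state(model, f0)
    if np.any(f0 <= 0):
        raise ValueError("initial abundances must be strictly positive")
    if times.size == 1:
        return f0[None, :].copy()

    def rhs(_t: float, f: np.ndarray) -> np.ndarray:
        # overflow during a diverging trajectory is detected afterwards
        with np.errstate(over="ignore", invalid="ignore"):
            return f * (model.alpha + model.beta @ f)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        f0,
        t_eval=times,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    y = sol.y.T
    if sol.status != 0 or y.shape[0] != times.size or not np.all(np.isfinite(y)):
        t_reached = sol.t[-1] if sol.t.size else times[0]
        if y.size and not np.all(np.isfinite(y)):
            bad = int(np.argmax(~np.isfinite(y).all(axis=0)))
        else:
            # blame the fastest-growing taxon at the last successful state
            last = y[-1] if y.size else f0
            bad = int(np.argmax(np.abs(last * (model.alpha + model.beta @ last))))
        raise IntegrationFailure(
            f"gLV integration failed near t={t_reached:.4g} "
            f"(taxon {model.taxa[bad]!r}): solver status {sol.status}"
        )
    y = np.clip(y, 0.0, None)
    y[0] = f0  # the solver's interpolant can perturb the t0 row by ~1e-13
    return y


def steady_state(
    model: CommunityModel, cond_limit: float = CONDITION_NUMBER_LIMIT
) -> SteadyState:
    """Solve ``beta f = -alpha`` and flag singularity and feasibility.

    A non-invertible (condition number above ``cond_limit``) interaction
    matrix yields a NaN-marked, ``singular`` result rather than an exception,
    so that driver scoring can skip and report the affected perturbation.
    """
    cond = np.linalg.cond(model.beta)
    if not np.isfinite(cond) or cond > cond_limit:
        return SteadyState(
            abundance=np.full(model.p, np.nan), feasible=False, singular=True
        )
    f = np.linalg.solve(model.beta, -model.alpha)
    return SteadyState(abundance=f, feasible=bool(np.all(f > 0)), singular=False)
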