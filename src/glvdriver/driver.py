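"""Driver scores from steady-state perturbations of the interaction matrix.

A driver taxon is one whose presence shapes the community's steady state.
Each taxon ``j`` is scored by manipulating the causal graph implied by the
gLV interaction matrix and measuring how far the steady state moves:

* **D1 (removal)** — zero the off-diagonal entries of row *and* column
  ``j``: taxon ``j`` neither affects nor is affected by the others.
* **D2 (do-operator)** — zero the off-diagonal entries of row ``j``: taxon
  ``j`` still affects the others but is no longer influenced by them.
* **D3 (anti-do operator)** — zero the off-diagonal entries of column
  ``j``: taxon ``j`` no longer affects the others but is still influenced.

Growth rates and the self-interaction ``beta_jj`` are preserved under every
manipulation (zeroing the diagonal too would make the perturbed matrix
exactly singular, leaving the perturbed steady state undefined).  The score
is the squared Euclidean distance ``D = ||f2* - f1*||_2^2`` between the
perturbed and baseline steady states.  D3 — a taxon's total outgoing
influence — is the recommended driver index: a taxon with no outgoing
interactions scores exactly zero under D3 no matter how strongly it is
itself regulated.
"""

from __future__ import annotations

import enum
import math

import numpy as np
import pandas as pd

from .glv import CommunityModel, SteadyState, steady_state

__all__ = ["PerturbationMode", "perturb_model", "driver_score", "rank_drivers"]


class PerturbationMode(enum.Enum):
    """The three interaction-matrix manipulations."""

    REMOVE = "D1"
    DO = "D2"
    ANTI_DO = "D3"

    @classmethod
    def from_label(cls, label: str) -> "PerturbationMode":
        for mode in cls:
            if label.upper() in (mode.value, mode.name):
                return mode
        raise ValueError(f"unknown perturbation mode {label!r}")


def perturb_model(
    model: CommunityModel, j: int, mode: PerturbationMode
) -> CommunityModel:
    """Return a copy of ``model`` with taxon ``j``'s interactions manipulated.

    Off-diagonal entries of row ``j`` (DO), column ``j`` (ANTI_DO), or both
    (REMOVE) are set to zero; ``alpha`` and the diagonal are untouched.
    """
    if not 0 <= j < model.p:
        raise IndexError(f"taxon index {j} out of range for p={model.p}")
    beta = model.beta.copy()
    diag = beta[j, j]
    if mode in (PerturbationMode.REMOVE, PerturbationMode.DO):
        beta[j, :] = 0.0
    if mode in (PerturbationMode.REMOVE, PerturbationMode.ANTI_DO):
        beta[:, j] = 0.0
    beta[j, j] = diag
    return CommunityModel(model.taxa, model.alpha.copy(), beta)


def _perturbed_state(
    model: CommunityModel, j: int, mode: PerturbationMode, removed_as_zero: bool
) -> SteadyState:
    if mode is PerturbationMode.REMOVE and removed_as_zero:
        # remove taxon j outright: component j is 0, the rest solve the
        # (p-1)-dimensional subsystem
        keep = np.arange(model.p) != j
        sub_beta = model.beta[np.ix_(keep, keep)]
        cond = np.linalg.cond(sub_beta)
        if not np.isfinite(cond) or cond > 1e12:
            return SteadyState(np.full(model.p, np.nan), False, True)
        f_sub = np.linalg.solve(sub_beta, -model.alpha[keep])
        f = np.zeros(model.p)
        f[keep] = f_sub
        return SteadyState(f, bool(np.all(f_sub > 0)), False)
    return steady_state(perturb_model(model, j, mode))


def driver_score(
    model: CommunityModel,
    j: int,
    mode: PerturbationMode,
    baseline: SteadyState | None = None,
    removed_as_zero: bool = False,
) -> float:
    """Squared steady-state displacement caused by perturbing taxon ``j``.

    Returns NaN (flagged missing) when the perturbed system is singular.

    Parameters
    ----------
    baseline
        Precomputed baseline steady state; computed from ``model`` if absent.
    removed_as_zero
        Under REMOVE, set component ``j`` of the perturbed state to 0 and
        solve the remaining ``(p-1)``-taxon subsystem, instead of letting the
        removed taxon equilibrate at its isolated abundance ``-alpha_j /
        beta_jj`` (the default, which follows from applying the steady-state
        formula to the manipulated full matrix).
    """
    base = baseline if baseline is not None else steady_state(model)
    if base.singular:
        raise ValueError("baseline steady state is singular; no scores computable")
    pert = _perturbed_state(model, j, mode, removed_as_zero)
    if pert.singular:
        return math.nan
    return float(np.sum((pert.abundance - base.abundance) ** 2))


def rank_drivers(
    model: CommunityModel,
    mode: PerturbationMode | str = PerturbationMode.ANTI_DO,
    top_fraction: float = 0.5,
    removed_as_zero: bool = False,
) -> pd.DataFrame:
    """Score every taxon under D1/D2/D3 and rank them.

    Returns a DataFrame indexed like ``model.taxa`` with columns ``D1, D2,
    D3``, per-index ranks (1 = largest; ties broken by taxon label; singular
    perturbations carry NaN score and no rank), per-index feasibility flags
    of the perturbed steady states, and a ``candidate`` flag marking the
    ``ceil(top_fraction * p)`` top-ranked taxa under ``mode``.
    """
    if isinstance(mode, str):
        mode = PerturbationMode.from_label(mode)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    base = steady_state(model)
    if base.singular:
        raise ValueError("baseline steady state is singular; no scores computable")

    table = pd.DataFrame(index=pd.Index(model.taxa, name="taxon"))
    table["baseline_feasible"] = base.feasible
    for m in PerturbationMode:
        scores, feas = [], []
        for j in range(model.p):
            pert = _perturbed_state(model, j, m, removed_as_zero)
            scores.append(
                math.nan if pert.singular
                else float(np.sum((pert.abundance - base.abundance) ** 2))
            )
            feas.append(bool(pert.feasible))
        table[m.value] = scores
        table[f"feasible_{m.value}"] = feas

    for m in PerturbationMode:
        col = m.value
        order = sorted(
            (t for t in model.taxa if not math.isnan(table.at[t, col])),
            key=lambda t: (-table.at[t, col], t),
        )
        ranks = pd.Series(np.nan, index=table.index)
        ranks[order] = np.arange(1, len(order) + 1)
        table[f"rank_{col}"] = ranks

    n_top = math.ceil(top_fraction * model.p)
    table["candidate"] = table[f"rank_{mode.value}"] <= n_top
    return table
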