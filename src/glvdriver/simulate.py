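"""Synthetic time-series microbiome count data from the gLV + NB model.

Datasets are generated in two stages: latent per-subject abundance
trajectories are integrated from a randomly drawn gLV community (one shared
truth per dataset, reflecting the assumption that growth and interaction
parameters are common across subjects of a population), then observation
noise is added by sampling each count from a negative binomial distribution
with mean equal to the latent abundance and dispersion ``phi``
(variance ``mu + mu^2/phi``; larger ``phi`` means less noise).

Default parameter distributions:

* growth rates ``alpha_j ~ U(0, 0.2)``;
* off-diagonal interactions ``beta_jk`` nonzero with probability ``pi``,
  drawn from ``U(-0.0005, 0.0005)``; diagonal self-limitation fixed at
  ``beta_jj = -0.001``;
* initial abundances per subject ``~ U(100, 10000)``;
* irregular integer sampling gaps ``~ U{1..5}``, grids starting at 0.

Ground truth (model and latent trajectories) is retained on the dataset for
parameter-recovery benchmarking.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .glv import CommunityModel, IntegrationFailure, simulate_trajectory

__all__ = [
    "SimulationConfig",
    "SubjectSeries",
    "TimeSeriesDataset",
    "draw_model",
    "draw_sampling_design",
    "add_nb_noise",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

GROWTH_RANGE = (0.0, 0.2)
INTERACTION_RANGE = (-0.0005, 0.0005)
SELF_INTERACTION = -0.001
INITIAL_RANGE = (100.0, 10_000.0)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic dataset.

    ``m`` may be a single int (same number of time points for every subject)
    or a length-``n`` sequence of per-subject counts.
    """

    n: int = 10
    p: int = 10
    m: int | tuple[int, ...] = 8
    pi: float = 0.8
    phi: float = 1.0
    interval_range: tuple[int, int] = (1, 5)
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be >= 1")
        m = self.m
        if not isinstance(m, int):
            m = tuple(int(v) for v in m)
            if len(m) != self.n:
                raise ValueError("per-subject m list must have length n")
            object.__setattr__(self, "m", m)
        ms = (m,) if isinstance(m, int) else m
        if any(v < 1 for v in ms):
            raise ValueError("m must be >= 1")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        lo, hi = self.interval_range
        if not (1 <= lo <= hi):
            raise ValueError("interval_range must satisfy 1 <= low <= high")

    @property
    def m_per_subject(self) -> tuple[int, ...]:
        return (self.m,) * self.n if isinstance(self.m, int) else tuple(self.m)


@dataclasses.dataclass
class SubjectSeries:
    """Observed (and, for synthetic data, latent) series of one subject."""

    subject: str
    times: np.ndarray  # strictly increasing, length m_i
    counts: np.ndarray  # m_i x p nonnegative integers
    latent: np.ndarray | None = None  # m_i x p latent abundances


@dataclasses.dataclass
class TimeSeriesDataset:
    """Per-subject irregular time grids with counts and optional ground truth."""

    taxa: list[str]
    subjects: list[SubjectSeries]
    truth: CommunityModel | None = None

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return len(self.taxa)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_taxa(p: int) -> list[str]:
    width = max(2, len(str(p)))
    return [f"sp{j + 1:0{width}d}" for j in range(p)]


def draw_model(p: int, pi: float, seed) -> CommunityModel:
    """Draw a random community from the simulation parameter distributions.

    ``alpha_j ~ U(0, 0.2)``; off-diagonal ``beta_jk`` is, independently with
    probability ``pi``, a ``U(-0.0005, 0.0005)`` draw and otherwise exactly 0;
    every diagonal entry is ``-0.001``.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    rng = _as_rng(seed)
    alpha = rng.uniform(*GROWTH_RANGE, size=p)
    values = rng.uniform(*INTERACTION_RANGE, size=(p, p))
    active = rng.random(size=(p, p)) < pi
    beta = np.where(active, values, 0.0)
    np.fill_diagonal(beta, SELF_INTERACTION)
    return CommunityModel(tuple(default_taxa(p)), alpha, beta)


def draw_sampling_design(
    n: int,
    m: int | Sequence[int],
    interval_range: tuple[int, int],
    seed,
) -> list[np.ndarray]:
    """Draw ``n`` per-subject time grids with random integer gaps.

    Each grid starts at 0 and accumulates ``m - 1`` gaps drawn uniformly from
    the inclusive integer range ``interval_range``; grids are drawn
    independently per subject.
    """
    ms = [int(m)] * n if isinstance(m, (int, np.integer)) else [int(v) for v in m]
    if any(v < 2 for v in ms):
        raise ValueError("each subject needs m >= 2 time points")
    lo, hi = interval_range
    rng = _as_rng(seed)
    grids = []
    for m_i in ms:
        gaps = rng.integers(lo, hi + 1, size=m_i - 1)
        grids.append(np.concatenate([[0.0], np.cumsum(gaps)]).astype(float))
    return grids


def add_nb_noise(latent: np.ndarray, phi: float, seed) -> np.ndarray:
    """Sample NB counts with mean ``latent`` and dispersion ``phi``.

    Uses the NB2 parameterization ``Var = mu + mu^2 / phi``; a zero mean
    yields a zero count deterministically.
    """
    latent = np.asarray(latent, dtype=float)
    if np.any(latent < 0) or not np.all(np.isfinite(latent)):
        raise ValueError("latent means must be finite and nonnegative")
    if phi <= 0:
        raise ValueError("phi must be positive")
    rng = _as_rng(seed)
    prob = phi / (phi + latent)
    draws = rng.negative_binomial(phi, prob)
    return np.where(latent > 0, draws, 0).astype(np.int64)


def generate_dataset(config: SimulationConfig) -> TimeSeriesDataset:
    """Generate a complete synthetic dataset per the simulation protocol.

    One shared truth model is drawn, each subject gets an independent time
    grid and initial state, latent trajectories are integrated, and NB noise
    is applied.  If integration blows up for a subject, its initial
    abundances are redrawn up to ``config.max_retries`` times (logged);
    ground truth and latents are retained on the returned dataset.
    Bit-reproducible for a fixed config.
    """
    ss = np.random.SeedSequence(config.seed)
    s_model, s_design, s_init, s_noise = ss.spawn(4)
    model = draw_model(config.p, config.pi, np.random.default_rng(s_model))
    grids = draw_sampling_design(
        config.n, config.m_per_subject, config.interval_range,
        np.random.default_rng(s_design),
    )
    rng_init = np.random.default_rng(s_init)
    rng_noise = np.random.default_rng(s_noise)

    subjects: list[SubjectSeries] = []
    for i, times in enumerate(grids):
        latent = None
        for attempt in range(config.max_retries + 1):
            f0 = rng_init.uniform(*INITIAL_RANGE, size=config.p)
            try:
                latent = simulate_trajectory(model, f0, times)
                break
            except IntegrationFailure as exc:
                logger.warning(
                    "subject %d attempt %d: %s; redrawing initial abundances",
                    i + 1, attempt + 1, exc,
                )
        if latent is None:
            raise IntegrationFailure(
                f"subject {i + 1}: integration failed after "
                f"{config.max_retries} initial-abundance redraws"
            )
        counts = add_nb_noise(latent, config.phi, rng_noise)
        subjects.append(
            SubjectSeries(subject=f"S{i + 1}", times=times, counts=counts,
                          latent=latent)
        )
    return TimeSeriesDataset(taxa=list(model.taxa), subjects=subjects, truth=model)
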