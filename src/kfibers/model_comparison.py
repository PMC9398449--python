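"""Bayesian comparison of KMT recruitment models against speed data.

Hybrid recruitment models mix nucleate-at-kinetochore and
capture-from-spindle recruitment with a capture fraction f ∈ [0, 1]
(f = 0: all KMTs nucleate at the kinetochore; f = 1: all are captured
non-KMTs).  For each f the flux-balance machinery predicts a tubulin
speed-vs-position curve; the posterior over f given the binned measured
line speeds uses an independent-Gaussian likelihood per position bin
(the bin standard errors, optionally inflated by Monte-Carlo prediction
noise) under a uniform prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from kfibers import flux_balance


@dataclass(frozen=True)
class SpeedDataset:
    """Binned line speeds vs initial line position (1 µm bins from pole)."""

    position_um: np.ndarray
    speed_um_per_min: np.ndarray
    sem: np.ndarray
    n_cells: Optional[np.ndarray] = None

    def __post_init__(self):
        p = np.asarray(self.position_um, dtype=float)
        v = np.asarray(self.speed_um_per_min, dtype=float)
        e = np.asarray(self.sem, dtype=float)
        if not (p.shape == v.shape == e.shape):
            raise ValueError("position, speed, sem must have equal shapes")
        if np.any(e <= 0):
            raise ValueError("SEM must be > 0 in every bin")
        if np.any(np.diff(p) <= 0):
            raise ValueError("position bins must be strictly increasing")
        object.__setattr__(self, "position_um", p)
        object.__setattr__(self, "speed_um_per_min", v)
        object.__setattr__(self, "sem", e)


@dataclass(frozen=True)
class ModelPosterior:
    """Posterior over the capture fraction f on a regular grid."""

    f_grid: np.ndarray
    probability: np.ndarray  # normalized to sum to 1
    log_likelihood: np.ndarray

    @property
    def mode(self) -> float:
        return float(self.f_grid[int(np.argmax(self.probability))])

    def mass_below(self, f_threshold: float) -> float:
        return float(np.sum(self.probability[self.f_grid <= f_threshold]))


def hybrid_speed_stack(
    profile: flux_balance.MinusEndProfile | Callable[[np.ndarray], np.ndarray],
    capture_j: flux_balance.RecruitmentModel,
    r: float = flux_balance.DETACHMENT_RATE_PER_MIN,
    s_p: float = flux_balance.POLE_REGION_UM,
    s_max: Optional[float] = None,
) -> Callable[[float], flux_balance.SpeedProfile]:
    """Factory returning f ↦ tubulin speed profile for hybrid models.

    Sharing one minus-end profile and one capture-recruitment shape, the
    returned callable solves the flux balance with capture fraction f
    and attaches the pole-region treadmilling channel.
    """

    def solve(f: float) -> flux_balance.SpeedProfile:
        if not 0.0 <= f <= 1.0:
            raise ValueError("capture fraction must lie in [0, 1]")
        if f == 0.0:
            model = flux_balance.nucleate_model()
        else:
            kind = "capture" if f >= 1.0 else "hybrid"
            model = flux_balance.RecruitmentModel(
                kind=kind, capture_fraction=f, j=capture_j.j
            )
        v = flux_balance.solve_speed(profile, model, r=r, s_max=s_max)
        return flux_balance.treadmill_profile(v, s_p=s_p)

    return solve


def hybrid_prediction(
    f: float,
    speed_stack: Callable[[float], flux_balance.SpeedProfile],
    positions_um: np.ndarray,
    simulate: Optional[Callable[[flux_balance.SpeedProfile, np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Predicted line speeds at the dataset's positions for capture fraction f.

    By default the prediction is the tubulin speed v_tub of the hybrid
    flux-balance solution evaluated at each position (what an ideal line
    tracker measures); passing ``simulate`` replaces this with a full
    photoconversion simulation + analysis round trip, e.g.
    ``simulate(speed_profile, positions) -> measured speeds``.
    """
    prof = speed_stack(f)
    positions = np.asarray(positions_um, dtype=float)
    if simulate is not None:
        return np.asarray(simulate(prof, positions), dtype=float)
    return prof.v_tub_at(positions)


def posterior(
    data: SpeedDataset,
    predictions: np.ndarray,
    f_grid: np.ndarray,
    mc_noise_sd: float | np.ndarray = 0.0,
) -> ModelPosterior:
    """Posterior over f from per-bin Gaussian likelihoods, uniform prior.

    ``predictions`` has shape (len(f_grid), len(data.position_um)).
    ``mc_noise_sd`` (scalar or per-bin) is folded into the likelihood
    variance to account for Monte-Carlo noise in the predictions.
    Likelihoods are normalized by their maximum before exponentiation,
    so the posterior is invariant to rescaling all likelihoods.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    preds = np.asarray(predictions, dtype=float)
    if preds.shape != (len(f_grid), len(data.position_um)):
        raise ValueError(
            f"predictions must be (n_f={len(f_grid)}, n_bins={len(data.position_um)}), "
            f"got {preds.shape}"
        )
    var = data.sem**2 + np.asarray(mc_noise_sd, dtype=float) ** 2
    resid = preds - data.speed_um_per_min[None, :]
    logL = -0.5 * np.sum(resid**2 / var[None, :], axis=1)
    logL = logL - logL.max()
    p = np.exp(logL)
    p = p / p.sum()
    return ModelPosterior(f_grid=f_grid, probability=p, log_likelihood=logL)


def compare_recruitment_models(
    data: SpeedDataset,
    speed_stack: Callable[[float], flux_balance.SpeedProfile],
    f_grid: Optional[np.ndarray] = None,
    mc_noise_sd: float = 0.0,
    simulate: Optional[Callable] = None,
) -> ModelPosterior:
    """End-to-end posterior over the capture fraction (default grid 0:0.05:1)."""
    if f_grid is None:
        f_grid = np.arange(0.0, 1.0 + 1e-9, 0.05)
    preds = np.stack(
        [hybrid_prediction(f, speed_stack, data.position_um, simulate=simulate) for f in f_grid]
    )
    return posterior(data, preds, f_grid, mc_noise_sd=mc_noise_sd)
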