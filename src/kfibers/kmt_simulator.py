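"""Discrete stochastic simulation of the KMT lifecycle.

Each kinetochore anchors one streamline at arc-length coordinate
s_kin.  New KMTs appear at the kinetochore with Poisson statistics; in
the nucleate-at-kinetochore model they start with zero length (minus
end at s_kin), in the capture model the initial minus-end position is
drawn from the recruitment distribution j(s) truncated to [0, s_kin].
Minus ends advect poleward, ds/dt = −v(s), by explicit Euler (v is
smooth and slow, so a dt well under 1/max|dv/ds| suffices); ends
reaching the pole are pinned at the defect edge while tubulin continues
to treadmill through them ("chipper-feeder" minus-end depolymerization).
Each KMT detaches after an exponential lifetime with rate r and is
removed.  KMTs never switch streamlines.

State snapshots record, per live KMT, the anchor (streamline index,
s_kin), the current minus-end coordinate and the birth time; pooled
steady-state snapshots feed the length and projected-orientation
distributions and the photoconversion renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from kfibers.flux_balance import DETACHMENT_RATE_PER_MIN, POLE_REGION_UM, SpeedProfile
from kfibers.nematic_field import Streamline


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the KMT lifecycle simulation.

    ``dt`` minutes per step (must be ≪ 1/r); ``r`` detachment rate
    (min⁻¹); ``nucleation_rate`` expected births per kinetochore per
    minute; ``s_p`` pole-region boundary (µm); ``burn_in`` minutes
    discarded before measurement (≥ 3/r); ``duration`` measured minutes
    after burn-in; snapshots every ``snapshot_interval`` minutes.
    """

    dt: float = 0.01
    r: float = DETACHMENT_RATE_PER_MIN
    nucleation_rate: float = 2.0
    s_p: float = POLE_REGION_UM
    burn_in: float = 10.0
    duration: float = 10.0
    snapshot_interval: float = 0.5
    seed: int = 0
    capture_fraction: float = 0.0

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.5 / self.r:
            raise ValueError(f"dt={self.dt} must satisfy 0 < dt << 1/r={1 / self.r:.2f}")
        if self.burn_in < 3.0 / self.r:
            raise ValueError(f"burn_in must be >= 3/r = {3 / self.r:.1f} min")
        if not 0.0 <= self.capture_fraction <= 1.0:
            raise ValueError("capture_fraction in [0, 1]")


@dataclass
class Snapshot:
    """Per-KMT state at one instant."""

    time: float
    streamline_idx: np.ndarray  # anchor streamline per KMT
    s_kin: np.ndarray  # kinetochore coordinate per KMT
    s_minus: np.ndarray  # current minus-end coordinate per KMT
    birth_time: np.ndarray

    @property
    def n_kmts(self) -> int:
        return len(self.s_minus)

    def lengths(self) -> np.ndarray:
        """Arc length from minus end to kinetochore along the streamline."""
        return self.s_kin - self.s_minus


@dataclass
class SimulatedKMTPopulation:
    """Snapshot time series plus the event log of completed lifetimes.

    ``lifetime_births`` holds the birth time of each completed lifetime;
    restricting to births well before the end of the run gives an
    uncensored sample of the detachment-time distribution.
    """

    snapshots: list[Snapshot]
    lifetimes: np.ndarray
    lifetime_births: np.ndarray
    streamlines: Sequence[Streamline]
    config: SimulationConfig

    def uncensored_lifetimes(self, margin: float | None = None) -> np.ndarray:
        """Lifetimes of KMTs born at least ``margin`` (default 10/r)
        before the end of the run."""
        if margin is None:
            margin = 10.0 / self.config.r
        t_end = self.config.duration
        return self.lifetimes[self.lifetime_births <= t_end - margin]

    def pooled(self, after: float = 0.0) -> Snapshot:
        """Pool all snapshots taken at time >= ``after`` into one."""
        snaps = [s for s in self.snapshots if s.time >= after]
        if not snaps:
            raise ValueError("no snapshots after requested time")
        return Snapshot(
            time=snaps[-1].time,
            streamline_idx=np.concatenate([s.streamline_idx for s in snaps]),
            s_kin=np.concatenate([s.s_kin for s in snaps]),
            s_minus=np.concatenate([s.s_minus for s in snaps]),
            birth_time=np.concatenate([s.birth_time for s in snaps]),
        )

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.array([s.time for s in self.snapshots])
        n = np.array([s.n_kmts for s in self.snapshots])
        return t, n


def _sample_capture_positions(
    rng: np.random.Generator,
    n: int,
    s_kin: float,
    j_fn,
    s_lo: float,
) -> np.ndarray:
    """Draw initial minus-end positions from j(s) truncated to [s_lo, s_kin]."""
    grid = np.linspace(s_lo, s_kin, 256)
    w = np.clip(np.asarray(j_fn(grid), dtype=float), 0.0, None)
    if w.sum() <= 0:
        return np.full(n, s_kin)
    cdf = np.cumsum(w)
    cdf = cdf / cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def run_simulation(
    cfg: SimulationConfig,
    streamlines: Sequence[Streamline],
    kinetochore_s: np.ndarray,
    kinetochore_streamline: np.ndarray,
    speed: SpeedProfile,
    j_fn=None,
    pin_floor: Optional[float] = None,
    initial_population: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedKMTPopulation:
    """Run the birth–advection–death KMT simulation.

    ``kinetochore_s[i]`` is the kinetochore arc-length coordinate on
    streamline ``kinetochore_streamline[i]``.  ``speed`` supplies v(s)
    (and, after :func:`~kfibers.flux_balance.treadmill_profile`, the
    tubulin speed used by the photoconversion renderer).  With
    ``cfg.capture_fraction > 0``, that fraction of births draws its
    initial minus-end position from ``j_fn``; the rest start at the
    kinetochore with zero length.  ``pin_floor`` (µm) is where arriving
    minus ends pin (defect edge; default 0).  ``initial_population``
    seeds the run with zero-length KMTs on random kinetochores at t=0,
    which with ``nucleation_rate=0`` gives a pure-death process.

    Snapshot times are measured from the end of burn-in; only
    post-burn-in snapshots are retained.  Fixed ``cfg.seed`` (or an
    explicit ``rng``) makes trajectories reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    kin_s = np.asarray(kinetochore_s, dtype=float)
    kin_sl = np.asarray(kinetochore_streamline, dtype=int)
    if kin_s.shape != kin_sl.shape:
        raise ValueError("kinetochore_s and kinetochore_streamline must match")
    if cfg.capture_fraction > 0 and j_fn is None:
        raise ValueError("capture_fraction > 0 requires a j_fn")
    if pin_floor is None:
        pin_floor = 0.0
    # v must be defined over the span of the kinetochore coordinates
    if speed.s[-1] + 1e-9 < kin_s.max():
        raise RuntimeError(
            f"speed profile ends at s={speed.s[-1]:.2f} but kinetochores reach "
            f"s={kin_s.max():.2f}"
        )

    # state arrays
    sl_idx: list[int] = []
    s_kin: list[float] = []
    s_minus: list[float] = []
    birth: list[float] = []
    death: list[float] = []

    t0 = -cfg.burn_in
    if initial_population > 0:
        ks = rng.integers(0, len(kin_s), initial_population)
        for k in ks:
            sl_idx.append(int(kin_sl[k]))
            s_kin.append(float(kin_s[k]))
            s_minus.append(float(kin_s[k]))
            birth.append(t0)
            death.append(t0 + rng.exponential(1.0 / cfg.r))

    state_sl = np.array(sl_idx, dtype=int)
    state_skin = np.array(s_kin, dtype=float)
    state_sm = np.array(s_minus, dtype=float)
    state_birth = np.array(birth, dtype=float)
    state_death = np.array(death, dtype=float)

    lifetimes: list[float] = []
    lifetime_births: list[float] = []
    snapshots: list[Snapshot] = []
    n_steps = int(round((cfg.burn_in + cfg.duration) / cfg.dt))
    snap_every = max(1, int(round(cfg.snapshot_interval / cfg.dt)))
    per_kt_mean = cfg.nucleation_rate * cfg.dt

    t = t0
    for step in range(n_steps):
        # births: Poisson per kinetochore (vectorized over kinetochores)
        n_births = rng.poisson(per_kt_mean, size=len(kin_s))
        tot = int(n_births.sum())
        if tot > 0:
            ks = np.repeat(np.arange(len(kin_s)), n_births)
            new_skin = kin_s[ks]
            new_sl = kin_sl[ks]
            if cfg.capture_fraction > 0:
                is_cap = rng.random(tot) < cfg.capture_fraction
            else:
                is_cap = np.zeros(tot, dtype=bool)
            new_sm = new_skin.copy()
            if np.any(is_cap):
                for i in np.nonzero(is_cap)[0]:
                    new_sm[i] = _sample_capture_positions(
                        rng, 1, new_skin[i], j_fn, pin_floor
                    )[0]
            state_sl = np.concatenate([state_sl, new_sl])
            state_skin = np.concatenate([state_skin, new_skin])
            state_sm = np.concatenate([state_sm, new_sm])
            state_birth = np.concatenate([state_birth, np.full(tot, t)])
            state_death = np.concatenate(
                [state_death, t + rng.exponential(1.0 / cfg.r, tot)]
            )

        # advection: ds/dt = -v(s), explicit Euler, pinned at the defect edge
        if len(state_sm):
            v = speed.v_at(state_sm)
            state_sm = np.maximum(state_sm - v * cfg.dt, pin_floor)

        t = t0 + (step + 1) * cfg.dt

        # deaths
        if len(state_sm):
            dead = state_death <= t
            if np.any(dead):
                lifetimes.extend((state_death[dead] - state_birth[dead]).tolist())
                lifetime_births.extend(state_birth[dead].tolist())
                keep = ~dead
                state_sl = state_sl[keep]
                state_skin = state_skin[keep]
                state_sm = state_sm[keep]
                state_birth = state_birth[keep]
                state_death = state_death[keep]

        if t >= 0 and (step + 1) % snap_every == 0:
            snapshots.append(
                Snapshot(
                    time=t,
                    streamline_idx=state_sl.copy(),
                    s_kin=state_skin.copy(),
                    s_minus=state_sm.copy(),
                    birth_time=state_birth.copy(),
                )
            )

    return SimulatedKMTPopulation(
        snapshots=snapshots,
        lifetimes=np.asarray(lifetimes),
        lifetime_births=np.asarray(lifetime_births),
        streamlines=streamlines,
        config=cfg,
    )


def length_distribution(
    pop: SimulatedKMTPopulation, bin_width: float = 0.5, after: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Binned distribution of KMT lengths (arc length minus end → kinetochore)
    pooled over steady-state snapshots.  Returns (bin_centers, density)."""
    snap = pop.pooled(after=after)
    lengths = snap.lengths()
    if len(lengths) == 0:
        raise ValueError("no KMTs in pooled snapshots")
    hi = max(lengths.max(), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (counts.sum() * bin_width)
    return centers, dens


def projected_orientation_distribution(
    pop: SimulatedKMTPopulation,
    segment_len: float = 0.1,
    bins: int = 20,
    after: float = 0.0,
    max_kmts: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of per-segment axial projection fractions.

    Each live KMT is divided into ``segment_len`` µm pieces along its
    streamline; each piece contributes |Δx| / |Δ| — the fraction of the
    segment lying along the spindle axis.  Returns (bin_centers,
    probability density) over [0, 1].
    """
    snap = pop.pooled(after=after)
    fracs: list[np.ndarray] = []
    order = np.arange(snap.n_kmts)
    if max_kmts is not None and snap.n_kmts > max_kmts:
        order = order[:max_kmts]
    for i in order:
        sl = pop.streamlines[snap.streamline_idx[i]]
        s0, s1 = snap.s_minus[i], snap.s_kin[i]
        if s1 - s0 < segment_len / 2:
            continue
        ss = np.arange(s0, s1, segment_len)
        if ss[-1] < s1:
            ss = np.append(ss, s1)
        pts = sl.point_at(ss)
        d = np.diff(np.atleast_2d(pts), axis=0)
        L = np.linalg.norm(d, axis=1)
        good = L > 1e-12
        fracs.append(np.abs(d[good, 0]) / L[good])
    if not fracs:
        raise ValueError("no segments")
    allf = np.concatenate(fracs)
    counts, edges = np.histogram(allf, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = counts / (counts.sum() * (edges[1] - edges[0]))
    return centers, dens
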