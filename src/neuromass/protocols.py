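"""Numerical experiments on the multipopulation model.

The protocols mirror the standard study design for seizure-like
propagation on a connectome:

* adiabatic up/down sweeps of the common excitability eta_bar (hysteretic
  LA <-> HA transition, maps of regimes over the coupling scale sigma);
* stimulation of a single area (or an EZ set) with a rectangular current
  pulse from a prepared all-LA network state, and detection of which
  areas are recruited into the high-activity regime;
* per-area threshold scans yielding eta_asy(k) (stimulated area stays in
  HA alone: asymptomatic event) and eta_gen(k) (all areas recruited:
  generalized event);
* heterogeneous-excitability repetitions and amplitude/duration sweeps.

Recruitment needs a numeric criterion the mean-field model itself
provides: the rate of the saddle equilibrium of a single population at
the run's eta_bar (with the run's recurrent self-coupling) separates the
LA and HA basins, so an area counts as in HA when its rate exceeds this
separatrix rate r_c and stays above it to the end of the trajectory.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectomes import ConnectomeMatrix, CouplingMatrix, build_coupling
from .fixed_points import single_fixed_points
from .model import NetworkState, Trajectory, integrate, relax
from .params import NeuralMassParams, StimulusProtocol

__all__ = [
    "SweepConfig",
    "SweepResult",
    "RecruitmentResult",
    "ThresholdMap",
    "CriterionError",
    "StatePreparationError",
    "rate_threshold",
    "adiabatic_sweep",
    "map_of_regimes",
    "prepare_LA_state",
    "run_stimulation",
    "detect_recruitments",
    "threshold_scan",
    "threshold_map",
    "heterogeneous_scan",
    "amplitude_sweep",
    "duration_sweep",
]


class CriterionError(RuntimeError):
    """No LA/HA separatrix exists at the requested parameters."""


class StatePreparationError(RuntimeError):
    """The all-LA network state could not be prepared."""


@dataclass
class SweepConfig:
    """Adiabatic sweep grid: eta_bar from -50 to 10 in steps of 1.5,
    2 s relaxation per step, carrying the final state forward."""

    eta_start: float = -50.0
    eta_stop: float = 10.0
    eta_step: float = 1.5
    settle_time: float = 2000.0  # ms
    dt: float = 0.01  # ms

    def __post_init__(self) -> None:
        if not (self.eta_step > 0):
            raise ValueError("eta_step must be positive")
        if not (self.settle_time > 0):
            raise ValueError("settle_time must be positive")

    @property
    def eta_grid(self) -> np.ndarray:
        n = int(round((self.eta_stop - self.eta_start) / self.eta_step))
        return self.eta_start + self.eta_step * np.arange(n + 1)


@dataclass
class SweepResult:
    """Equilibrium rates per sweep step (network average and per area)."""

    eta_values: np.ndarray
    mean_rate: np.ndarray
    per_population_rates: np.ndarray
    direction: str
    final_state: NetworkState = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_population_rates,
            columns=[f"r_{k}" for k in range(self.per_population_rates.shape[1])],
        )
        df.insert(0, "eta_bar", self.eta_values)
        df.insert(1, "mean_rate", self.mean_rate)
        df.insert(2, "direction", self.direction)
        return df


@dataclass
class RecruitmentResult:
    """Outcome of one stimulation run.

    ``recruit_time`` holds the per-area time (ms after stimulus onset) at
    which the area enters and stays in the HA regime, NaN where the area
    is never recruited.  ``n_recruited`` includes the stimulated area(s).
    """

    recruit_time: np.ndarray
    stimulated: tuple[int, ...]
    r_c: np.ndarray
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        n = self.recruit_time.size
        rec = set(np.flatnonzero(np.isfinite(self.recruit_time)))
        stim = set(self.stimulated)
        if not rec:
            self.classification = "none"
        elif rec <= stim:
            self.classification = "asymptomatic"
        elif len(rec) == n:
            self.classification = "generalized"
        else:
            self.classification = "partial"

    @property
    def n_recruited(self) -> int:
        return int(np.isfinite(self.recruit_time).sum())

    @property
    def order(self) -> list[int]:
        rec = np.flatnonzero(np.isfinite(self.recruit_time))
        return [int(k) for k in rec[np.argsort(self.recruit_time[rec])]]


@dataclass
class ThresholdMap:
    """Per-area seizure thresholds on a fixed eta_bar grid.

    ``eta_asy[k]`` is the smallest grid eta_bar at which stimulating area
    k yields at least one recruited area; ``eta_gen[k]`` the smallest at
    which every area is recruited (NaN when never attained on the grid).
    Grid values where the all-LA state cannot be prepared are flagged in
    ``saturated`` and excluded from the minimisation.
    """

    eta_grid: np.ndarray
    areas: np.ndarray
    eta_asy: np.ndarray
    eta_gen: np.ndarray
    n_recruited: np.ndarray  # shape (n_areas, n_grid), -1 where saturated
    saturated: np.ndarray  # shape (n_grid,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area": self.areas,
            "eta_asy": self.eta_asy,
            "eta_gen": self.eta_gen,
        })


def rate_threshold(
    eta_bar: float,
    J_self: float,
    delta: float = 1.0,
    tau_m: float = 20.0,
    search_halfwidth: float = 60.0,
) -> float:
    """Separatrix rate r_c between the LA and HA basins.

    Returns the rate of the saddle equilibrium of a single population at
    ``eta_bar`` with recurrent coupling ``J_self``.  Outside the bistable
    window the geometric mean of the LA and HA rates at the nearest
    bistable eta_bar is used instead; raises :class:`CriterionError` when
    no bistability exists anywhere nearby (e.g. J_self too small).
    """
    def saddle(e):
        fps = single_fixed_points(e, delta=delta, tau_m=tau_m, J_self=J_self)
        return fps if len(fps) == 3 else None

    fps = saddle(eta_bar)
    if fps is not None:
        return fps[1].r_star
    step = 0.1
    for d in np.arange(step, search_halfwidth + step, step):
        for e in (eta_bar - d, eta_bar + d):
            fps = saddle(e)
            if fps is not None:
                return float(np.sqrt(fps[0].r_star * fps[2].r_star))
    raise CriterionError(
        f"no LA/HA bistability near eta_bar={eta_bar} for J_self={J_self}; "
        "the recruitment criterion is undefined"
    )


def _rc_vector(params: NeuralMassParams, coupling: CouplingMatrix) -> np.ndarray:
    """Per-area separatrix rate, using each area's eta_bar and its own
    recurrent (diagonal) coupling."""
    n = coupling.n_pop
    eta = params.eta_vector(n)
    diag = np.diag(coupling.J)
    out = np.empty(n)
    cache: dict[tuple[float, float], float] = {}
    for k in range(n):
        key = (round(float(eta[k]), 12), round(float(diag[k]), 12))
        if key not in cache:
            cache[key] = rate_threshold(
                eta[k], diag[k], delta=params.delta, tau_m=params.tau_m
            )
        out[k] = cache[key]
    return out


def adiabatic_sweep(
    coupling: CouplingMatrix,
    params: NeuralMassParams,
    config: SweepConfig | None = None,
    direction: str = "both",
):
    """Up/down adiabatic sweep of the common excitability.

    Up: start all areas at (r, v) = (0, 0) at eta_start and step eta_bar
    upward, relaxing ``settle_time`` per step and carrying the final state
    forward; down: continue from the top state stepping back down.
    Returns one :class:`SweepResult`, or an (up, down) pair for
    ``direction="both"``.
    """
    config = config or SweepConfig()
    grid = config.eta_grid
    n = coupling.n_pop

    def _one(etas: np.ndarray, state: NetworkState, label: str) -> SweepResult:
        rates = np.empty((etas.size, n))
        for i, e in enumerate(etas):
            p = NeuralMassParams(
                tau_m=params.tau_m, delta=params.delta, eta_bar=e,
                I_B=params.I_B,
            )
            try:
                state = relax(p, coupling, state, config.settle_time,
                              dt=config.dt)
            except Exception as err:
                raise type(err)(f"{err} (sweep at eta_bar={e})") from err
            rates[i] = state.r
        return SweepResult(
            eta_values=etas.copy(), mean_rate=rates.mean(axis=1),
            per_population_rates=rates, direction=label, final_state=state,
        )

    if direction in ("up", "both"):
        up = _one(grid, NetworkState.zeros(n), "up")
        if direction == "up":
            return up
    if direction == "down":
        # start on the HA branch at the top of the grid
        fps = single_fixed_points(
            grid[-1], delta=params.delta, tau_m=params.tau_m,
            J_self=float(np.diag(coupling.J).mean()),
        )
        top = fps[-1]
        state = NetworkState(np.full(n, top.r_star), np.full(n, top.v_star))
        return _one(grid[::-1], state, "down")
    down = _one(grid[::-1], up.final_state, "down")
    return up, down


def map_of_regimes(
    conn: ConnectomeMatrix,
    params: NeuralMassParams,
    sigma_values: np.ndarray | None = None,
    config: SweepConfig | None = None,
    intra: float = 20.0,
    inter_scale: float = 5.0,
) -> dict:
    """Network-average equilibrium rate over the (sigma, eta_bar) plane.

    One up/down sweep pair per sigma; returns a dict with the grids and
    two 2-D arrays (n_sigma, n_eta) of <r*>.
    """
    if sigma_values is None:
        sigma_values = np.arange(0.0, 2.0 + 1e-9, 0.05)
    config = config or SweepConfig()
    grid = config.eta_grid
    up_map = np.empty((len(sigma_values), grid.size))
    down_map = np.empty_like(up_map)
    for i, s in enumerate(sigma_values):
        coupling = build_coupling(conn, sigma=float(s), intra=intra,
                                  inter_scale=inter_scale)
        up, down = adiabatic_sweep(coupling, params, config)
        up_map[i] = up.mean_rate
        down_map[i] = down.mean_rate[::-1]  # align with ascending grid
    return {
        "sigma_values": np.asarray(sigma_values, dtype=float),
        "eta_values": grid,
        "up": up_map,
        "down": down_map,
    }


def prepare_LA_state(
    coupling: CouplingMatrix,
    params: NeuralMassParams,
    settle_time: float = 2000.0,
    dt: float = 0.01,
    r_c: np.ndarray | None = None,
) -> NetworkState:
    """All-LA network state: relax from (r, v) = (0, 0) and verify that
    every area stays below the HA criterion."""
    n = coupling.n_pop
    if r_c is None:
        r_c = _rc_vector(params, coupling)
    state = relax(params, coupling, NetworkState.zeros(n), settle_time, dt=dt)
    above = np.flatnonzero(state.r >= r_c)
    if above.size:
        raise StatePreparationError(
            f"areas {above.tolist()} relaxed into the HA regime; "
            "eta_bar too large for an all-LA preparation"
        )
    return state


def run_stimulation(
    coupling: CouplingMatrix,
    params: NeuralMassParams,
    stim: StimulusProtocol,
    post_window: float = 2000.0,
    state0: NetworkState | None = None,
    settle_time: float = 2000.0,
    dt: float = 0.01,
    record_dt: float = 0.1,
    r_c: np.ndarray | None = None,
) -> Trajectory:
    """Stimulation run: baseline, rectangular pulse, and ``post_window``
    ms after pulse offset, started from a prepared all-LA state."""
    if state0 is None:
        state0 = prepare_LA_state(coupling, params, settle_time=settle_time,
                                  dt=dt, r_c=r_c)
    t_total = stim.t_off + post_window
    return integrate(params, coupling, state0, t_total, dt=dt,
                     stimulus=stim, record_dt=record_dt)


def detect_recruitments(
    traj: Trajectory,
    stim: StimulusProtocol,
    criterion: np.ndarray | float,
) -> RecruitmentResult:
    """Which areas passed from LA to HA, and when.

    An area is recruited iff its rate at the trajectory end exceeds the
    separatrix rate r_c; its recruitment time is the first time after
    stimulus onset at which the rate crosses r_c from below and remains
    above through the trajectory end.  Times are measured from onset.
    """
    r_c = np.broadcast_to(np.asarray(criterion, dtype=float),
                          (traj.n_pop,))
    if np.any(~np.isfinite(r_c)) or np.any(r_c <= 0):
        raise CriterionError("recruitment criterion must be finite positive")
    times = traj.times
    above = traj.r >= r_c[None, :]
    recruit_time = np.full(traj.n_pop, np.nan)
    after_onset = times >= stim.t_on
    for k in range(traj.n_pop):
        if not above[-1, k]:
            continue
        col = above[:, k]
        below = np.flatnonzero(~col)
        start = 0 if below.size == 0 else below[-1] + 1
        # sustained crossing must not precede the stimulus onset
        idx = max(start, int(np.argmax(after_onset)))
        recruit_time[k] = times[idx] - stim.t_on
    return RecruitmentResult(
        recruit_time=recruit_time, stimulated=tuple(stim.targets), r_c=r_c,
    )


class _LACache:
    """Shared per-eta cache of (r_c, prepared LA state) for grid scans."""

    def __init__(self, coupling: CouplingMatrix, params: NeuralMassParams,
                 settle_time: float, dt: float):
        self.coupling = coupling
        self.params = params
        self.settle_time = settle_time
        self.dt = dt
        self._store: dict[float, tuple] = {}

    def get(self, eta: float):
        """Returns (r_c, state) or None when the all-LA state is not
        preparable at this eta (saturated-HA regime)."""
        key = round(float(eta), 9)
        if key not in self._store:
            p = NeuralMassParams(
                tau_m=self.params.tau_m, delta=self.params.delta,
                eta_bar=eta, I_B=self.params.I_B,
            )
            try:
                r_c = _rc_vector(p, self.coupling)
                state = prepare_LA_state(
                    self.coupling, p, settle_time=self.settle_time,
                    dt=self.dt, r_c=r_c,
                )
                self._store[key] = (p, r_c, state)
            except (StatePreparationError, CriterionError):
                self._store[key] = None
        return self._store[key]


def _scan_area(
    cache: _LACache, area: int, eta_grid: np.ndarray,
    amplitude: float, duration: float, post_window: float,
):
    n = cache.coupling.n_pop
    counts = np.full(eta_grid.size, -1, dtype=int)
    saturated = np.zeros(eta_grid.size, dtype=bool)
    for i, e in enumerate(eta_grid):
        prep = cache.get(e)
        if prep is None:
            saturated[i] = True
            continue
        p, r_c, state = prep
        stim = StimulusProtocol(targets=(area,), amplitude=amplitude,
                                t_on=0.0, duration=duration)
        traj = run_stimulation(
            cache.coupling, p, stim, post_window=post_window,
            state0=state.copy(), dt=cache.dt, record_dt=1.0,
        )
        counts[i] = detect_recruitments(traj, stim, r_c).n_recruited
    ok = counts >= 0
    asy = eta_grid[ok & (counts >= 1)]
    gen = eta_grid[ok & (counts == n)]
    eta_asy = float(asy.min()) if asy.size else np.nan
    eta_gen = float(gen.min()) if gen.size else np.nan
    return eta_asy, eta_gen, counts, saturated


def threshold_scan(
    conn_or_coupling,
    params: NeuralMassParams,
    area: int,
    eta_range: tuple[float, float] = (-15.0, -4.0),
    eta_step: float = 0.1,
    sigma: float = 1.0,
    amplitude: float = 10.0,
    duration: float = 400.0,
    post_window: float = 2000.0,
    settle_time: float = 2000.0,
    dt: float = 0.01,
    _cache: "_LACache | None" = None,
):
    """Scan eta_bar for one stimulated area.

    Returns (eta_asy, eta_gen, n_recruited per grid value, saturated
    mask); thresholds are grid values, not interpolated.
    """
    coupling = (
        conn_or_coupling
        if isinstance(conn_or_coupling, CouplingMatrix)
        else build_coupling(conn_or_coupling, sigma=sigma)
    )
    if not (0 <= area < coupling.n_pop):
        raise ValueError(f"area {area} out of range")
    lo, hi = eta_range
    n_steps = int(round((hi - lo) / eta_step))
    eta_grid = lo + eta_step * np.arange(n_steps + 1)
    cache = _cache or _LACache(coupling, params, settle_time, dt)
    return _scan_area(cache, area, eta_grid, amplitude, duration,
                      post_window)


def threshold_map(
    conn_or_coupling,
    params: NeuralMassParams,
    areas=None,
    **scan_kwargs,
) -> ThresholdMap:
    """Per-area threshold scan over all (or the given) areas, sharing the
    LA-state preparation across areas."""
    coupling = (
        conn_or_coupling
        if isinstance(conn_or_coupling, CouplingMatrix)
        else build_coupling(conn_or_coupling,
                            sigma=scan_kwargs.get("sigma", 1.0))
    )
    n = coupling.n_pop
    areas = np.arange(n) if areas is None else np.asarray(areas, dtype=int)
    settle_time = scan_kwargs.get("settle_time", 2000.0)
    dt = scan_kwargs.get("dt", 0.01)
    cache = _LACache(coupling, params, settle_time, dt)
    eta_asy = np.empty(areas.size)
    eta_gen = np.empty(areas.size)
    counts = None
    saturated = None
    for i, k in enumerate(areas):
        a, g, c, sat = threshold_scan(
            coupling, params, int(k), _cache=cache, **scan_kwargs
        )
        if counts is None:
            counts = np.empty((areas.size, c.size), dtype=int)
            saturated = sat
        eta_asy[i], eta_gen[i] = a, g
        counts[i] = c
    lo, hi = scan_kwargs.get("eta_range", (-15.0, -4.0))
    step = scan_kwargs.get("eta_step", 0.1)
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    return ThresholdMap(
        eta_grid=grid, areas=areas, eta_asy=eta_asy, eta_gen=eta_gen,
        n_recruited=counts, saturated=saturated,
    )


def heterogeneous_scan(
    conn_or_coupling,
    params: NeuralMassParams,
    eta_G_values: np.ndarray,
    sd: float = 0.1,
    reps: int = 10,
    seed: int | None = None,
    areas=None,
    sigma: float = 1.0,
    amplitude: float = 10.0,
    duration: float = 400.0,
    post_window: float = 2000.0,
    settle_time: float = 2000.0,
    dt: float = 0.01,
) -> np.ndarray:
    """Average recruitment counts with Gaussian-distributed excitabilities.

    For each repetition, per-area excitabilities are drawn from
    Normal(eta_G, sd); each area in ``areas`` is stimulated in turn and
    the recruitment count recorded (-1 where the all-LA state is not
    preparable).  Returns the count averaged over repetitions, shape
    (n_areas, n_eta_G); grid points saturated in every repetition yield
    NaN.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    coupling = (
        conn_or_coupling
        if isinstance(conn_or_coupling, CouplingMatrix)
        else build_coupling(conn_or_coupling, sigma=sigma)
    )
    n = coupling.n_pop
    areas = np.arange(n) if areas is None else np.asarray(areas, dtype=int)
    eta_G_values = np.asarray(eta_G_values, dtype=float)
    rng = np.random.default_rng(seed)
    if sd == 0:
        reps = 1
    sums = np.zeros((areas.size, eta_G_values.size))
    n_ok = np.zeros_like(sums)
    for _ in range(reps):
        offsets = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        for j, eG in enumerate(eta_G_values):
            p = NeuralMassParams(
                tau_m=params.tau_m, delta=params.delta,
                eta_bar=eG + offsets, I_B=params.I_B,
            )
            try:
                r_c = _rc_vector(p, coupling)
                state = prepare_LA_state(
                    coupling, p, settle_time=settle_time, dt=dt, r_c=r_c,
                )
            except (StatePreparationError, CriterionError):
                continue
            for i, k in enumerate(areas):
                stim = StimulusProtocol(targets=(int(k),),
                                        amplitude=amplitude,
                                        duration=duration)
                traj = run_stimulation(
                    coupling, p, stim, post_window=post_window,
                    state0=state.copy(), dt=dt, record_dt=1.0,
                )
                sums[i, j] += detect_recruitments(traj, stim,
                                                  r_c).n_recruited
                n_ok[i, j] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)


def _first_recruits_table(
    coupling, params, area, values, vary: str, amplitude, duration,
    first_n, post_window, settle_time, dt,
) -> pd.DataFrame:
    r_c = _rc_vector(params, coupling)
    state = prepare_LA_state(coupling, params, settle_time=settle_time,
                             dt=dt, r_c=r_c)
    rows = []
    for val in values:
        amp = float(val) if vary == "amplitude" else amplitude
        dur = float(val) if vary == "duration" else duration
        if amp == 0.0 or dur == 0.0:
            order, times = [], []
        else:
            stim = StimulusProtocol(targets=(area,), amplitude=amp,
                                    duration=dur)
            traj = run_stimulation(
                coupling, params, stim, post_window=post_window,
                state0=state.copy(), dt=dt, record_dt=1.0,
            )
            res = detect_recruitments(traj, stim, r_c)
            order = [k for k in res.order if k != area]
            times = [res.recruit_time[k] for k in order]
        for pos in range(first_n):
            rows.append({
                vary: float(val),
                "position": pos + 1,
                "area": order[pos] if pos < len(order) else None,
                "time_ms": times[pos] if pos < len(times) else np.nan,
            })
    return pd.DataFrame(rows)


def amplitude_sweep(
    conn_or_coupling,
    params: NeuralMassParams,
    area: int,
    I_S_values,
    t_I: float = 400.0,
    sigma: float = 1.0,
    first_n: int = 10,
    post_window: float = 2000.0,
    settle_time: float = 2000.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Recruitment times of the first ``first_n`` areas vs pulse amplitude.

    Missing recruitments are recorded as None/NaN rows; recruitment times
    shorten as the amplitude grows while the order is nearly preserved.
    """
    coupling = (
        conn_or_coupling
        if isinstance(conn_or_coupling, CouplingMatrix)
        else build_coupling(conn_or_coupling, sigma=sigma)
    )
    return _first_recruits_table(
        coupling, params, int(area), I_S_values, "amplitude",
        amplitude=None, duration=t_I, first_n=first_n,
        post_window=post_window, settle_time=settle_time, dt=dt,
    )


def duration_sweep(
    conn_or_coupling,
    params: NeuralMassParams,
    area: int,
    t_I_values,
    I_S: float = 15.0,
    sigma: float = 1.0,
    first_n: int = 10,
    post_window: float = 2000.0,
    settle_time: float = 2000.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Recruitment times of the first areas vs pulse duration (fixed
    amplitude); once the pulse outlasts full recruitment, further
    lengthening leaves times unchanged."""
    coupling = (
        conn_or_coupling
        if isinstance(conn_or_coupling, CouplingMatrix)
        else build_coupling(conn_or_coupling, sigma=sigma)
    )
    return _first_recruits_table(
        coupling, params, int(area), t_I_values, "duration",
        amplitude=I_S, duration=None, first_n=first_n,
        post_window=post_window, settle_time=settle_time, dt=dt,
    )
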