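"""Right-hand sides and integration of the neural-mass network model.

Each brain region k is an exact mean-field reduction of an infinite
all-to-all QIF population with Lorentzian-distributed excitabilities,
described by its firing rate r_k (1/ms) and mean membrane potential v_k:

    tau_m dr_k/dt = delta / (tau_m pi) + 2 r_k v_k
    tau_m dv_k/dt = v_k^2 + eta_bar(k) + I_B + I_S^(k)(t)
                    - (pi tau_m r_k)^2 + tau_m sum_l J_kl r_l

with J the coupling matrix built from the structural connectome
(diagonal = recurrent intra-population synapses).  Integration is explicit
fixed-step RK4; the default step of 0.01 ms resolves the several-hundred-Hz
damped focus oscillations with >= 40 steps per period.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._integrators import rk4_network
from .params import NeuralMassParams, StimulusProtocol

__all__ = [
    "NetworkState",
    "Trajectory",
    "IntegrationError",
    "single_rhs",
    "network_rhs",
    "integrate",
    "relax",
]

DEFAULT_DT = 0.01  # ms


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass
class NetworkState:
    """Per-population firing rates (1/ms) and mean membrane potentials."""

    r: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.r.shape != self.v.shape:
            raise ValueError("r and v must have equal length")
        if np.any(self.r < 0):
            raise ValueError("firing rates must be nonnegative")

    @property
    def n_pop(self) -> int:
        return self.r.size

    def copy(self) -> "NetworkState":
        return NetworkState(self.r.copy(), self.v.copy())

    @classmethod
    def zeros(cls, n_pop: int) -> "NetworkState":
        return cls(np.zeros(n_pop), np.zeros(n_pop))


@dataclass
class Trajectory:
    """Sampled trajectory of the network on a strictly increasing time grid.

    ``r`` and ``v`` have shape (n_times, n_pop); times are in ms from the
    start of the run.  The applied stimulus is kept as the protocol object
    and can be materialised per population via :meth:`stimulus_trace`.
    """

    times: np.ndarray
    r: np.ndarray
    v: np.ndarray
    stimulus: StimulusProtocol | None = None
    dt: float = DEFAULT_DT
    params: NeuralMassParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.times.size != self.r.shape[0] or self.r.shape != self.v.shape:
            raise ValueError("sample count must equal time-grid length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_pop(self) -> int:
        return self.r.shape[1]

    def final_state(self) -> NetworkState:
        return NetworkState(self.r[-1].copy(), self.v[-1].copy())

    def stimulus_trace(self) -> np.ndarray:
        """Applied current I_S^(k)(t), shape (n_times, n_pop)."""
        out = np.zeros_like(self.r)
        if self.stimulus is not None:
            s = self.stimulus
            window = (self.times >= s.t_on) & (self.times < s.t_off)
            out[np.ix_(window, list(s.targets))] = s.amplitude
        return out

    def save_npz(self, path) -> None:
        """Export as a compressed array container with a JSON sidecar of
        the run parameters."""
        import json
        from pathlib import Path

        np.savez_compressed(
            path, times=self.times, r=self.r, v=self.v,
            stim=self.stimulus_trace(),
        )
        meta: dict = {"dt_ms": self.dt}
        if self.params is not None:
            eta = np.asarray(self.params.eta_bar).tolist()
            meta.update(tau_m=self.params.tau_m, delta=self.params.delta,
                        eta_bar=eta, I_B=self.params.I_B)
        if self.stimulus is not None:
            s = self.stimulus
            meta["stimulus"] = {
                "targets": list(s.targets), "amplitude": s.amplitude,
                "t_on_ms": s.t_on, "duration_ms": s.duration,
            }
        p = Path(path)
        p.with_suffix(p.suffix + ".json").write_text(
            json.dumps(meta, indent=1)
        )


def _coupling_array(coupling, n_pop: int | None = None) -> np.ndarray:
    J = getattr(coupling, "J", coupling)
    J = np.asarray(J, dtype=float)
    if J.ndim == 0:  # scalar self-coupling for a single population
        J = J.reshape(1, 1)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("coupling must be a square matrix")
    if n_pop is not None and J.shape[0] != n_pop:
        raise ValueError(
            f"coupling is {J.shape[0]}x{J.shape[0]} but the state has "
            f"{n_pop} populations"
        )
    return J


def single_rhs(
    r: float,
    v: float,
    params: NeuralMassParams,
    J_self: float = 0.0,
    I_ext: float = 0.0,
) -> tuple[float, float]:
    """Time derivatives (dr/dt, dv/dt) of a single population."""
    if not (np.isfinite(r) and np.isfinite(v)):
        raise ValueError("non-finite state")
    if r < 0:
        raise ValueError("firing rate must be nonnegative")
    eta = float(np.asarray(params.eta_bar).ravel()[0])
    tau = params.tau_m
    dr = (params.delta / (tau * np.pi) + 2.0 * r * v) / tau
    dv = (
        v * v + eta + params.I_B + I_ext
        - (np.pi * tau * r) ** 2 + tau * J_self * r
    ) / tau
    return dr, dv


def network_rhs(
    state: NetworkState,
    params: NeuralMassParams,
    coupling,
    stimulus_values: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised derivatives of the multipopulation model.

    ``stimulus_values`` is the instantaneous per-population current
    I_S^(k); with zero off-diagonal coupling each component reduces to
    :func:`single_rhs` of the corresponding population.
    """
    n = state.n_pop
    J = _coupling_array(coupling, n)
    eta = params.eta_vector(n)
    i_stim = np.broadcast_to(np.asarray(stimulus_values, dtype=float), (n,))
    tau = params.tau_m
    r, v = state.r, state.v
    dr = (params.delta / (tau * np.pi) + 2.0 * r * v) / tau
    dv = (
        v * v + eta + params.I_B + i_stim
        - (np.pi * tau * r) ** 2 + tau * (J @ r)
    ) / tau
    return dr, dv


def integrate(
    params: NeuralMassParams,
    coupling,
    state0: NetworkState,
    t_span: float,
    dt: float = DEFAULT_DT,
    stimulus: StimulusProtocol | None = None,
    record_dt: float | None = 0.1,
) -> Trajectory:
    """Integrate the network for ``t_span`` ms with fixed-step RK4.

    A rectangular stimulus pulse is applied to its target populations for
    ``t_on <= t < t_on + duration``.  The state is recorded every
    ``record_dt`` ms (None records only the first and final state).
    Raises :class:`IntegrationError` naming the blow-up time if the state
    diverges.
    """
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if not (t_span > 0):
        raise ValueError("t_span must be positive")
    n = state0.n_pop
    J = _coupling_array(coupling, n)
    eta = params.eta_vector(n)
    n_steps = int(round(t_span / dt))

    stim_mask = np.zeros(n)
    stim_amp = 0.0
    on_step, off_step = 0, 0
    if stimulus is not None:
        stimulus.validate_targets(n)
        stim_mask[list(stimulus.targets)] = 1.0
        stim_amp = stimulus.amplitude
        on_step = int(round(stimulus.t_on / dt))
        off_step = int(round(stimulus.t_off / dt))

    if record_dt is None:
        stride = n_steps
    else:
        stride = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // stride + 1
    if n_steps % stride != 0:
        n_rec += 1
    rec_r = np.empty((n_rec, n))
    rec_v = np.empty((n_rec, n))

    r = state0.r.copy()
    v = state0.v.copy()
    fail = rk4_network(
        r, v, J, eta, float(params.I_B), params.tau_m, params.delta,
        dt, n_steps, stim_amp, stim_mask, on_step, off_step, stride,
        rec_r, rec_v,
    )
    if fail >= 0:
        raise IntegrationError(
            f"state diverged at t = {fail * dt:.3f} ms"
        )
    times = np.minimum(
        np.arange(n_rec) * stride * dt, n_steps * dt
    )
    times[-1] = n_steps * dt
    if n_rec >= 2 and times[-1] <= times[-2]:
        # final step fell on the record grid: drop the duplicate slot
        times, rec_r, rec_v = times[:-1], rec_r[:-1], rec_v[:-1]
    return Trajectory(
        times=times, r=rec_r, v=rec_v, stimulus=stimulus, dt=dt,
        params=params,
    )


def relax(
    params: NeuralMassParams,
    coupling,
    state0: NetworkState,
    duration: float,
    dt: float = DEFAULT_DT,
) -> NetworkState:
    """Final state after ``duration`` ms without stimulation (no recording)."""
    traj = integrate(params, coupling, state0, duration, dt=dt,
                     record_dt=None)
    return traj.final_state()
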