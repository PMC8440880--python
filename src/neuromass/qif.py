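"""Finite-N microscopic QIF network: the exactness oracle of the mean field.

Simulates N all-to-all coupled quadratic integrate-and-fire neurons without
autapses,

    tau_m dV_i/dt = V_i^2 + eta_i + I_B + I_S(t) + tau_m J s(t),

with s(t) the population-averaged delta-spike train, so every presynaptic
spike kicks each other membrane potential by J/N.  The default integrator
advances each membrane with the closed-form solution of the quadratic
(Riccati) flow between kicks, which realises the ideal infinite
threshold/reset exactly; an Euler scheme with a finite V_peak and a
two-phase hold (+V_peak then -V_peak, tau_m/V_peak ms each, restoring the
ideal neuron's travel time beyond the threshold) is kept as an
independent cross-check.  For large N the binned population rate and the
centre of the membrane-potential distribution converge to the neural-mass
fixed points.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._integrators import qif_euler, qif_exact_map
from .model import IntegrationError
from .params import QIFParams

__all__ = [
    "sample_lorentzian",
    "lorentzian_voltage_samples",
    "qif_simulate",
    "QIFResult",
]


def sample_lorentzian(
    eta_bar: float,
    delta: float,
    N: int,
    scheme: str = "deterministic_quantiles",
    seed: int | None = None,
) -> np.ndarray:
    """Sample N excitabilities from the Lorentzian g(eta).

    ``deterministic_quantiles`` places samples at the equidistant quantiles
    eta_i = eta_bar + delta * tan(pi (2i - N - 1) / (2 (N + 1))), i = 1..N,
    which removes sampling noise from finite-size checks; ``random`` draws
    i.i.d. Cauchy(eta_bar, delta) variates with the given seed.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if scheme == "deterministic_quantiles":
        i = np.arange(1, N + 1)
        return eta_bar + delta * np.tan(
            np.pi * (2 * i - N - 1) / (2.0 * (N + 1))
        )
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return eta_bar + delta * rng.standard_cauchy(N)
    raise ValueError(f"unknown sampling scheme {scheme!r}")


def lorentzian_voltage_samples(
    r0: float,
    v0: float,
    N: int,
    tau_m: float = 20.0,
    V_peak: float = 100.0,
) -> np.ndarray:
    """Deterministic voltages matching the stationary mean-field state.

    At a fixed point the membrane potentials are Lorentzian-distributed
    with centre v0 and HWHM pi*tau_m*r0; quantile samples clipped to the
    numerical range (-V_peak, V_peak) initialise the microscopic network
    on the corresponding macroscopic branch.
    """
    i = np.arange(1, N + 1)
    width = max(np.pi * tau_m * r0, 1e-12)
    V = v0 + width * np.tan(np.pi * (2 * i - N - 1) / (2.0 * (N + 1)))
    return np.clip(V, -0.95 * V_peak, 0.95 * V_peak)


@dataclass
class QIFResult:
    """Binned output of a microscopic run.

    ``rate`` is the smoothed population rate in 1/ms on the 1-ms bin grid
    ``t_bins``; ``v_mean`` the population-mean voltage per bin (all
    neurons), ``v_mean_masked`` the mean excluding neurons held in the
    threshold excursion.  ``spikes`` is the raw spike count per bin.
    """

    t_bins: np.ndarray
    rate: np.ndarray
    v_mean: np.ndarray
    v_mean_masked: np.ndarray
    spikes: np.ndarray
    v_median: np.ndarray | None = None

    def time_average(
        self, t_start: float, t_end: float | None = None,
        voltage: str = "median",
    ) -> tuple[float, float]:
        """Time-averaged (rate, voltage centre) over [t_start, t_end] ms.

        ``voltage`` selects the estimator: "median" (per-bin sample
        median, the robust centre of the heavy-tailed voltage
        distribution; falls back to the clipped mean when unavailable),
        "mean" (clipped mean over all neurons) or "masked" (clipped mean
        excluding neurons held in the threshold excursion).
        """
        sel = self.t_bins >= t_start
        if t_end is not None:
            sel &= self.t_bins <= t_end
        if voltage == "median" and self.v_median is not None:
            v = self.v_median
        elif voltage == "masked":
            v = self.v_mean_masked
        else:
            v = self.v_mean
        return float(self.rate[sel].mean()), float(v[sel].mean())


def qif_simulate(
    qif: QIFParams,
    duration: float,
    I_S: float = 0.0,
    t_on: float = 0.0,
    t_I: float = 0.0,
    bin_ms: float = 1.0,
    smooth_ms: float = 10.0,
    method: str = "exact",
) -> QIFResult:
    """Simulate the QIF network for ``duration`` ms.

    ``method="exact"`` advances each membrane with the closed-form
    solution of the Riccati equation between synaptic kicks (ideal
    infinite threshold/reset; ``V_peak`` only clips the voltage entering
    the population mean); ``method="euler"`` is plain Euler stepping with
    the finite-threshold reset and two-phase hold, kept as an independent
    cross-check of the exact map.  The rectangular stimulus of amplitude
    ``I_S`` is applied to every neuron for ``t_on <= t < t_on + t_I``.
    The population rate is the binned spike count / (N * bin) smoothed
    with a rectangular kernel of ``smooth_ms``.
    """
    dt = qif.dt
    n_steps = int(round(duration / dt))
    bin_steps = max(1, int(round(bin_ms / dt)))
    n_bins = int(np.ceil(n_steps / bin_steps))

    if qif.V0 is not None:
        V = np.asarray(qif.V0, dtype=float).copy()
        if V.shape != (qif.N,):
            raise ValueError("V0 must have shape (N,)")
    else:
        V = np.full(qif.N, -1.0)

    spike_bins = np.zeros(n_bins, dtype=np.int64)
    v_mean = np.zeros(n_bins)
    v_mean_masked = np.zeros(n_bins)
    on_step = int(round(t_on / dt))
    off_step = int(round((t_on + t_I) / dt))

    v_median = None
    if method == "exact":
        v_median = np.zeros(n_bins)
        fail = qif_exact_map(
            V, qif.eta_samples, qif.J, qif.tau_m, qif.I_B, dt, n_steps,
            qif.V_peak, on_step, off_step, I_S, bin_steps, spike_bins,
            v_mean, v_median,
        )
        v_mean_masked = v_mean.copy()
    elif method == "euler":
        n_hold = (
            int(round(qif.tau_m / qif.V_peak / dt)) if qif.refractory else 0
        )
        phase = np.zeros(qif.N, dtype=np.int8)
        hold_left = np.zeros(qif.N, dtype=np.int64)
        fail = qif_euler(
            V, qif.eta_samples, qif.J, qif.tau_m, qif.I_B, dt, n_steps,
            qif.V_peak, on_step, off_step, I_S, n_hold, phase, hold_left,
            bin_steps, spike_bins, v_mean, v_mean_masked,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    if fail >= 0:
        raise IntegrationError(
            f"membrane potential overflowed at t = {fail * dt:.3f} ms; "
            "reduce dt"
        )

    rate = spike_bins / (qif.N * bin_ms)
    w = max(1, int(round(smooth_ms / bin_ms)))
    if w > 1:
        kernel = np.full(w, 1.0 / w)
        rate = np.convolve(rate, kernel, mode="same")
    t_bins = (np.arange(n_bins) + 0.5) * bin_ms
    return QIFResult(
        t_bins=t_bins, rate=rate, v_mean=v_mean,
        v_mean_masked=v_mean_masked, spikes=spike_bins, v_median=v_median,
    )
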