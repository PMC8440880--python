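"""Parameter containers for the neural-mass and microscopic QIF models.

Units convention: time is measured in milliseconds throughout the package and
firing rates in 1/ms; rates are converted to Hz (x1000) only at I/O
boundaries.  Voltages and currents are dimensionless, as in the underlying
mean-field equations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeuralMassParams", "StimulusProtocol", "QIFParams"]


@dataclass
class NeuralMassParams:
    """Parameters of one (or several) exact QIF-derived neural-mass populations.

    Parameters
    ----------
    tau_m : float
        Membrane time constant in ms (default 20).
    delta : float
        Half-width at half-maximum of the Lorentzian excitability
        distribution (> 0, default 1).
    eta_bar : float or array
        Mean excitability; a scalar applies to every population, an array
        gives one value per population.
    I_B : float
        Constant background DC current (default 0).
    """

    tau_m: float = 20.0
    delta: float = 1.0
    eta_bar: np.ndarray | float = 0.0
    I_B: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_m > 0):
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")
        eta = np.asarray(self.eta_bar, dtype=float)
        if not np.all(np.isfinite(eta)):
            raise ValueError("eta_bar must be finite")
        if not np.isfinite(self.I_B):
            raise ValueError("I_B must be finite")

    def eta_vector(self, n_pop: int) -> np.ndarray:
        """Broadcast ``eta_bar`` to a length-``n_pop`` vector."""
        eta = np.asarray(self.eta_bar, dtype=float)
        if eta.ndim == 0:
            return np.full(n_pop, float(eta))
        if eta.shape != (n_pop,):
            raise ValueError(
                f"eta_bar has length {eta.shape}, expected ({n_pop},)"
            )
        return eta.copy()


@dataclass
class StimulusProtocol:
    """Rectangular current pulse delivered to a set of populations.

    The pulse has amplitude ``amplitude`` on ``targets`` for
    ``t_on <= t < t_on + duration`` and is zero elsewhere.  Defaults follow
    the standard perturbation experiment: amplitude 10, duration 400 ms.
    """

    targets: tuple[int, ...]
    amplitude: float = 10.0
    t_on: float = 0.0
    duration: float = 400.0

    def __post_init__(self) -> None:
        self.targets = tuple(int(t) for t in np.atleast_1d(self.targets))
        if len(self.targets) == 0:
            raise ValueError("stimulus must target at least one population")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be >= 0")
        if not (self.duration > 0):
            raise ValueError("stimulus duration must be positive")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration

    def validate_targets(self, n_pop: int) -> None:
        if any(t < 0 or t >= n_pop for t in self.targets):
            raise ValueError(
                f"stimulus targets {self.targets} out of range [0, {n_pop})"
            )


@dataclass
class QIFParams:
    """Parameters of the finite-N microscopic QIF network.

    The network is all-to-all coupled without autapses; each presynaptic
    spike increments every other membrane potential by J/N.  The infinite
    spike threshold of the ideal QIF neuron is replaced by a finite
    ``V_peak`` (reset at -V_peak) with a refractory hold of
    2*tau_m/V_peak ms that accounts for the time the ideal neuron spends
    beyond +/-V_peak.
    """

    N: int
    eta_samples: np.ndarray
    J: float = 0.0
    tau_m: float = 20.0
    V_peak: float = 100.0
    dt: float = 0.01
    I_B: float = 0.0
    refractory: bool = True
    seed: int | None = None
    V0: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (self.V_peak > 0):
            raise ValueError("V_peak must be positive")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        self.eta_samples = np.asarray(self.eta_samples, dtype=float)
        if self.eta_samples.shape != (self.N,):
            raise ValueError(
                f"eta_samples has shape {self.eta_samples.shape}, "
                f"expected ({self.N},)"
            )
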