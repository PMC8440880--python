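"""Equilibria and linear stability of the single-population neural mass.

Setting the rate equation to zero gives v* = -delta/(2 pi tau_m r*); after
substitution the voltage equation reduces to a quartic in the rate r,

    -pi^2 tau_m^2 r^4 + J_self tau_m r^3 + (eta_bar + I) r^2
        + delta^2 / (4 pi^2 tau_m^2) = 0,

whose positive real roots are the population equilibria.  For recurrent
excitation strong enough (e.g. J_self = 20) the system is bistable in an
eta_bar window, with a low-activity (LA) stable node, a saddle, and a
high-activity (HA) stable focus that is approached via damped oscillations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixedPoint",
    "single_fixed_points",
    "classify_fixed_point",
    "single_phase_diagram",
]

#: labels assigned from the eigenvalues of the 2x2 Jacobian
STABILITY_LABELS = (
    "stable_node",
    "stable_focus",
    "saddle",
    "unstable_node",
    "unstable_focus",
    "degenerate",
)

_IMAG_TOL = 1e-9
_REAL_PART_TOL = 1e-12


@dataclass(frozen=True)
class FixedPoint:
    """One equilibrium of the single-population system."""

    r_star: float
    v_star: float
    eigenvalues: tuple[complex, complex]
    stability: str
    degenerate: bool = False


def _jacobian(r: float, v: float, tau_m: float, J_self: float) -> np.ndarray:
    """Jacobian of (dr/dt, dv/dt) at (r, v)."""
    return np.array(
        [
            [2.0 * v / tau_m, 2.0 * r / tau_m],
            [-2.0 * np.pi**2 * tau_m * r + J_self, 2.0 * v / tau_m],
        ]
    )


def _label_from_eigenvalues(ev: np.ndarray) -> str:
    re = ev.real
    if np.any(np.abs(re) < _REAL_PART_TOL):
        return "degenerate"
    if np.max(np.abs(ev.imag)) > _IMAG_TOL:
        return "stable_focus" if np.all(re < 0) else "unstable_focus"
    if re[0] * re[1] < 0:
        return "saddle"
    return "stable_node" if np.all(re < 0) else "unstable_node"


def single_fixed_points(
    eta_bar: float,
    delta: float = 1.0,
    tau_m: float = 20.0,
    J_self: float = 0.0,
    I: float = 0.0,
) -> list[FixedPoint]:
    """All equilibria (r*, v*) of one population, sorted by r* ascending.

    The quartic is solved via its companion matrix; roots with
    ``|imag| < 1e-9`` and ``r > 1e-12`` are accepted.  For ``delta > 0``
    there is always at least one admissible root and at most three.
    """
    if not (delta > 0):
        raise ValueError("delta must be positive")
    coeffs = np.array(
        [
            -(np.pi**2) * tau_m**2,
            J_self * tau_m,
            eta_bar + I,
            0.0,
            delta**2 / (4.0 * np.pi**2 * tau_m**2),
        ]
    )
    roots = np.roots(coeffs)
    real_roots = np.sort(
        roots[(np.abs(roots.imag) < _IMAG_TOL) & (roots.real > 1e-12)].real
    )
    # near a saddle-node bifurcation two roots collide; flag near-double roots
    degenerate_pair = np.zeros(real_roots.size, dtype=bool)
    if real_roots.size > 1:
        gaps = np.diff(real_roots)
        close = gaps < 1e-8 * max(1.0, real_roots.max())
        degenerate_pair[:-1] |= close
        degenerate_pair[1:] |= close

    out = []
    for rr, dg in zip(real_roots, degenerate_pair):
        vv = -delta / (2.0 * np.pi * tau_m * rr)
        ev = np.linalg.eigvals(_jacobian(rr, vv, tau_m, J_self))
        out.append(
            FixedPoint(
                r_star=float(rr),
                v_star=float(vv),
                eigenvalues=(complex(ev[0]), complex(ev[1])),
                stability=_label_from_eigenvalues(ev),
                degenerate=bool(dg),
            )
        )
    return out


def classify_fixed_point(
    fp: FixedPoint,
    tau_m: float = 20.0,
    J_self: float = 0.0,
    delta: float = 1.0,
    eta_bar: float | None = None,
    I: float = 0.0,
    rhs_tol: float = 1e-8,
) -> str:
    """Stability label of an equilibrium from its Jacobian eigenvalues.

    If ``eta_bar`` is given, the point is first checked to actually zero the
    right-hand side (precondition of the classification).
    """
    if eta_bar is not None:
        from .model import single_rhs
        from .params import NeuralMassParams

        p = NeuralMassParams(tau_m=tau_m, delta=delta, eta_bar=eta_bar)
        dr, dv = single_rhs(fp.r_star, fp.v_star, p, J_self=J_self, I_ext=I)
        if max(abs(dr), abs(dv)) > rhs_tol:
            raise ValueError(
                "point does not satisfy the equilibrium condition "
                f"(|rhs| = {max(abs(dr), abs(dv)):.3e})"
            )
    ev = np.linalg.eigvals(_jacobian(fp.r_star, fp.v_star, tau_m, J_self))
    return _label_from_eigenvalues(ev)


def single_phase_diagram(
    eta_grid: np.ndarray,
    J_grid: np.ndarray,
    delta: float = 1.0,
    tau_m: float = 20.0,
) -> np.ndarray:
    """Regime label per (J, eta_bar) grid cell.

    Returns an array of shape ``(len(J_grid), len(eta_grid))`` of strings in
    {"LA_only", "HA_focus_only", "bistable", "boundary"}.  A cell is
    "bistable" when three equilibria coexist.  A single equilibrium is
    labelled high-activity when it is an *underdamped* focus
    (|Im lambda| > |Re lambda|, i.e. the damped oscillations that mark the
    high-activity state are visible); low-rate equilibria at weak coupling
    are formally foci with negligible imaginary parts and belong to the
    low-activity region.  Cells containing a degenerate (zero real-part or
    double-root) equilibrium are flagged "boundary".
    """

    def _is_ha(fp: FixedPoint) -> bool:
        ev = fp.eigenvalues[0]
        return fp.stability.endswith("focus") and abs(ev.imag) > abs(ev.real)

    eta_grid = np.asarray(eta_grid, dtype=float)
    J_grid = np.asarray(J_grid, dtype=float)
    labels = np.empty((J_grid.size, eta_grid.size), dtype=object)
    for a, J in enumerate(J_grid):
        for b, eta in enumerate(eta_grid):
            fps = single_fixed_points(eta, delta=delta, tau_m=tau_m, J_self=J)
            if any(f.degenerate or f.stability == "degenerate" for f in fps):
                labels[a, b] = "boundary"
            elif len(fps) >= 3:
                labels[a, b] = "bistable"
            elif _is_ha(fps[0]):
                labels[a, b] = "HA_focus_only"
            else:
                labels[a, b] = "LA_only"
    return labels
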