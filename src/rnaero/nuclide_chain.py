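"""Decay constants and Bateman ingrowth for the short-lived ²²²Rn chain.

The chain treated here is

    ²²²Rn (α, 3.82 d) → ²¹⁸Po (α, 3.05 min) → ²¹⁴Pb (β/γ, 26.8 min)
        → ²¹⁴Bi (β/γ, 19.7 min) → ²¹⁴Po (α, 164 µs)

²¹⁴Po is never integrated as a state variable: its 164 µs half-life keeps
it in secular equilibrium with ²¹⁴Bi, so its activity is reported as an
alias of the ²¹⁴Bi activity.

Unit conventions used throughout the package: activity concentrations in
Bq m⁻³, atom number concentrations in cm⁻³, time grids in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Nuclide",
    "ChainTrajectory",
    "RN222",
    "PO218",
    "PB214",
    "BI214",
    "PO214",
    "CHAIN",
    "decay_constant",
    "activity_to_number",
    "number_to_activity",
    "bateman_ingrowth",
]

LN2 = math.log(2.0)

#: seconds per unit for the accepted explicit time units
_TIME_UNITS = {"s": 1.0, "min": 60.0, "h": 3600.0, "d": 86400.0}

# Alpha-particle energies (MeV) from standard nuclear data; the potential
# alpha energy of an airborne atom counts every alpha it and its short-lived
# descendants down to Po-214 will emit (beta/gamma energy is not counted).
E_ALPHA_PO218 = 6.00
E_ALPHA_PO214 = 7.69
E_ALPHA_RN222 = 5.49


class InvalidInputError(ValueError):
    """Raised when a physical precondition (sign, unit, ordering) fails."""


def decay_constant(t_half: float, unit: str) -> float:
    """Radioactive-transformation rate constant λ = ln 2 / t_half in s⁻¹.

    Parameters
    ----------
    t_half : half-life, strictly positive.
    unit : one of ``"s"``, ``"min"``, ``"h"``, ``"d"``. The unit is
        mandatory — a bare number has no decay constant.
    """
    if unit not in _TIME_UNITS:
        raise InvalidInputError(
            f"half-life unit must be one of {sorted(_TIME_UNITS)}, got {unit!r}"
        )
    if not (t_half > 0):
        raise InvalidInputError(f"half-life must be positive, got {t_half!r}")
    return LN2 / (t_half * _TIME_UNITS[unit])


@dataclass(frozen=True)
class Nuclide:
    """One member of the decay chain.

    ``e_alpha_potential`` is the potential alpha energy per atom (MeV): the
    alpha energy this atom and all its short-lived descendants down to
    ²¹⁴Po will eventually emit.
    """

    name: str
    t_half: float
    t_half_unit: str
    e_alpha_potential: float
    lam: float = field(init=False)

    def __post_init__(self) -> None:
        if self.e_alpha_potential < 0:
            raise InvalidInputError("potential alpha energy must be >= 0")
        object.__setattr__(self, "lam", decay_constant(self.t_half, self.t_half_unit))


RN222 = Nuclide("Rn-222", 3.82, "d", E_ALPHA_RN222 + E_ALPHA_PO218 + E_ALPHA_PO214)
PO218 = Nuclide("Po-218", 3.05, "min", E_ALPHA_PO218 + E_ALPHA_PO214)
PB214 = Nuclide("Pb-214", 26.8, "min", E_ALPHA_PO214)
BI214 = Nuclide("Bi-214", 19.7, "min", E_ALPHA_PO214)
PO214 = Nuclide("Po-214", 164e-6, "s", E_ALPHA_PO214)

#: serial chain actually integrated (Po-214 aliased to Bi-214)
CHAIN: tuple[Nuclide, ...] = (RN222, PO218, PB214, BI214)

#: m⁻³ per cm⁻³
_M3_PER_CM3 = 1.0e6


def activity_to_number(c_activity: float, nuclide: Nuclide) -> float:
    """Convert activity concentration (Bq m⁻³) to atoms cm⁻³.

    Radioactivity law C^A = λ C^N: one Bq m⁻³ corresponds to 1/λ atoms per
    m³, i.e. 1/(λ · 10⁶) atoms per cm³.
    """
    if c_activity < 0:
        raise InvalidInputError(f"activity must be >= 0, got {c_activity}")
    return c_activity / nuclide.lam / _M3_PER_CM3


def number_to_activity(c_number: float, nuclide: Nuclide) -> float:
    """Convert atoms cm⁻³ back to activity concentration Bq m⁻³."""
    if c_number < 0:
        raise InvalidInputError(f"number concentration must be >= 0, got {c_number}")
    return c_number * nuclide.lam * _M3_PER_CM3


@dataclass
class ChainTrajectory:
    """Activity and atom-number series of the chain on a common time grid.

    ``activity`` maps nuclide name -> Bq m⁻³ array; ``number`` maps
    nuclide name -> atoms cm⁻³ array.  ``Po-214`` appears in ``activity``
    only, tied to ``Bi-214``.
    """

    times: np.ndarray
    activity: dict[str, np.ndarray]
    number: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        """Flat table: time_s, A_* (Bq m⁻³), N_* (cm⁻³)."""
        cols: dict[str, np.ndarray] = {"time_s": self.times}
        for nuc in ("Rn-222", "Po-218", "Pb-214", "Bi-214", "Po-214"):
            cols[f"A_{nuc.replace('-', '')}"] = self.activity[nuc]
        for nuc in ("Rn-222", "Po-218", "Pb-214", "Bi-214"):
            cols[f"N_{nuc.replace('-', '')}"] = self.number[nuc]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bateman_numbers(n0: np.ndarray, lams: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Atom numbers of a serial chain at times t for initial numbers n0.

    Classic Bateman solution; falls back to ODE integration if any pair of
    decay constants is nearly degenerate (the analytic product formula
    divides by λ_j − λ_i).
    """
    k = len(lams)
    rel = np.abs(lams[:, None] - lams[None, :]) / np.maximum(lams[:, None], lams[None, :])
    degenerate = np.any(rel[~np.eye(k, dtype=bool)] < 1e-9)
    if degenerate:
        return _ode_numbers(n0, lams, t)

    out = np.zeros((k, len(t)))
    # superpose the solution for each initially present ancestor
    for start in range(k):
        if n0[start] == 0:
            continue
        for i in range(start, k):
            sub = lams[start : i + 1]
            coeff = np.prod(sub[:-1]) if len(sub) > 1 else 1.0
            acc = np.zeros(len(t))
            for j, lj in enumerate(sub):
                denom = np.prod(np.delete(sub, j) - lj) if len(sub) > 1 else 1.0
                acc += np.exp(-lj * t) / denom if len(sub) > 1 else np.exp(-lj * t)
            if i > start:
                acc[t == 0.0] = 0.0  # descendants absent at t=0; kill round-off
            out[i] += n0[start] * coeff * acc
    return out


def _ode_numbers(n0: np.ndarray, lams: np.ndarray, t: np.ndarray) -> np.ndarray:
    def rhs(_t, n):
        dn = -lams * n
        dn[1:] += lams[:-1] * n[:-1]
        return dn

    t_end = float(t[-1]) if len(t) > 1 else max(float(t[0]), 1.0)
    sol = solve_ivp(rhs, (0.0, t_end), n0, t_eval=t, rtol=1e-10, atol=1e-20,
                    method="LSODA")
    return sol.y


def bateman_ingrowth(c_rn0: float, times: np.ndarray) -> ChainTrajectory:
    """Ingrowth of ²¹⁸Po, ²¹⁴Pb, ²¹⁴Bi(/²¹⁴Po) from pure radon, no removal.

    Parameters
    ----------
    c_rn0 : initial radon activity concentration, Bq m⁻³; progeny start at
        zero (closed system).
    times : sorted grid of seconds starting at 0.
    """
    times = np.asarray(times, dtype=float)
    if c_rn0 < 0:
        raise InvalidInputError("initial radon activity must be >= 0")
    if times.ndim != 1 or len(times) == 0:
        raise InvalidInputError("times must be a non-empty 1-D grid")
    if times[0] != 0 or np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise InvalidInputError("times must be sorted, non-negative, starting at 0")

    lams = np.array([n.lam for n in CHAIN])
    n0 = np.zeros(len(CHAIN))
    n0[0] = activity_to_number(c_rn0, RN222)  # cm⁻³; linear system, unit carries through
    numbers = _bateman_numbers(n0, lams, times)

    number = {nuc.name: numbers[i] for i, nuc in enumerate(CHAIN)}
    activity = {
        nuc.name: numbers[i] * nuc.lam * _M3_PER_CM3 for i, nuc in enumerate(CHAIN)
    }
    activity["Po-214"] = activity["Bi-214"].copy()  # secular tie at 164 µs
    return ChainTrajectory(times=times, activity=activity, number=number)
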