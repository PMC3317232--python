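"""Forward model and inversion of a two-detector gross-alpha progeny monitor.

The instrument pumps air for a few minutes over a wire screen that strips
the sub-5-nm (unattached) activity onto one detector and passes the
aerosol-attached activity onto a filter over a second detector.  Each
detector then counts gross alpha decays in three consecutive intervals
within 110 minutes after sampling; because the expected counts in each
interval are linear in the three airborne activity concentrations
(²¹⁸Po, ²¹⁴Pb, ²¹⁴Bi), the per-nuclide activities follow from a 3×3
linear solve.  The interval deconvolution implemented here is a linear
least-squares reconstruction built on the exact decay kinetics of the
deposited atoms; the original instrument firmware uses a proprietary
estimator, so this stage is a documented, self-consistent stand-in rather
than a replica.

Deposition during the pumping phase is modelled as continuous collection
with simultaneous decay/ingrowth on the filter, not as an instantaneous
deposit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .nuclide_chain import BI214, PB214, PO218, InvalidInputError

__all__ = [
    "CountingSchedule",
    "AlphaCounts",
    "InversionResult",
    "forward_counts",
    "design_matrix",
    "invert_counts",
]

_LAMS = np.array([PO218.lam, PB214.lam, BI214.lam])  # s⁻¹, filter chain order


class ConfigurationError(ValueError):
    """Invalid counting schedule."""


class InversionError(ValueError):
    """Singular or degenerate design matrix."""


@dataclass(frozen=True)
class CountingSchedule:
    """Sampling and counting geometry of the monitor.

    ``intervals`` are (start, end) pairs in seconds measured from the end
    of pumping; they must be ordered, non-overlapping and lie within the
    110-minute counting window.
    """

    sampling_duration_s: float = 6 * 60.0
    flow_m3_per_s: float = 2.4e-3 / 60.0          # 2.4 dm³ min⁻¹
    screen_cutoff_nm: float = 5.0
    intervals: tuple[tuple[float, float], ...] = (
        (0.0, 30 * 60.0),
        (30 * 60.0, 70 * 60.0),
        (70 * 60.0, 110 * 60.0),
    )
    efficiency: float = 0.25
    detector_area_mm2: float = 150.0
    window_s: float = 110 * 60.0

    def __post_init__(self) -> None:
        if self.flow_m3_per_s <= 0 or self.sampling_duration_s <= 0:
            raise ConfigurationError("flow and sampling duration must be positive")
        if not (0 < self.efficiency <= 1):
            raise ConfigurationError("efficiency must lie in (0, 1]")
        prev_end = 0.0
        for (t1, t2) in self.intervals:
            if not (0 <= t1 < t2 <= self.window_s):
                raise ConfigurationError(f"interval ({t1}, {t2}) outside counting window")
            if t1 < prev_end:
                raise ConfigurationError("intervals must be ordered and non-overlapping")
            prev_end = t2


@dataclass
class AlphaCounts:
    """Counts per interval for the unattached-screen and attached-filter
    detectors. Integer-valued when Poisson noise has been applied."""

    unattached: np.ndarray
    attached: np.ndarray
    poisson: bool = False

    def to_frame(self, sched: CountingSchedule) -> pd.DataFrame:
        rows = []
        for det, counts in (("unattached", self.unattached), ("attached", self.attached)):
            for i, ((t1, t2), c) in enumerate(zip(sched.intervals, counts)):
                rows.append({"detector": det, "interval_index": i,
                             "t_start_s": t1, "t_end_s": t2, "counts": c})
        return pd.DataFrame(rows)


def _decay_matrix() -> np.ndarray:
    m = np.diag(-_LAMS)
    m[1, 0] = _LAMS[0]
    m[2, 1] = _LAMS[1]
    return m


def _deposited_atoms(activities: np.ndarray, sched: CountingSchedule) -> np.ndarray:
    """Atoms of each nuclide on the filter at the end of pumping.

    Collection is a constant source s_i = (A_i/λ_i)·Q atoms s⁻¹ feeding the
    filter chain dN/dt = M N + s, solved exactly via the matrix exponential.
    """
    m = _decay_matrix()
    s = activities / _LAMS * sched.flow_m3_per_s  # atoms per second onto filter
    t = sched.sampling_duration_s
    em = expm(m * t)
    # filter starts clean: N(T) = M⁻¹(e^{MT} − I)s
    return np.linalg.solve(m, (em - np.eye(3)) @ s)


def _interval_alpha_integral(n0: np.ndarray, t1: float, t2: float) -> float:
    """∫ (λ_Po218·N_Po218 + λ_Bi214·N_Bi214) dt over [t1, t2] of free decay.

    The ²¹⁴Po alpha rate is tied to the ²¹⁴Bi decay rate. Uses
    ∫N dt = M⁻¹(N(t2) − N(t1)), exact for the linear decay system.
    """
    m = _decay_matrix()
    n_t1 = expm(m * t1) @ n0
    n_t2 = expm(m * t2) @ n0
    integral = np.linalg.solve(m, n_t2 - n_t1)
    return float(_LAMS[0] * integral[0] + _LAMS[2] * integral[2])


def forward_counts(activities: np.ndarray, sched: CountingSchedule) -> np.ndarray:
    """Expected alpha counts per interval for one detector/fraction.

    ``activities`` holds the airborne (²¹⁸Po, ²¹⁴Pb, ²¹⁴Bi) activity
    concentrations in Bq m⁻³ for the fraction this detector collects.
    """
    activities = np.asarray(activities, dtype=float)
    if activities.shape != (3,):
        raise InvalidInputError("expected three per-nuclide activities")
    if np.any(activities < 0):
        raise InvalidInputError("activities must be >= 0")
    n0 = _deposited_atoms(activities, sched)
    return np.array([
        sched.efficiency * _interval_alpha_integral(n0, t1, t2)
        for (t1, t2) in sched.intervals
    ])


def design_matrix(sched: CountingSchedule) -> np.ndarray:
    """Counts-per-unit-activity matrix D with counts = D @ activities."""
    cols = [forward_counts(np.eye(3)[j], sched) for j in range(3)]
    return np.column_stack(cols)


@dataclass
class InversionResult:
    activities: np.ndarray          # Bq m⁻³, order Po-218, Pb-214, Bi-214
    sigma: np.ndarray               # 1-σ uncertainties from Poisson statistics
    clipped: bool                   # True if negative solutions were zeroed
    condition_number: float


def invert_counts(counts: np.ndarray, sched: CountingSchedule) -> InversionResult:
    """Recover per-nuclide activities from one detector's interval counts.

    Solves the square linear system counts = D·A exactly; with Poisson
    noise this coincides with the weighted least-squares estimate. The
    reported 1-σ uncertainties propagate Var(counts) = counts through D⁻¹.
    Negative estimates (possible under noise) are clipped to zero and
    flagged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(sched.intervals),):
        raise InvalidInputError("counts shape does not match schedule intervals")
    d = design_matrix(sched)
    cond = float(np.linalg.cond(d))
    if not np.isfinite(cond) or cond > 1e12:
        raise InversionError(f"design matrix singular (cond={cond:.3g}); "
                             "intervals give no contrast")
    a = np.linalg.solve(d, counts)
    d_inv = np.linalg.inv(d)
    var = d_inv @ np.diag(np.maximum(counts, 0.0)) @ d_inv.T
    sigma = np.sqrt(np.clip(np.diag(var), 0.0, None))
    clipped = bool(np.any(a < 0))
    return InversionResult(activities=np.clip(a, 0.0, None), sigma=sigma,
                           clipped=clipped, condition_number=cond)


def apply_poisson(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw integer counts from the expected values."""
    return rng.poisson(np.asarray(expected, dtype=float)).astype(float)
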