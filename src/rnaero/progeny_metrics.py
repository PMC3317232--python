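"""Scalar exposure metrics for short-lived radon decay products (RnDP).

Implements the standard radiometric bookkeeping used in indoor-radon
studies: equilibrium equivalent concentration (EEC), equilibrium factor F,
potential alpha-energy concentration E_α, unattached activity fraction
f_un and its atom-number analogue x_un, the empirical dosimetric
dose-conversion factor, working-level-month (WLM) exposure, and the
classical inverse f_un–aerosol-concentration predictor.

All activity concentrations are in Bq m⁻³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nuclide_chain import BI214, PB214, PO218, InvalidInputError

__all__ = [
    "ProgenyRecord",
    "ProgenyMetrics",
    "EEC_WEIGHTS",
    "E_ALPHA_COEFFS",
    "E_ALPHA_BI214_PRINTED",
    "WLM_REFERENCE_MEV_M3",
    "WLM_REFERENCE_HOURS",
    "DCF_CONVENTIONAL_HOME",
    "DCF_CONVENTIONAL_WORK",
    "eec",
    "equilibrium_factor",
    "potential_alpha_energy",
    "unattached_fractions",
    "dose_conversion_empirical",
    "exposure_wlm",
    "predicted_fun",
]

#: EEC weights for (²¹⁸Po, ²¹⁴Pb, ²¹⁴Bi); ²¹⁴Po is folded into the Bi term.
EEC_WEIGHTS = (0.1065, 0.515, 0.379)

#: Potential alpha-energy coefficients, MeV m⁻³ per Bq m⁻³ of each nuclide.
#: The ²¹⁴Bi coefficient is 13120 by internal consistency with the EEC
#: weights (3690/34640 = 0.1065, 17830/34640 ≈ 0.515, 13120/34640 ≈ 0.379);
#: a widely reprinted variant carries 113120, selectable but flagged.
E_ALPHA_COEFFS = (3690.0, 17830.0, 13120.0)
E_ALPHA_BI214_PRINTED = 113120.0

#: 1 WLM = 170 h of breathing air at E_α = 1.3e8 MeV m⁻³
WLM_REFERENCE_MEV_M3 = 1.3e8
WLM_REFERENCE_HOURS = 170.0

#: ICRP-65 conventional dose conversion factors, mSv per WLM
DCF_CONVENTIONAL_HOME = 4.0
DCF_CONVENTIONAL_WORK = 5.0


class UndefinedMetricError(ValueError):
    """A ratio metric is undefined for this input (e.g. zero denominator)."""


def _check_nonneg(*vals: float) -> None:
    for v in vals:
        if v < 0:
            raise InvalidInputError(f"activity concentrations must be >= 0, got {v}")


def eec(c_po218: float, c_pb214: float, c_bi214: float) -> float:
    """Equilibrium equivalent concentration of RnDP, Bq m⁻³.

    Weighted mixture 0.1065·C(²¹⁸Po) + 0.515·C(²¹⁴Pb) + 0.379·C(²¹⁴Bi);
    the weights are the fractional contributions of each nuclide to the
    potential alpha energy of an equilibrium mixture.
    """
    _check_nonneg(c_po218, c_pb214, c_bi214)
    w = EEC_WEIGHTS
    return w[0] * c_po218 + w[1] * c_pb214 + w[2] * c_bi214


def equilibrium_factor(eec_value: float, c_rn: float) -> float:
    """Equilibrium factor F = EEC / C_Rn (1 at secular equilibrium)."""
    _check_nonneg(eec_value)
    if c_rn <= 0:
        raise UndefinedMetricError("equilibrium factor undefined for C_Rn <= 0")
    return eec_value / c_rn


def potential_alpha_energy(
    c_po218: float,
    c_pb214: float,
    c_bi214: float,
    *,
    bi214_coefficient: float = E_ALPHA_COEFFS[2],
) -> float:
    """Potential alpha-energy concentration E_α, MeV m⁻³."""
    _check_nonneg(c_po218, c_pb214, c_bi214)
    if bi214_coefficient == E_ALPHA_BI214_PRINTED:
        warnings.warn(
            "using the 113120 Bi-214 coefficient, which is inconsistent "
            "with the EEC weights by a factor ~10; 13120 is the "
            "self-consistent value",
            stacklevel=2,
        )
    return E_ALPHA_COEFFS[0] * c_po218 + E_ALPHA_COEFFS[1] * c_pb214 + bi214_coefficient * c_bi214


@dataclass(frozen=True)
class ProgenyRecord:
    """One progeny-monitor observation: radon plus per-nuclide activities
    split into unattached (molecular-cluster, <~5 nm) and attached
    (aerosol-borne) fractions, all in Bq m⁻³."""

    timestamp: pd.Timestamp
    c_rn: float
    c_po218_un: float
    c_pb214_un: float
    c_bi214_un: float
    c_po218_att: float
    c_pb214_att: float
    c_bi214_att: float
    temperature: Optional[float] = None
    rel_humidity: Optional[float] = None

    def __post_init__(self) -> None:
        _check_nonneg(
            self.c_rn,
            self.c_po218_un, self.c_pb214_un, self.c_bi214_un,
            self.c_po218_att, self.c_pb214_att, self.c_bi214_att,
        )

    @property
    def totals(self) -> tuple[float, float, float]:
        """Per-nuclide total (unattached + attached) activities."""
        return (
            self.c_po218_un + self.c_po218_att,
            self.c_pb214_un + self.c_pb214_att,
            self.c_bi214_un + self.c_bi214_att,
        )


@dataclass(frozen=True)
class ProgenyMetrics:
    """Derived exposure metrics for one :class:`ProgenyRecord`."""

    eec: float            # Bq m⁻³
    eec_un: float         # Bq m⁻³, unattached part only
    f_factor: float       # equilibrium factor, dimensionless
    f_un: float           # unattached activity fraction
    x_un: float           # unattached atom-number fraction
    e_alpha: float        # MeV m⁻³
    dcf: float            # mSv WLM⁻¹, empirical dosimetric value


def unattached_fractions(rec: ProgenyRecord) -> tuple[float, float]:
    """Unattached activity fraction f_un and number fraction x_un.

    f_un is the EEC of the unattached nuclides over the EEC of the totals.
    x_un is the ratio of unattached atom numbers to all airborne progeny
    atoms, with atoms obtained from activities via N = C/λ (the shared
    unit factor cancels).
    """
    un = (rec.c_po218_un, rec.c_pb214_un, rec.c_bi214_un)
    att = (rec.c_po218_att, rec.c_pb214_att, rec.c_bi214_att)
    eec_tot = eec(*(u + a for u, a in zip(un, att)))
    if eec_tot == 0:
        raise UndefinedMetricError("all progeny activities are zero; f_un undefined")
    f_un = eec(*un) / eec_tot

    lams = (PO218.lam, PB214.lam, BI214.lam)
    n_un = sum(a / lam for a, lam in zip(un, lams))
    n_att = sum(a / lam for a, lam in zip(att, lams))
    if n_un + n_att == 0:
        raise UndefinedMetricError("all progeny activities are zero; x_un undefined")
    return f_un, n_un / (n_un + n_att)


def dose_conversion_empirical(f_un: float) -> float:
    """Dosimetric dose-conversion factor D_CF = 11.35 + 43·f_un, mSv WLM⁻¹."""
    if not (0.0 <= f_un <= 1.0):
        raise InvalidInputError(f"f_un must lie in [0, 1], got {f_un}")
    return 11.35 + 43.0 * f_un


def derive_metrics(rec: ProgenyRecord) -> ProgenyMetrics:
    """All derived metrics for a single record."""
    tot = rec.totals
    eec_tot = eec(*tot)
    f_un, x_un = unattached_fractions(rec)
    return ProgenyMetrics(
        eec=eec_tot,
        eec_un=eec(rec.c_po218_un, rec.c_pb214_un, rec.c_bi214_un),
        f_factor=equilibrium_factor(eec_tot, rec.c_rn),
        f_un=f_un,
        x_un=x_un,
        e_alpha=potential_alpha_energy(*tot),
        dcf=dose_conversion_empirical(f_un),
    )


def exposure_wlm(e_alpha: Sequence[float], duration_h: Sequence[float] | float) -> float:
    """Cumulative exposure in working-level-months.

    Time-integral of the potential alpha-energy concentration divided by
    the WLM reference integral (170 h at 1.3·10⁸ MeV m⁻³). ``duration_h``
    is the dwell time of each sample in hours (scalar broadcast allowed).
    """
    e = np.asarray(e_alpha, dtype=float)
    if e.size == 0:
        raise InvalidInputError("empty E_alpha series")
    d = np.broadcast_to(np.asarray(duration_h, dtype=float), e.shape)
    if np.any(e < 0) or np.any(d <= 0):
        raise InvalidInputError("E_alpha must be >= 0 and durations > 0")
    return float(np.sum(e * d) / (WLM_REFERENCE_HOURS * WLM_REFERENCE_MEV_M3))


def effective_dose(wlm: float, dcf: float) -> float:
    """Effective dose in mSv for a given exposure and conversion factor."""
    return wlm * dcf


def predicted_fun(c_tot: float) -> float:
    """Classical inverse predictor f_un ≈ 400 / C_tot (C_tot in cm⁻³).

    Exposed as a diagnostic only: the pipeline compares it with measured
    f_un rather than substituting it. Capped at 1 since f_un is a fraction.
    """
    if c_tot <= 0:
        raise InvalidInputError(f"total concentration must be > 0, got {c_tot}")
    return min(400.0 / c_tot, 1.0)
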