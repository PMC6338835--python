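"""Repeated photoswitching cycles and correction of cycle-dependent rate drift.

The donor's off-switching rate creeps up slowly with the number of on-off
cycles it has undergone, independent of whether an acceptor is attached and
by approximately the same absolute amount per cycle for the donor-alone
control and the FRET construct.  Left uncorrected, that drift masquerades as
a slow loss of FRET over a time-lapse experiment.  The fix is empirical: fit
a line to the donor-only control's rate-vs-cycle series and subtract the
fitted slope, anchored to cycle 1, from every measured rate.

The control must be the same donor chimera without the acceptor — local
environment can change photoswitching, so only a matched control isolates
the cycle effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .fretcalc import FretMeasurement, efd_from_rates

__all__ = ["CycleSeries", "DriftModel", "estimate_drift", "correct_rates", "efd_series"]


@dataclass
class CycleSeries:
    """Fitted off-switching rate constants over repeated cycles."""

    cycles: np.ndarray
    k: np.ndarray
    construct: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.k = np.asarray(self.k, dtype=float)
        if self.cycles.shape != self.k.shape or self.cycles.ndim != 1:
            raise ValueError("cycles and k must be matching 1-D vectors")
        if self.cycles.size and not np.all(np.diff(self.cycles) > 0):
            raise ValueError("cycle indices must be strictly increasing")

    @property
    def n(self) -> int:
        return self.cycles.size


@dataclass(frozen=True)
class DriftModel:
    """Linear rate-vs-cycle model ``k = intercept + slope * cycle``."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("drift model parameters must be finite")


def estimate_drift(control: CycleSeries) -> DriftModel:
    """Ordinary least-squares line through a donor-only control series."""
    if not control.is_control:
        raise ValueError("drift must be estimated from a donor-only control series")
    if control.n < 3:
        raise ValueError("need at least 3 cycles to estimate drift")
    if np.ptp(control.k) == 0:
        # flat series: OLS slope is exactly 0 and r^2 is undefined
        return DriftModel(slope=0.0, intercept=float(control.k[0]), r_squared=1.0)
    res = stats.linregress(control.cycles.astype(float), control.k)
    return DriftModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def correct_rates(series: CycleSeries, drift: DriftModel) -> CycleSeries:
    """Remove the control's drift slope, anchored at cycle 1.

    ``k_corr(c) = k(c) - slope * (c - 1)`` — additive, because the control
    and the FRET construct drift with similar absolute slopes despite
    different baseline rates; cycle 1 is the reference state and is left
    unchanged.
    """
    k_corr = series.k - drift.slope * (series.cycles - 1)
    return replace(series, k=k_corr)


def efd_series(
    donor_series: CycleSeries,
    da_series: CycleSeries,
    drift: DriftModel | None = None,
) -> list[FretMeasurement]:
    """Per-cycle donor-side efficiencies from paired rate series.

    When the donor control was measured concurrently (one control rate per
    cycle), each cycle's efficiency uses that cycle's control rate directly
    and no drift model is needed.  A single-cycle control is broadcast as a
    fixed reference, in which case passing ``drift`` (estimated from a
    separate donor-only run) corrects both series before the rate ratio.
    """
    if donor_series.n == 1:
        donor_k = np.full(da_series.n, donor_series.k[0])
        donor_cycles = da_series.cycles
    else:
        if donor_series.n != da_series.n or not np.array_equal(
            donor_series.cycles, da_series.cycles
        ):
            raise ValueError("donor and FRET series must cover the same cycles")
        donor_k = donor_series.k
        donor_cycles = donor_series.cycles

    da_k = da_series.k
    if drift is not None:
        da_k = da_k - drift.slope * (da_series.cycles - 1)
        if donor_series.n > 1:
            donor_k = donor_k - drift.slope * (donor_cycles - 1)

    return [
        efd_from_rates(float(k_da), float(k_d), cycle=int(c))
        for c, k_da, k_d in zip(da_series.cycles, da_k, donor_k)
    ]
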