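"""FRET efficiency estimators from photoswitching kinetics and intensities.

Four routes to an efficiency, all computable from the same photoswitching
dataset:

* rate ratio — ``EfD = 1 - k_DA / k_D``: energy transfer competes with
  off-switching, so the donor switches off more slowly next to an acceptor;
* acceptor photobleaching — ``EfD = (I_post - I_pre) / I_post`` from the
  donor signal before/after destroying the acceptor;
* sensitized emission — the FRET-channel signal with donor bleed-through and
  direct acceptor excitation removed (``Fc_on``), converted to ``EfD`` with a
  calibrated G factor;
* acceptor-side ``EfA`` — ``Fc_on`` relative to the directly excited
  acceptor signal, scaled by the donor/acceptor extinction ratio at the
  donor excitation wavelength.

The photoswitchable donor makes the sensitized-emission routes self-
contained: with the donor switched off (50-100x dimmer), the FRET channel
reads out the direct acceptor excitation in situ, so no acceptor-alone
control sample is needed.

Efficiencies here are occupancy-weighted: ``EfD = E*[DA]/[D_total]`` and
``EfA = E*[DA]/[A_total]``, i.e. the per-complex efficiency scaled by the
fraction of that side's population actually in complexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .decayfit import FitConfig, fit_single_exponential
from .iostacks import ImageStack, RoiMask, extract_trace

__all__ = [
    "CrossTalkFactors",
    "SensitizedSet",
    "GFactor",
    "ExtinctionPair",
    "FretMeasurement",
    "FcOn",
    "EPS_DONOR_DRONPA_488",
    "EPS_ACCEPTOR_MCHERRY_488",
    "efd_from_rates",
    "efd_acceptor_photobleach",
    "donor_bleedthrough_factor",
    "sensitized_emission",
    "calibrate_g",
    "efd_sensitized",
    "efa_sensitized",
    "measure_on_off_levels",
    "multi_acceptor_efficiency",
]

#: Extinction coefficients (mol^-1 cm^-1) of Dronpa and mCherry at 488 nm,
#: the donor excitation wavelength; defaults for the EfA excitability ratio.
EPS_DONOR_DRONPA_488 = 62_600.0
EPS_ACCEPTOR_MCHERRY_488 = 7_700.0


@dataclass(frozen=True)
class CrossTalkFactors:
    """Spectral cross-talk ratios for one optical configuration.

    ``d`` is donor bleed-through into the FRET channel (I_DA/I_DD measured on
    donor-alone samples).  ``a_opt`` is the classic direct-excitation factor
    (I_DA/I_AA from acceptor-alone samples); optional, because the on/off
    subtraction replaces it in the default pipeline.
    """

    d: float
    d_sd: float = 0.0
    a_opt: float | None = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("bleed-through factor d must be >= 0")
        if self.a_opt is not None and self.a_opt < 0:
            raise ValueError("direct-excitation factor a must be >= 0")


@dataclass
class SensitizedSet:
    """The intensity readouts feeding the sensitized-emission estimators.

    All values in photoelectrons and background-subtracted: ``i_dd_on`` is
    the donor-channel signal with the donor on, ``i_da_on``/``i_da_off`` the
    FRET-channel signal with the donor on/off, ``i_aa`` the optional
    acceptor-excitation acceptor signal.
    """

    i_dd_on: float
    i_da_on: float
    i_da_off: float
    i_aa: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = [self.i_dd_on, self.i_da_on, self.i_da_off]
        if self.i_aa is not None:
            vals.append(self.i_aa)
        if not np.all(np.isfinite(vals)):
            raise ValueError("sensitized-emission intensities must be finite")
        if self.i_da_off < 0:
            raise ValueError("off-state FRET-channel signal must be >= 0")


@dataclass(frozen=True)
class GFactor:
    """Ratio linking sensitized emission to the donor signal lost to FRET."""

    value: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("G factor must be positive")


@dataclass(frozen=True)
class ExtinctionPair:
    """Extinction coefficients at the donor excitation wavelength.

    ``donor_copies``/``acceptor_copies`` scale the coefficients for chimeras
    with known stoichiometry (e.g. two donors per complex doubles the
    effective donor excitability).  Scaling is explicit, never inferred.
    """

    eps_d: float = EPS_DONOR_DRONPA_488
    eps_a: float = EPS_ACCEPTOR_MCHERRY_488
    donor_copies: int = 1
    acceptor_copies: int = 1

    def __post_init__(self) -> None:
        if self.eps_d <= 0 or self.eps_a <= 0:
            raise ValueError("extinction coefficients must be positive")
        if self.donor_copies < 1 or self.acceptor_copies < 1:
            raise ValueError("copy numbers must be >= 1")

    @property
    def eps_d_eff(self) -> float:
        return self.eps_d * self.donor_copies

    @property
    def eps_a_eff(self) -> float:
        return self.eps_a * self.acceptor_copies


@dataclass(frozen=True)
class FretMeasurement:
    """A single FRET efficiency with its side, method and provenance."""

    value: float
    side: str  # "donor" (EfD) or "acceptor" (EfA)
    method: str  # rate_ratio | acceptor_pb | sensitized_D | sensitized_A
    cycle: int | None = None
    flags: tuple[str, ...] = ()

    _DONOR_METHODS = ("rate_ratio", "acceptor_pb", "sensitized_D")

    def __post_init__(self) -> None:
        if self.side not in ("donor", "acceptor"):
            raise ValueError("side must be 'donor' or 'acceptor'")
        if self.side == "acceptor" and self.method != "sensitized_A":
            raise ValueError("EfA is only produced by the sensitized_A method")
        if self.side == "donor" and self.method not in self._DONOR_METHODS:
            raise ValueError(f"unknown donor-side method {self.method!r}")


class FcOn(NamedTuple):
    """Sensitized-emission signal with a negativity flag (never clamped)."""

    value: float
    negative: bool


def efd_from_rates(k_da: float, k_d: float, cycle: int | None = None) -> FretMeasurement:
    """Donor-side efficiency from off-switching rates: ``1 - k_DA/k_D``.

    ``k_da`` is the rate with the acceptor present, ``k_d`` the matching
    donor-alone control rate under the same illumination.  A negative value
    (``k_da > k_d``) is reported and flagged, not suppressed — it usually
    signals a control/illumination mismatch worth seeing.
    """
    if not (k_d > 0 and k_da > 0):
        raise ValueError("rate constants must be positive")
    value = 1.0 - k_da / k_d
    flags = ("negative_efficiency",) if value < 0 else ()
    return FretMeasurement(value, "donor", "rate_ratio", cycle=cycle, flags=flags)


def efd_acceptor_photobleach(i_pre: float, i_post: float) -> FretMeasurement:
    """Donor de-quenching efficiency: ``(I_post - I_pre) / I_post``.

    ``i_pre``/``i_post`` are the donor signals in the first frame after
    photoswitching on, before and after acceptor photobleaching.
    """
    if i_post <= 0:
        raise ValueError("post-bleach intensity must be positive")
    value = (i_post - i_pre) / i_post
    flags = ("negative_efficiency",) if value < 0 else ()
    return FretMeasurement(value, "donor", "acceptor_pb", flags=flags)


def donor_bleedthrough_factor(donor_alone: Sequence[SensitizedSet]) -> CrossTalkFactors:
    """Bleed-through ratio d from donor-alone measurements.

    Per measurement ``d_i = (I_DA_on - I_DA_off) / I_DD_on``; the residual
    FRET-channel signal with the donor off is subtracted first, since even a
    donor-alone sample leaves a small off-state floor there.  Returns the
    mean across measurements with the sample SD.
    """
    if len(donor_alone) == 0:
        raise ValueError("need at least one donor-alone measurement")
    ds = []
    for s in donor_alone:
        if s.i_dd_on <= 0:
            raise ValueError("donor-alone I_DD_on must be positive")
        ds.append((s.i_da_on - s.i_da_off) / s.i_dd_on)
    ds = np.asarray(ds)
    sd = float(ds.std(ddof=1)) if ds.size > 1 else 0.0
    return CrossTalkFactors(d=float(ds.mean()), d_sd=sd)


def sensitized_emission(s: SensitizedSet, ct: CrossTalkFactors) -> FcOn:
    """Cross-talk-free sensitized emission: ``Fc_on = I_DA_on - I_DA_off - d*I_DD_on``.

    The off-state FRET-channel signal stands in for the direct acceptor
    excitation, and the d factor removes donor bleed-through.  A negative
    result is returned flagged — clamping would hide calibration errors.
    """
    value = s.i_da_on - s.i_da_off - ct.d * s.i_dd_on
    return FcOn(float(value), bool(value < 0))


def calibrate_g(fc_on: float, efd_ref: float, i_dd_on: float, provenance: str = "") -> GFactor:
    """G factor from a reference construct of known efficiency.

    ``G = Fc_on * (1 - EfD) / (EfD * I_DD_on)`` with ``efd_ref`` typically a
    rate-ratio measurement on a tandem-dimer calibration construct.  G is
    specific to a donor/acceptor pairing and optical configuration but is
    independent of the construct's efficiency, so one calibration serves all
    subsequent sensitized-emission analyses on the same setup.
    """
    if not 0 < efd_ref < 1:
        raise ValueError("reference EfD must lie strictly between 0 and 1")
    if fc_on <= 0:
        raise ValueError("calibration Fc_on must be positive")
    if i_dd_on <= 0:
        raise ValueError("calibration I_DD_on must be positive")
    value = fc_on * (1.0 - efd_ref) / (efd_ref * i_dd_on)
    return GFactor(value=value, provenance=provenance)


def efd_sensitized(fc_on: float, i_dd_on: float, g: GFactor | float) -> FretMeasurement:
    """Donor-side efficiency from sensitized emission.

    ``EfD = (Fc_on/G) / (I_DD_on + Fc_on/G)``: Fc_on/G estimates the donor
    signal lost to transfer, and the efficiency is that loss over the total
    the donor would have emitted.
    """
    g_val = g.value if isinstance(g, GFactor) else float(g)
    if g_val <= 0:
        raise ValueError("G factor must be positive")
    if i_dd_on <= 0:
        raise ValueError("I_DD_on must be positive")
    lost = fc_on / g_val
    value = lost / (i_dd_on + lost)
    flags = ("negative_fc",) if fc_on < 0 else ()
    return FretMeasurement(float(value), "donor", "sensitized_D", flags=flags)


def efa_sensitized(fc_on: float, i_da_off: float, ext: ExtinctionPair) -> FretMeasurement:
    """Acceptor-side efficiency: ``EfA = (eps_A/eps_D) * Fc_on / I_DA_off``.

    ``I_DA_off`` measures direct acceptor excitation (donor switched off),
    so ``Fc_on / I_DA_off`` compares transferred to directly excited
    acceptor photons; the extinction ratio converts that into the fraction
    of acceptors receiving transfer.  Copy-number-scaled coefficients from
    ``ext`` handle chimeras with unequal donor/acceptor stoichiometry.
    """
    if i_da_off <= 0:
        raise ValueError("I_DA_off must be positive")
    value = (ext.eps_a_eff / ext.eps_d_eff) * (fc_on / i_da_off)
    flags = ("negative_fc",) if fc_on < 0 else ()
    return FretMeasurement(float(value), "acceptor", "sensitized_A", flags=flags)


def measure_on_off_levels(
    donor_stack: ImageStack,
    fret_stack: ImageStack,
    roi: RoiMask,
    off_frac: float = 0.02,
    first_k: int = 1,
    fit_cfg: FitConfig | None = None,
) -> SensitizedSet:
    """Extract on/off-state intensity levels from a photoswitching cycle.

    On-state levels are the first frame of the cycle (optionally the mean of
    the first ``first_k`` frames for low-signal data).  The off level is the
    mean FRET-channel signal over frames where the donor-channel signal has
    decayed to within ``off_frac`` of its fitted amplitude above the fitted
    offset; if the donor never switches that far off, the last 10% of frames
    are used instead and the result is flagged ``incomplete_switching``.

    Both stacks must be co-registered, background-subtracted and share the
    same frame times.
    """
    if donor_stack.n_frames != fret_stack.n_frames or not np.allclose(
        donor_stack.times, fret_stack.times
    ):
        raise ValueError("donor and FRET stacks must share frame times")
    if not 0 < off_frac < 1:
        raise ValueError("off_frac must be in (0, 1)")
    if first_k < 1 or first_k > donor_stack.n_frames:
        raise ValueError("first_k out of range")

    donor_trace = extract_trace(donor_stack, roi)
    fret_trace = extract_trace(fret_stack, roi)
    fit = fit_single_exponential(donor_trace, fit_cfg)
    flags: list[str] = []
    if not fit.converged:
        raise ValueError("donor decay fit did not converge; cannot define the off state")

    amplitude = donor_trace.values[0] - fit.c
    off_mask = (donor_trace.values - fit.c) < off_frac * amplitude
    if off_mask.sum() >= 2:
        i_da_off = float(fret_trace.values[off_mask].mean())
    else:
        n_tail = max(2, donor_stack.n_frames // 10)
        if n_tail > donor_stack.n_frames:
            raise ValueError("too few frames to estimate an off level")
        i_da_off = float(fret_trace.values[-n_tail:].mean())
        flags.append("incomplete_switching")
        warnings.warn(
            "donor did not switch below the off threshold; off level taken "
            "from the trace tail",
            RuntimeWarning,
        )

    i_dd_on = float(donor_trace.values[:first_k].mean())
    i_da_on = float(fret_trace.values[:first_k].mean())
    if i_da_off < 0:
        flags.append("negative_off_level")
        i_da_off = max(i_da_off, 0.0)
    return SensitizedSet(
        i_dd_on=i_dd_on, i_da_on=i_da_on, i_da_off=i_da_off, flags=tuple(flags)
    )


def multi_acceptor_efficiency(e_single: float, n_acceptors: int) -> float:
    """Combined efficiency of one donor next to n identical acceptors.

    Transfer rates add: each acceptor contributes ``k_T = e/(1-e)`` in units
    of the donor's other de-excitation rate, so
    ``E_n = n*e / (n*e + 1 - e)``.
    """
    if not 0 <= e_single < 1:
        raise ValueError("per-pair efficiency must be in [0, 1)")
    if n_acceptors < 1:
        raise ValueError("need at least one acceptor")
    return n_acceptors * e_single / (n_acceptors * e_single + 1.0 - e_single)
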