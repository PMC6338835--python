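"""Synthetic photoswitching FRET experiments with known ground truth.

The generator emulates the measurement protocol end to end: a donor that
switches off mono-exponentially under donor excitation, FRET-coupled slowing
of that rate (``k_DA = k_D * (1 - E)``), a residual off-state brightness of
``1/contrast`` (so the fitted offset and the imperfect off-state cross-talk
are emergent, not bolted on), donor bleed-through into the FRET channel,
direct acceptor excitation scaled by the extinction ratio, Poisson photon
noise plus Gaussian camera read noise, multiplicative flat-field
heterogeneity (which scales the photoswitching *rates* as well as the
brightness, since switching is excitation-driven), repeated cycles with an
optional linear per-cycle rate drift, and acceptor photobleaching.

Scenes are specified as concentrations of free donor ``[D]``, free acceptor
``[A]`` and donor-acceptor complexes ``[DA]`` with per-complex efficiency
and copy numbers, so every estimator in the package has an exact ground
truth (``EfD = E_eff*[DA]*n_D / ([D] + [DA]*n_D)`` and
``EfA = E_eff*[DA]*n_D / ([A] + [DA]*n_A)``) to be judged against.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fretcalc import (
    EPS_ACCEPTOR_MCHERRY_488,
    EPS_DONOR_DRONPA_488,
    SensitizedSet,
    multi_acceptor_efficiency,
)
from .iostacks import ImageStack

__all__ = [
    "PhotophysicsModel",
    "Region",
    "SceneSpec",
    "AcquisitionSpec",
    "tandem_dimer_scene",
    "donor_alone_scene",
    "region_rates",
    "switching_curve",
    "expected_traces",
    "expected_levels",
    "simulate_stack",
    "simulate_cycles",
    "simulate_acceptor_photobleach",
    "bleach_acceptors",
    "ground_truth",
]

#: Reference donor extinction used to normalize the brightness scale, so that
#: ``photons_initial`` means "expected first-frame electrons per unit
#: concentration for a Dronpa-like donor".
EPS_D_REF = EPS_DONOR_DRONPA_488


@dataclass(frozen=True)
class PhotophysicsModel:
    """Donor/acceptor photophysics shared by every region of a scene.

    ``k_d`` is the donor off-switching rate at reference illumination;
    ``contrast`` the on/off brightness ratio (50-100x for a Dronpa-like
    donor; ``math.inf`` gives the idealized perfectly dark off state);
    ``d_true`` the donor bleed-through fraction into the FRET channel;
    ``q_rel`` the detected sensitized-acceptor brightness per transferred
    excitation relative to donor-channel brightness; ``drift_slope`` the
    additive per-cycle increase of the off-switching rate (s^-1/cycle),
    applied equally to donor-alone and FRET constructs.
    """

    k_d: float = 1.0
    contrast: float = 75.0
    d_true: float = 0.08
    q_rel: float = 1.0
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_d > 0:
            raise ValueError("k_d must be positive")
        if not self.contrast > 1:
            raise ValueError("on/off contrast must exceed 1")
        if not 0 <= self.d_true < 1:
            raise ValueError("bleed-through fraction must be in [0, 1)")
        if self.q_rel < 0:
            raise ValueError("q_rel must be >= 0")

    @property
    def off_residual(self) -> float:
        return 0.0 if math.isinf(self.contrast) else 1.0 / self.contrast


@dataclass(frozen=True)
class Region:
    """One homogeneous scene region: concentrations and complex makeup.

    Concentrations are in donor-pairing units: ``conc_da`` counts complexes,
    each carrying ``donor_copies`` donors and ``acceptor_copies`` acceptors;
    ``conc_d``/``conc_a`` count free (uncomplexed) donors/acceptors.
    """

    conc_d: float = 0.0
    conc_a: float = 0.0
    conc_da: float = 1.0
    e_single: float = 0.3
    donor_copies: int = 1
    acceptor_copies: int = 1
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if min(self.conc_d, self.conc_a, self.conc_da) < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 <= self.e_single < 1:
            raise ValueError("per-pair efficiency must be in [0, 1)")
        if self.donor_copies < 1 or self.acceptor_copies < 1:
            raise ValueError("copy numbers must be >= 1")


@dataclass(frozen=True)
class SceneSpec:
    """A labelled collection of regions, optionally placed on an image grid."""

    label: str = "scene"
    shape: tuple[int, int] | None = None
    regions: tuple[Region, ...] = (Region(),)

    def __post_init__(self) -> None:
        if len(self.regions) == 0:
            raise ValueError("scene needs at least one region")
        if self.shape is not None:
            for r in self.regions:
                if r.mask is not None and r.mask.shape != tuple(self.shape):
                    raise ValueError("region mask shape does not match scene shape")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Detection and protocol parameters for one simulated experiment."""

    n_frames: int = 100
    frame_interval: float = 0.05
    photons_initial: float = 500.0
    eps_d: float = EPS_DONOR_DRONPA_488
    eps_a: float = EPS_ACCEPTOR_MCHERRY_488
    background_e: float = 20.0
    read_noise_e: float = 2.0
    gain_e_per_adu: float = 2.0
    flatfield: float | np.ndarray = 1.0
    n_cycles: int = 1
    reactivation_efficiency: float = 1.0
    acceptor_pb_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if not self.photons_initial > 0:
            raise ValueError("photons_initial must be positive")
        if not 0 < self.reactivation_efficiency <= 1:
            raise ValueError("reactivation_efficiency must be in (0, 1]")
        if not 0 <= self.acceptor_pb_fraction <= 1:
            raise ValueError("acceptor_pb_fraction must be in [0, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def tandem_dimer_scene(
    e_single: float = 0.3,
    conc_da: float = 1.0,
    donor_copies: int = 1,
    acceptor_copies: int = 1,
    conc_d: float = 0.0,
    conc_a: float = 0.0,
    label: str = "tandem",
    shape: tuple[int, int] | None = None,
) -> SceneSpec:
    """Convenience scene: a single homogeneous region of complexes."""
    region = Region(
        conc_d=conc_d,
        conc_a=conc_a,
        conc_da=conc_da,
        e_single=e_single,
        donor_copies=donor_copies,
        acceptor_copies=acceptor_copies,
    )
    return SceneSpec(label=label, shape=shape, regions=(region,))


def donor_alone_scene(
    conc_d: float = 1.0, label: str = "donor_alone", shape: tuple[int, int] | None = None
) -> SceneSpec:
    """Convenience scene: free donor only (the control construct)."""
    return SceneSpec(
        label=label, shape=shape, regions=(Region(conc_d=conc_d, conc_da=0.0),)
    )


def region_rates(region: Region, model: PhotophysicsModel) -> tuple[float, float]:
    """Effective per-complex efficiency and complexed-donor switching rate."""
    if region.conc_da > 0:
        e_eff = multi_acceptor_efficiency(region.e_single, region.acceptor_copies)
    else:
        e_eff = 0.0
    return e_eff, model.k_d * (1.0 - e_eff)


def switching_curve(t: np.ndarray, k, model: PhotophysicsModel) -> np.ndarray:
    """Relative on-state brightness ``(1 - r) * exp(-k t) + r``, r = 1/contrast."""
    r = model.off_residual
    k = np.asarray(k, dtype=float)
    return (1.0 - r) * np.exp(-np.multiply.outer(k, np.asarray(t, dtype=float))) + r


def _region_expectations(
    region: Region,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
    t: np.ndarray,
    rate_offset: float = 0.0,
    illum=1.0,
    amp_scale: float = 1.0,
):
    """Donor- and FRET-channel expectations (background included).

    ``illum`` may be a scalar or a per-pixel vector; rates and brightness
    both scale with it, since photoswitching is excitation-driven.  The
    returned arrays have shape ``t.shape`` for scalar ``illum`` and
    ``(npix, nt)`` otherwise.
    """
    e_eff, k_da = region_rates(region, model)
    illum = np.asarray(illum, dtype=float)
    b = acq.photons_initial * (acq.eps_d / EPS_D_REF) * illum * amp_scale
    k_d_eff = model.k_d * illum + rate_offset
    k_da_eff = k_da * illum + rate_offset
    g_d = switching_curve(t, k_d_eff, model)
    g_da = switching_curve(t, k_da_eff, model)
    if illum.ndim > 0:
        b = b[:, None]

    n_d, n_a = region.donor_copies, region.acceptor_copies
    s_dd = b * (region.conc_d * g_d + region.conc_da * n_d * (1.0 - e_eff) * g_da)
    a_direct = (
        acq.photons_initial
        * illum
        * amp_scale
        * (acq.eps_a / acq.eps_d)
        * (region.conc_a + region.conc_da * n_a)
        * model.q_rel
    )
    fc = (
        acq.photons_initial
        * illum
        * amp_scale
        * model.q_rel
        * region.conc_da
        * n_d
        * e_eff
    )
    if illum.ndim > 0:
        a_direct = a_direct[:, None]
        fc = fc[:, None]
    s_da = model.d_true * s_dd + a_direct + fc * g_da + acq.background_e
    return s_dd + acq.background_e, s_da


def expected_traces(
    region: Region,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
    rate_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless donor- and FRET-channel expectation traces over the cycle.

    Background is included, exactly as a detector would record it; subtract
    ``acq.background_e`` to obtain the background-corrected signals the
    estimators operate on.
    """
    return _region_expectations(region, model, acq, acq.times, rate_offset=rate_offset)


def expected_levels(
    region: Region,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
) -> SensitizedSet:
    """Exact background-subtracted on/off levels for sensitized emission.

    On-state levels are the cycle-start (t = 0) expectations; the off level
    is the t -> infinity asymptote, where the donor on-state population has
    fully decayed and only the off-state residual, direct acceptor
    excitation and residual transfer remain.
    """
    t = np.array([0.0])
    s_dd_on, s_da_on = _region_expectations(region, model, acq, t)
    # asymptotic limit: exp(-k t) -> 0, so the switching curve -> off residual
    r = model.off_residual
    e_eff, _ = region_rates(region, model)
    b = acq.photons_initial * (acq.eps_d / EPS_D_REF)
    s_dd_inf = b * (region.conc_d + region.conc_da * region.donor_copies * (1.0 - e_eff)) * r
    a_direct = (
        acq.photons_initial
        * (acq.eps_a / acq.eps_d)
        * (region.conc_a + region.conc_da * region.acceptor_copies)
        * model.q_rel
    )
    fc_inf = (
        acq.photons_initial * model.q_rel * region.conc_da * region.donor_copies * e_eff * r
    )
    s_da_inf = model.d_true * s_dd_inf + a_direct + fc_inf
    return SensitizedSet(
        i_dd_on=float(s_dd_on[0] - acq.background_e),
        i_da_on=float(s_da_on[0] - acq.background_e),
        i_da_off=float(s_da_inf),
    )


def _flatfield_image(acq: AcquisitionSpec, shape: tuple[int, int]) -> np.ndarray:
    ff = np.asarray(acq.flatfield, dtype=float)
    if ff.ndim == 0:
        return np.full(shape, float(ff))
    if ff.shape != shape:
        raise ValueError(f"flatfield shape {ff.shape} does not match scene shape {shape}")
    return ff


def _scene_shape(scene: SceneSpec) -> tuple[int, int]:
    return tuple(scene.shape) if scene.shape is not None else (32, 32)


def _expectation_images(
    scene: SceneSpec,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
    rate_offset: float = 0.0,
    amp_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    shape = _scene_shape(scene)
    t = acq.times
    ff = _flatfield_image(acq, shape)
    mu_dd = np.full((acq.n_frames,) + shape, float(acq.background_e))
    mu_da = np.full((acq.n_frames,) + shape, float(acq.background_e))
    covered = np.zeros(shape, dtype=bool)
    for region in scene.regions:
        mask = (
            np.ones(shape, dtype=bool) if region.mask is None else region.mask.astype(bool)
        )
        if (covered & mask).any():
            raise ValueError("scene regions overlap")
        covered |= mask
        illum = ff[mask]
        s_dd, s_da = _region_expectations(
            region, model, acq, t, rate_offset=rate_offset, illum=illum, amp_scale=amp_scale
        )
        mu_dd[:, mask] = s_dd.T
        mu_da[:, mask] = s_da.T
    return mu_dd, mu_da


def simulate_stack(
    scene: SceneSpec,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
    rate_offset: float = 0.0,
    amp_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[ImageStack, ImageStack]:
    """One noisy photoswitching cycle as a dual-channel stack pair.

    Per pixel and frame the recorded value is
    ``Poisson(expectation) + Normal(0, read_noise)``; the flat-field scales
    both brightness and rates.  Reproducible for a fixed ``acq.seed`` (or an
    explicitly passed generator).
    """
    if rng is None:
        if acq.seed is None:
            raise ValueError("set acq.seed (or pass rng) so the simulation is reproducible")
        rng = np.random.default_rng(acq.seed)
    mu_dd, mu_da = _expectation_images(scene, model, acq, rate_offset, amp_scale)
    data = []
    for mu in (mu_dd, mu_da):
        noisy = rng.poisson(np.clip(mu, 0, None)).astype(float)
        if acq.read_noise_e > 0:
            noisy += rng.normal(0.0, acq.read_noise_e, size=mu.shape)
        data.append(noisy)
    meta = {"scene": scene.label}
    donor = ImageStack(data[0], acq.times, "donor_em_donor_exc", dict(meta))
    fret = ImageStack(data[1], acq.times, "acceptor_em_donor_exc", dict(meta))
    return donor, fret


def simulate_cycles(
    scene: SceneSpec,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
) -> tuple[list[tuple[ImageStack, ImageStack]], pd.DataFrame]:
    """Repeated photoswitching cycles with drift and incomplete reactivation.

    Cycle ``c`` (1-based) adds ``drift_slope * (c - 1)`` to every off-
    switching rate and scales amplitudes by ``reactivation_efficiency**(c-1)``.
    Returns the per-cycle stack pairs plus a ground-truth table of the true
    rates and efficiencies.
    """
    if acq.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if acq.seed is None:
        raise ValueError("set acq.seed so the simulation is reproducible")
    rng = np.random.default_rng(acq.seed)
    stacks = []
    rows = []
    efd_true, efa_true = ground_truth(scene)
    for c in range(1, acq.n_cycles + 1):
        offset = model.drift_slope * (c - 1)
        amp = acq.reactivation_efficiency ** (c - 1)
        stacks.append(simulate_stack(scene, model, acq, rate_offset=offset, amp_scale=amp, rng=rng))
        e_eff, k_da = region_rates(scene.regions[0], model)
        rows.append(
            {
                "cycle": c,
                "k_d_true": model.k_d + offset,
                "k_da_true": k_da + offset,
                "amp_scale": amp,
                "efd_true": efd_true,
                "efa_true": efa_true,
            }
        )
    return stacks, pd.DataFrame(rows)


def bleach_acceptors(scene: SceneSpec, pb_fraction: float) -> SceneSpec:
    """Scene after photobleaching a fraction of the acceptors.

    A bleached acceptor can no longer accept: complexes whose acceptors are
    destroyed join the free-donor pool (``donor_copies`` donors each).
    Bleaching acts on whole complexes; partial bleaching within a
    multi-acceptor complex is not modeled.
    """
    if not 0 <= pb_fraction <= 1:
        raise ValueError("pb_fraction must be in [0, 1]")
    new_regions = []
    for r in scene.regions:
        bleached = r.conc_da * pb_fraction
        new_regions.append(
            replace(
                r,
                conc_da=r.conc_da - bleached,
                conc_d=r.conc_d + bleached * r.donor_copies,
                conc_a=r.conc_a * (1.0 - pb_fraction),
            )
        )
    return replace(scene, regions=tuple(new_regions), label=scene.label + "_postPB")


def simulate_acceptor_photobleach(
    scene: SceneSpec,
    model: PhotophysicsModel,
    acq: AcquisitionSpec,
):
    """Pre- and post-photobleach photoswitching cycles.

    The post-bleach scene has ``acq.acceptor_pb_fraction`` of the complexes
    converted to unquenched free donors; with full bleaching the post-bleach
    donor kinetics equal the donor-alone kinetics.
    """
    if acq.seed is None:
        raise ValueError("set acq.seed so the simulation is reproducible")
    rng = np.random.default_rng(acq.seed)
    pre = simulate_stack(scene, model, acq, rng=rng)
    post_scene = bleach_acceptors(scene, acq.acceptor_pb_fraction)
    post = simulate_stack(post_scene, model, acq, rng=rng)
    return pre, post


def ground_truth(scene: SceneSpec) -> tuple[float, float]:
    """True (EfD, EfA) of a scene, aggregated over regions.

    Donor side: per-complex efficiency times the fraction of all donors in
    complexes.  Acceptor side: transfer events per acceptor, i.e. the same
    numerator over the total acceptor population.  Zero denominators yield
    NaN with a warning.
    """
    num = 0.0
    donors = 0.0
    acceptors = 0.0
    for r in scene.regions:
        e_eff = (
            multi_acceptor_efficiency(r.e_single, r.acceptor_copies) if r.conc_da > 0 else 0.0
        )
        num += e_eff * r.conc_da * r.donor_copies
        donors += r.conc_d + r.conc_da * r.donor_copies
        acceptors += r.conc_a + r.conc_da * r.acceptor_copies
    if donors == 0:
        warnings.warn("no donors in scene; EfD undefined", RuntimeWarning)
        efd = float("nan")
    else:
        efd = num / donors
    if acceptors == 0:
        efa = 0.0 if num == 0 else float("nan")
        if num > 0:
            warnings.warn("no acceptors in scene; EfA undefined", RuntimeWarning)
    else:
        efa = num / acceptors
    return float(efd), float(efa)
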