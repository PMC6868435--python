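"""Mechanics of the lambda-DNA tether in series with the optical trap.

The tether is modelled as an extensible worm-like chain (Marko-Siggia
interpolation with an enthalpic stretch-modulus term) in series with a
harmonic trap.  Driving the piezo stage at constant speed through this
series compliance yields the force-versus-time loading schedule and the
instantaneous loading rate dF/dt that the rupture-kinetics analysis
consumes.  A freely jointed chain describes the short ssDNA segment
revealed by unfolding.

Force balance for a stage displacement ``s`` (nm from the trap origin)::

    x_wlc(F) + F / kappa = s

with the extensible Marko-Siggia relation::

    F = (kBT/P) * [ 1/(4 (1 - x/Lc + F/K)^2) - 1/4 + x/Lc - F/K ]

Both relations are strictly monotone, so the force at a stage position
and the extension at a force are unique and mutually inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core_io import KBT_ROOM

__all__ = [
    "TetherModel",
    "SsDnaModel",
    "LoadingSchedule",
    "DEFAULT_STAGE_START",
    "DEFAULT_STAGE_END",
    "wlc_extension",
    "force_at_stage",
    "system_compliance",
    "loading_schedule",
    "constant_loading_schedule",
    "ssdna_extension",
    "calibrate_end_stage",
    "calibrate_trap_stiffness",
]

#: Stage ramp endpoints (nm) reproducing the published protocol:
#: 14 um start, end inside the 16.8-17.2 um window, chosen so the ramp
#: tops out near 28 pN in ~6.5 s at 455 nm/s.
DEFAULT_STAGE_START = 14000.0
DEFAULT_STAGE_END = 16960.0


@dataclass(frozen=True)
class TetherModel:
    """Mechanical constants of the lambda-DNA + trap system.

    Defaults are standard lambda-DNA elasticity (16.4 um contour,
    50 nm persistence length, 1200 pN stretch modulus) with a trap
    stiffness of 0.046 pN/nm and the instrument's 455 nm/s stage speed.
    """

    contour_length: float = 16400.0  # nm
    persistence_length: float = 50.0  # nm
    stretch_modulus: float = 1200.0  # pN
    trap_stiffness: float = 0.046  # pN/nm
    stage_speed: float = 455.0  # nm/s
    kBT: float = KBT_ROOM  # pN*nm

    def __post_init__(self) -> None:
        for name in (
            "contour_length",
            "persistence_length",
            "stretch_modulus",
            "trap_stiffness",
            "stage_speed",
            "kBT",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"TetherModel.{name} must be > 0")


@dataclass(frozen=True)
class SsDnaModel:
    """Freely jointed chain for the unfolded single-stranded segment."""

    n_nt: int
    contour_per_nt: float = 0.63  # nm per nucleotide
    kuhn_length: float = 1.5  # nm
    forster_radius: float = 5.4  # nm, for the optional mechanistic E(F) mode
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        for name in ("n_nt", "contour_per_nt", "kuhn_length", "forster_radius", "kBT"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SsDnaModel.{name} must be > 0")

    @property
    def contour_length(self) -> float:
        return self.n_nt * self.contour_per_nt


def _ms_force(l: float, model: TetherModel) -> float:
    """Marko-Siggia force at effective fractional extension ``l``."""
    return (model.kBT / model.persistence_length) * (
        0.25 / (1.0 - l) ** 2 - 0.25 + l
    )


def _ms_fraction(F: float, model: TetherModel) -> float:
    """Invert Marko-Siggia: effective fractional extension at force F."""
    if F <= 0:
        return 0.0
    try:
        return brentq(lambda l: _ms_force(l, model) - F, 0.0, 1.0 - 1e-14, xtol=1e-14)
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"worm-like-chain inversion failed for F={F} pN on bracket (0, 1)"
        ) from exc


def wlc_extension(F, model: TetherModel = TetherModel()):
    """Extension (nm) of the extensible WLC tether at force ``F`` (pN).

    Accepts a scalar or array; strictly increasing and continuous in F,
    with x(0) = 0.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    scalar = F.ndim == 0
    Fv = np.atleast_1d(F)
    frac = np.array([_ms_fraction(f, model) for f in Fv])
    x = model.contour_length * (frac + Fv / model.stretch_modulus)
    return float(x[0]) if scalar else x


def system_compliance(F, model: TetherModel = TetherModel()):
    """Total compliance d(stage)/dF = dx_wlc/dF + 1/kappa, in nm/pN."""
    F = np.asarray(F, dtype=float)
    scalar = F.ndim == 0
    Fv = np.atleast_1d(F)
    out = np.empty_like(Fv)
    for i, f in enumerate(Fv):
        l = _ms_fraction(f, model)
        dFdl = (model.kBT / model.persistence_length) * (0.5 / (1.0 - l) ** 3 + 1.0)
        out[i] = model.contour_length * (1.0 / dFdl + 1.0 / model.stretch_modulus)
    out += 1.0 / model.trap_stiffness
    return float(out[0]) if scalar else out


def force_at_stage(stage, model: TetherModel = TetherModel()):
    """Force (pN) balancing the tether + trap at a given stage position.

    Unique by monotonicity of the series compliance.  Stage positions at
    or below the zero-force slack return 0 pN with a warning.
    """
    stage_arr = np.asarray(stage, dtype=float)
    scalar = stage_arr.ndim == 0

    def solve_one(s: float) -> float:
        if s <= 0:
            warnings.warn(f"stage {s} nm is inside the zero-force slack; returning F=0")
            return 0.0
        total = lambda F: wlc_extension(F, model) + F / model.trap_stiffness - s
        hi = 1.0
        while total(hi) < 0:
            hi *= 2.0
            if hi > 1e5:  # pragma: no cover - defensive
                raise RuntimeError(f"no force below 1e5 pN reaches stage {s} nm")
        return brentq(total, 0.0, hi, xtol=1e-12, rtol=1e-14)

    out = np.array([solve_one(s) for s in np.atleast_1d(stage_arr)])
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class LoadingSchedule:
    """Force protocol of one constant-velocity stretch.

    ``force_of_time`` maps t (s, 0 at the first sample) to force (pN);
    ``rate_of_force`` maps force to the instantaneous loading rate
    dF/dt (pN/s); ``effective_rate`` is the force-averaged loading rate
    over [f_start, f_max], the single-number summary used by the
    constant-rate Dudko-Szabo convention.
    """

    force_of_time: Callable
    time_of_force: Callable
    rate_of_force: Callable
    f_start: float
    f_max: float
    duration: float
    effective_rate: float


def loading_schedule(
    start_stage: float = DEFAULT_STAGE_START,
    end_stage: float = DEFAULT_STAGE_END,
    model: TetherModel = TetherModel(),
    n_grid: int = 1200,
) -> LoadingSchedule:
    """Build the loading schedule for a stage ramp at the model's speed."""
    if not end_stage > start_stage:
        raise ValueError("end_stage must exceed start_stage")
    stages = np.linspace(start_stage, end_stage, n_grid)
    forces = force_at_stage(stages, model)
    times = (stages - start_stage) / model.stage_speed
    f_of_t = PchipInterpolator(times, forces, extrapolate=False)
    t_of_f = PchipInterpolator(forces, times, extrapolate=False)

    def rate_of_force(F):
        return model.stage_speed / system_compliance(F, model)

    fgrid = np.linspace(forces[0], forces[-1], 600)
    rates = rate_of_force(fgrid)
    eff = float(np.trapezoid(rates, fgrid) / (fgrid[-1] - fgrid[0]))
    return LoadingSchedule(
        force_of_time=f_of_t,
        time_of_force=t_of_f,
        rate_of_force=rate_of_force,
        f_start=float(forces[0]),
        f_max=float(forces[-1]),
        duration=float(times[-1]),
        effective_rate=eff,
    )


def constant_loading_schedule(rate: float, f_max: float, f_start: float = 0.0) -> LoadingSchedule:
    """Idealized linear ramp F = f_start + rate * t (Bell-Evans setting)."""
    if not rate > 0 or not f_max > f_start:
        raise ValueError("need rate > 0 and f_max > f_start")
    duration = (f_max - f_start) / rate
    return LoadingSchedule(
        force_of_time=lambda t: f_start + rate * np.asarray(t, dtype=float),
        time_of_force=lambda F: (np.asarray(F, dtype=float) - f_start) / rate,
        rate_of_force=lambda F: np.full_like(np.asarray(F, dtype=float), rate)
        if np.ndim(F)
        else rate,
        f_start=f_start,
        f_max=f_max,
        duration=duration,
        effective_rate=rate,
    )


def ssdna_extension(F, model: SsDnaModel):
    """Freely-jointed-chain extension (nm) of ssDNA at force F (pN).

    x = L * [coth(u) - 1/u] with u = F*b/kBT; the small-u limit u/3 is
    used below u = 1e-4 to avoid cancellation.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    scalar = F.ndim == 0
    u = np.atleast_1d(F) * model.kuhn_length / model.kBT
    lang = np.where(u > 1e-4, 1.0 / np.tanh(np.maximum(u, 1e-12)) - 1.0 / np.maximum(u, 1e-12), u / 3.0)
    x = model.contour_length * lang
    return float(x[0]) if scalar else x


def calibrate_end_stage(
    f_end: float,
    model: TetherModel = TetherModel(),
) -> float:
    """Stage position (nm) at which the ramp reaches ``f_end`` pN."""
    return float(wlc_extension(f_end, model) + f_end / model.trap_stiffness)


def calibrate_trap_stiffness(
    f_start: float,
    f_end: float,
    duration: float,
    model: TetherModel = TetherModel(),
) -> TetherModel:
    """Solve for the trap stiffness that spans (f_start, f_end) in ``duration``.

    The stage travel is duration * speed; the tether part of the travel
    is fixed by the WLC, and the remainder (f_end - f_start)/kappa pins
    kappa.
    """
    travel = duration * model.stage_speed
    dx_wlc = wlc_extension(f_end, model) - wlc_extension(f_start, model)
    trap_travel = travel - dx_wlc
    if trap_travel <= 0:
        raise ValueError(
            "requested ramp is shorter than the bare tether extension change; "
            "no positive trap stiffness can match it"
        )
    kappa = (f_end - f_start) / trap_travel
    return replace(model, trap_stiffness=float(kappa))
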