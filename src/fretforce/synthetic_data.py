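"""Synthetic-trace generators for every pipeline input.

Three generators emulate the statistical structure of the experiments
so that each analysis stage can be exercised at desk scale:

* :func:`gen_intensity_traces` - zero-force TIRF traces at 30 ms per
  frame with Poisson shot noise, channel backgrounds, donor-to-acceptor
  crosstalk, an acceptor-dark (donor-only) fraction and exponential
  photobleaching;
* :func:`gen_pulling_ensemble` - 20 ms pulling cycles driven by the
  lambda-DNA loading schedule, with per-cycle archetype E(F) curves
  (complete / Type I / Type II / ultrastable), rupture forces drawn
  from Dudko-Szabo hazards, refolding at low force on relaxation, and
  cycle-to-cycle archetype switching;
* :func:`gen_vectorial_traces` - real-time unwinding/folding traces
  (gradual rise vs flat baseline classes).

Every generator emits machine-readable ground truth next to the traces
and is byte-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core_io import IntensityTrace, PullingCycle
from .dudko_szabo import DsMixture, DsParams, _as_mixture, _hazard_grid
from .fret_analysis import CorrectionSpec, MixtureComponent
from .tether_mechanics import (
    DEFAULT_STAGE_END,
    DEFAULT_STAGE_START,
    LoadingSchedule,
    TetherModel,
    loading_schedule,
)
from .core_io import KBT_ROOM

__all__ = [
    "FretPopulationSpec",
    "ArchetypeCurve",
    "PullingEnsembleSpec",
    "VectorialSpec",
    "ARCHETYPES",
    "gen_intensity_traces",
    "gen_pulling_ensemble",
    "gen_vectorial_traces",
]


@dataclass(frozen=True)
class FretPopulationSpec:
    """Zero-force population for the TIRF generator.

    Defaults emulate the five-repeat telomeric construct in 100 mM K+:
    three non-interconverting folded subpopulations (5' GQ ~0.66,
    3' GQ ~0.75, long-loop GQ ~0.85 at 18/64/18 % of folded events)
    plus a 20 % acceptor-dark fraction, 500 counts/frame total
    intensity and a 0.02 /s photobleaching rate.
    """

    components: tuple[MixtureComponent, ...] = (
        MixtureComponent(center=0.66, width=0.05, label="five_prime_GQ"),
        MixtureComponent(center=0.75, width=0.05, label="three_prime_GQ"),
        MixtureComponent(center=0.85, width=0.05, label="long_loop_GQ"),
    )
    weights: tuple[float, ...] = (0.148, 0.512, 0.14)  # absolute, with donor-only
    donor_only_fraction: float = 0.2
    n_molecules: int = 200
    frames: int = 50
    total_intensity: float = 500.0
    frame_interval: float = 0.03
    bleach_rate: float = 0.02  # 1/s
    correction: CorrectionSpec = CorrectionSpec(
        donor_background=10.0, acceptor_background=10.0, crosstalk=0.05
    )
    shot_noise: bool = True

    def __post_init__(self) -> None:
        total = sum(self.weights) + self.donor_only_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("component weights + donor_only_fraction must sum to 1")
        if not self.total_intensity > 0:
            raise ValueError("total_intensity must be > 0")

    @classmethod
    def from_folded_weights(
        cls,
        folded_weights: Sequence[float],
        donor_only_fraction: float = 0.2,
        **kwargs,
    ) -> "FretPopulationSpec":
        """Build a spec from weights over folded components only."""
        w = np.asarray(folded_weights, dtype=float)
        w = w / w.sum() * (1.0 - donor_only_fraction)
        return cls(weights=tuple(w), donor_only_fraction=donor_only_fraction, **kwargs)


def gen_intensity_traces(
    spec: FretPopulationSpec, seed: int | None = None
) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Generate TIRF intensity traces and their ground truth.

    Per molecule a subpopulation (or the donor-only class) is drawn by
    weight and the molecule's steady E level is drawn from the
    component's Gaussian (static heterogeneity: individual molecules
    hold their E, so the component width appears as the
    molecule-to-molecule histogram width, as observed).  Per frame the
    total intensity is partitioned between the channels and Poisson
    shot noise, crosstalk and backgrounds are applied; the trace is
    truncated at an exponential photobleaching time.
    """
    rng = np.random.default_rng(seed)
    probs = np.array(list(spec.weights) + [spec.donor_only_fraction])
    labels = [c.label for c in spec.components] + ["donor_only"]
    centers = [c.center for c in spec.components] + [0.0]
    widths = [c.width for c in spec.components] + [0.0]
    corr = spec.correction

    traces: list[IntensityTrace] = []
    truth_rows = []
    for m in range(spec.n_molecules):
        mol = f"mol{m:04d}"
        j = int(rng.choice(len(probs), p=probs / probs.sum()))
        if spec.bleach_rate > 0:
            t_bleach = rng.exponential(1.0 / spec.bleach_rate)
            n_frames = int(min(spec.frames, max(1, np.ceil(t_bleach / spec.frame_interval))))
        else:
            t_bleach = np.inf
            n_frames = spec.frames
        level = float(np.clip(centers[j] + widths[j] * rng.standard_normal(), 0.0, 1.0))
        e_true = np.full(n_frames, level)
        a_sig = e_true * spec.total_intensity
        d_sig = (1.0 - e_true) * spec.total_intensity
        if spec.shot_noise:
            donor = rng.poisson(d_sig) + rng.poisson(corr.donor_background, n_frames)
            acceptor = (
                rng.poisson(a_sig)
                + rng.poisson(corr.crosstalk * d_sig)
                + rng.poisson(corr.acceptor_background, n_frames)
            )
        else:
            donor = d_sig + corr.donor_background
            acceptor = a_sig + corr.crosstalk * d_sig + corr.acceptor_background
        traces.append(
            IntensityTrace(
                molecule_id=mol,
                frame_interval=spec.frame_interval,
                donor=np.asarray(donor, dtype=float),
                acceptor=np.asarray(acceptor, dtype=float),
            )
        )
        truth_rows.append(
            {
                "molecule_id": mol,
                "label": labels[j],
                "true_center": centers[j],
                "true_level": level if labels[j] != "donor_only" else 0.0,
                "n_frames": n_frames,
            }
        )
    return traces, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ArchetypeCurve:
    """E-versus-force archetype for one mechanical species.

    Anchor points are interpolated by a monotone piecewise cubic
    (PCHIP); rupture-bearing archetypes carry the Dudko-Szabo
    parameters of their unfolding pathway and drop to a slowly
    declining ssDNA baseline (anchored at E ~ 0.10 at the rupture
    force) once unfolded.
    """

    label: str
    anchors: tuple[tuple[float, float], ...]
    rupture_model: DsParams | DsMixture | None = None
    post_rupture_e: float = 0.10
    post_rupture_e_end: float = 0.05

    def __post_init__(self) -> None:
        f = np.array([a[0] for a in self.anchors])
        e = np.array([a[1] for a in self.anchors])
        if np.any(np.diff(f) <= 0):
            raise ValueError(f"archetype {self.label}: anchor forces must increase")
        if np.any((e < 0) | (e > 1)):
            raise ValueError(f"archetype {self.label}: anchor E outside [0, 1]")

    def e_of_force(self, F) -> np.ndarray:
        f = np.array([a[0] for a in self.anchors])
        e = np.array([a[1] for a in self.anchors])
        if len(f) < 3:
            return np.interp(np.asarray(F, dtype=float), f, e)
        interp = PchipInterpolator(f, e, extrapolate=False)
        Fv = np.clip(np.asarray(F, dtype=float), f[0], f[-1])
        return interp(Fv)

    def post_rupture(self, F, f_rupture: float, f_max: float) -> np.ndarray:
        Fv = np.asarray(F, dtype=float)
        frac = np.clip((Fv - f_rupture) / max(f_max - f_rupture, 1e-9), 0.0, 1.0)
        return self.post_rupture_e - (self.post_rupture_e - self.post_rupture_e_end) * frac


#: Archetypes anchored at the published E-versus-force landmarks.
ARCHETYPES: dict[str, ArchetypeCurve] = {
    "complete": ArchetypeCurve(
        label="complete",
        anchors=((0.0, 0.80), (28.5, 0.80)),
        rupture_model=DsParams(dx_dagger=4.3, tau0=50.0, dG_dagger=6.5),
    ),
    "type_I": ArchetypeCurve(
        label="type_I",
        anchors=((0.0, 0.75), (2.0, 0.75), (28.5, 0.245)),
    ),
    "type_II": ArchetypeCurve(
        label="type_II",
        anchors=((0.0, 0.68), (2.0, 0.68), (28.5, 0.37)),
    ),
    "hTel28_1": ArchetypeCurve(
        label="hTel28_1",
        anchors=((0.0, 0.72), (2.0, 0.72), (8.0, 0.25), (28.5, 0.25)),
    ),
    "ultrastable": ArchetypeCurve(
        label="ultrastable",
        anchors=((0.0, 0.80), (28.5, 0.80)),
    ),
}


@dataclass(frozen=True)
class PullingEnsembleSpec:
    """Ensemble recipe for the pulling-cycle generator.

    ``species`` maps archetype labels to exact counts (with
    ``exact_counts=True``) or sampling weights.  With a switching
    matrix, each molecule's archetype evolves across cycles as a Markov
    chain; with exact counts the label multiset is fixed and shuffled
    across cycle slots.
    """

    species: Mapping[str, float] = field(
        default_factory=lambda: {"complete": 58, "type_I": 150, "type_II": 55}
    )
    exact_counts: bool = True
    switching: Mapping[str, Mapping[str, float]] | None = None
    cycles_per_molecule: int = 4
    e_noise: float = 0.03
    total_intensity: float = 500.0
    dt: float = 0.02
    refold_range: tuple[float, float] = (1.0, 7.0)
    tether: TetherModel = TetherModel()
    stage_start: float = DEFAULT_STAGE_START
    stage_end: float = DEFAULT_STAGE_END
    rate_mode: str = "effective"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.species.values()):
            raise ValueError("species counts/weights must be >= 0")
        if self.switching is not None:
            for lab, row in self.switching.items():
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ValueError(f"switching row {lab} must sum to 1")
        for lab in self.species:
            if lab not in ARCHETYPES:
                raise ValueError(f"unknown archetype {lab!r}")


def _truncated_rupture(
    model: DsParams | DsMixture,
    schedule: LoadingSchedule,
    rng: np.random.Generator,
    rate_mode: str,
    kBT: float = KBT_ROOM,
) -> float:
    """Draw one rupture force conditional on rupture within the ramp."""
    mix = _as_mixture(model)
    j = int(rng.choice(len(mix.components), p=np.asarray(mix.weights)))
    g, _, H = _hazard_grid(mix.components[j], schedule, kBT, rate_mode, 2001)
    u = rng.random()
    target = -np.log1p(-u * (1.0 - np.exp(-H[-1])))
    return float(np.interp(target, H, g))


def gen_pulling_ensemble(
    spec: PullingEnsembleSpec, seed: int | None = None
) -> tuple[list[PullingCycle], pd.DataFrame]:
    """Generate a pulling-cycle ensemble and its ground truth.

    The force-versus-time ramp comes from the tether loading schedule.
    Each cycle follows its archetype's E(F) curve on stretch and
    retraces it on relax; rupture-bearing archetypes additionally
    switch to the ssDNA baseline at a rupture force drawn from the
    archetype's Dudko-Szabo hazard (conditioned on rupture within the
    ramp - the archetype asserts that the cycle unfolds completely)
    and refold abruptly at a low force drawn uniformly from
    ``refold_range`` on the way back.  Gaussian E-noise is applied
    before conversion to channel counts.
    """
    rng = np.random.default_rng(seed)
    schedule = loading_schedule(spec.stage_start, spec.stage_end, spec.tether)
    n_half = int(np.floor(schedule.duration / spec.dt)) + 1
    t_half = np.arange(n_half) * spec.dt
    f_up = np.asarray(schedule.force_of_time(t_half), dtype=float)
    stage_up = spec.stage_start + spec.tether.stage_speed * t_half

    labels_order = list(spec.species)
    if spec.exact_counts:
        counts = {lab: int(round(c)) for lab, c in spec.species.items()}
        total = sum(counts.values())
        pool = np.array(
            [lab for lab, c in counts.items() for _ in range(c)], dtype=object
        )
        rng.shuffle(pool)
        n_molecules = int(np.ceil(total / spec.cycles_per_molecule))
    else:
        weights = np.array([spec.species[lab] for lab in labels_order], dtype=float)
        weights = weights / weights.sum()
        total = None
        n_molecules = None  # driven by switching below

    cycles: list[PullingCycle] = []
    truth_rows = []

    def synth_cycle(mol: str, cyc: int, archetype: ArchetypeCurve):
        e_up = np.asarray(archetype.e_of_force(f_up), dtype=float)
        f_rupt = np.nan
        f_ref = np.nan
        if archetype.rupture_model is not None:
            f_rupt = _truncated_rupture(
                archetype.rupture_model, schedule, rng, spec.rate_mode
            )
            unfolded = f_up >= f_rupt
            e_up = np.where(
                unfolded, archetype.post_rupture(f_up, f_rupt, schedule.f_max), e_up
            )
        f_down = f_up[::-1][1:]
        if archetype.rupture_model is not None and np.isfinite(f_rupt):
            f_ref = rng.uniform(*spec.refold_range)
            e_down = np.where(
                f_down > f_ref,
                archetype.post_rupture(f_down, f_rupt, schedule.f_max),
                archetype.e_of_force(f_down),
            )
        else:
            e_down = np.asarray(archetype.e_of_force(f_down), dtype=float)
        e = np.concatenate([e_up, e_down])
        e = np.clip(e + spec.e_noise * rng.standard_normal(len(e)), 0.0, 1.0)
        force = np.concatenate([f_up, f_down])
        stage = np.concatenate([stage_up, stage_up[::-1][1:]])
        time = np.arange(len(e)) * spec.dt
        direction = np.array(
            ["stretch"] * n_half + ["relax"] * (n_half - 1), dtype=object
        )
        donor = np.round((1.0 - e) * spec.total_intensity)
        acceptor = np.round(e * spec.total_intensity)
        cycles.append(
            PullingCycle(
                molecule_id=mol,
                cycle_index=cyc,
                time=time,
                stage_position=stage,
                force=force,
                donor=donor,
                acceptor=acceptor,
                direction=direction,
            )
        )
        truth_rows.append(
            {
                "molecule_id": mol,
                "cycle": cyc,
                "archetype": archetype.label,
                "rupture_force_pN": f_rupt,
                "refold_force_pN": f_ref,
            }
        )

    if spec.exact_counts:
        k = 0
        for m in range(n_molecules):
            mol = f"mol{m:04d}"
            for c in range(spec.cycles_per_molecule):
                if k >= len(pool):
                    break
                synth_cycle(mol, c, ARCHETYPES[pool[k]])
                k += 1
    else:
        if spec.switching is None:
            raise ValueError("weight mode requires a switching matrix (may be identity rows)")
        n_molecules = max(
            1, int(round(sum(spec.species.values()) / spec.cycles_per_molecule))
        )
        trans = np.array(
            [
                [spec.switching[a].get(b, 0.0) for b in labels_order]
                for a in labels_order
            ]
        )
        for m in range(n_molecules):
            mol = f"mol{m:04d}"
            state = int(rng.choice(len(labels_order), p=weights))
            for c in range(spec.cycles_per_molecule):
                synth_cycle(mol, c, ARCHETYPES[labels_order[state]])
                state = int(rng.choice(len(labels_order), p=trans[state]))
    return cycles, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class VectorialSpec:
    """Recipe for real-time vectorial-folding traces.

    Default class fractions correspond to ~47 % of molecules folding
    after unwinding, of which ~64 % reach the 3' GQ directly and ~22 %
    the 5' GQ level.  The rise time is the observable band-to-band
    time (baseline-band exit to terminal-band entry), normally
    distributed around 0.7 s.
    """

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct_3prime": 0.301,
            "five_prime": 0.103,
            "unfolded_ssDNA": 0.066,
            "not_unwound": 0.530,
        }
    )
    baseline_e: float = 0.07
    terminal_e: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct_3prime": 0.73,
            "five_prime": 0.62,
            "unfolded_ssDNA": 0.35,
        }
    )
    rise_mean: float = 0.7  # s
    rise_sd: float = 0.1  # s
    noise_sigma: float = 0.04
    n_traces: int = 100
    duration: float = 10.0  # s
    frame_interval: float = 0.03
    total_intensity: float = 500.0
    start_window: tuple[float, float] = (1.0, 3.0)  # unwinding onset, s

    def __post_init__(self) -> None:
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def gen_vectorial_traces(
    spec: VectorialSpec, seed: int | None = None
) -> tuple[list[IntensityTrace], pd.DataFrame]:
    """Generate real-time folding traces and ground truth.

    Rising classes follow a linear ramp from the duplex baseline to the
    class terminal E; the ramp's total span is scaled so that the
    detectable rise (exit from the baseline +-0.1 band to entry into
    the terminal +-0.05 band) matches the drawn rise time.  Poisson
    shot noise partitions the total intensity between the channels.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(spec.duration / spec.frame_interval))
    t = np.arange(n_frames) * spec.frame_interval
    labels = list(spec.fractions)
    probs = np.array([spec.fractions[k] for k in labels])

    traces: list[IntensityTrace] = []
    rows = []
    for m in range(spec.n_traces):
        mol = f"vec{m:04d}"
        label = labels[int(rng.choice(len(labels), p=probs))]
        rise = np.nan
        t0 = np.nan
        if label == "not_unwound":
            e = np.full(n_frames, spec.baseline_e)
        else:
            term = spec.terminal_e[label]
            amp = term - spec.baseline_e
            rise = max(float(rng.normal(spec.rise_mean, spec.rise_sd)), 0.2)
            # fraction of the ramp between the detection bands
            f1 = 0.1 / amp
            f2 = (amp - 0.05) / amp
            ramp_total = rise / max(f2 - f1, 1e-6)
            t0 = rng.uniform(*spec.start_window)
            frac = np.clip((t - t0) / ramp_total, 0.0, 1.0)
            e = spec.baseline_e + amp * frac
        e_noisy = np.clip(e + spec.noise_sigma * rng.standard_normal(n_frames), 0.0, 1.0)
        donor = rng.poisson((1.0 - e_noisy) * spec.total_intensity)
        acceptor = rng.poisson(e_noisy * spec.total_intensity)
        traces.append(
            IntensityTrace(
                molecule_id=mol,
                frame_interval=spec.frame_interval,
                donor=np.asarray(donor, dtype=float),
                acceptor=np.asarray(acceptor, dtype=float),
            )
        )
        rows.append(
            {
                "molecule_id": mol,
                "label": label,
                "rise_time_s": rise,
                "onset_s": t0,
                "terminal_e": spec.terminal_e.get(label, spec.baseline_e),
            }
        )
    return traces, pd.DataFrame(rows)
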