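"""Force-ramp trajectory analysis.

Segments stretch/relax cycles, detects abrupt FRET transitions and
extracts unfolding/refolding forces at the transition midpoints,
classifies cycles by the lowest efficiency reached near the maximum
force (complete / Type I / Type II / no unfolding), accumulates
cycle-to-cycle switching statistics, and bins ensemble E-versus-force
response curves.

Class boundaries on the lowest 5-sample running-median E (0.15, 0.30,
0.45) bracket the three experimental anchors (E ~ 0, ~0.2, ~0.37); a
"complete" call additionally requires an abrupt rupture event, since
cooperative unfolding at 20 ms sampling is effectively instantaneous
while Type I strand slippage is gradual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import InsufficientDataError, PullingCycle, TraceValidationError
from .dudko_szabo import RuptureSamples
from .fret_analysis import CorrectionSpec, running_median

__all__ = [
    "RuptureEvent",
    "CycleLabel",
    "SwitchingMatrix",
    "HalfCycle",
    "LABELS",
    "segment_cycles",
    "detect_rupture",
    "classify_cycle",
    "classify_ensemble",
    "switching_stats",
    "mean_E_vs_force",
    "rupture_force_table",
]

log = logging.getLogger("fretforce")

LABELS = ("complete", "type_I", "type_II", "no_unfolding")


@dataclass
class RuptureEvent:
    """An abrupt E transition and the force at its midpoint."""

    cycle_index: int
    kind: str  # 'unfold' or 'refold'
    force: float
    e_before: float
    e_after: float
    sample_index: int

    @property
    def delta_e(self) -> float:
        return abs(self.e_after - self.e_before)


@dataclass
class HalfCycle:
    """One monotone (stretch or relax) half of a pulling cycle."""

    molecule_id: str
    cycle_index: int
    phase: str  # 'stretch' | 'relax'
    time: np.ndarray
    stage: np.ndarray
    force: np.ndarray
    efficiency: np.ndarray
    partial: bool = False


@dataclass
class CycleLabel:
    """Classification of one cycle plus its rupture events."""

    molecule_id: str
    cycle_index: int
    label: str
    lowest_e: float
    events: list[RuptureEvent] = field(default_factory=list)


@dataclass
class SwitchingMatrix:
    """Counts of consecutive-cycle label pairs, aggregated over molecules."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def conditional_switch_fraction(self) -> dict[str, float]:
        """P(next label differs | current label), per label."""
        out = {}
        for i, lab in enumerate(self.labels):
            row = self.counts[i].sum()
            if row > 0:
                out[lab] = float((row - self.counts[i, i]) / row)
            else:
                out[lab] = float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "counts": self.counts.tolist(),
            "conditional_switch_fraction": self.conditional_switch_fraction(),
        }


def segment_cycles(
    cycles: Iterable[PullingCycle],
    corr: CorrectionSpec = CorrectionSpec(),
) -> list[tuple[HalfCycle, HalfCycle | None]]:
    """Split each cycle into its stretch and relax halves.

    The boundary is the stage-velocity sign change (stage maximum); the
    direction flags must agree with it, otherwise the cycle is
    rejected.  A final relax half that does not return near the start
    stage is flagged partial.
    """
    from .fret_analysis import fret_efficiency
    from .core_io import IntensityTrace

    out = []
    for cyc in cycles:
        turn = int(np.argmax(cyc.stage_position))
        flags = cyc.direction
        if np.any(flags[: turn + 1] == "relax") or np.any(flags[turn + 1 :] == "stretch"):
            raise TraceValidationError(
                f"{cyc.molecule_id} cycle {cyc.cycle_index}: direction flags do not "
                "alternate stretch->relax at the stage turnaround"
            )
        e = fret_efficiency(
            IntensityTrace(
                molecule_id=cyc.molecule_id,
                frame_interval=max(float(np.median(np.diff(cyc.time))), 1e-9),
                donor=cyc.donor,
                acceptor=cyc.acceptor,
            ),
            corr,
        )
        stretch = HalfCycle(
            molecule_id=cyc.molecule_id,
            cycle_index=cyc.cycle_index,
            phase="stretch",
            time=cyc.time[: turn + 1],
            stage=cyc.stage_position[: turn + 1],
            force=cyc.force[: turn + 1],
            efficiency=e[: turn + 1],
        )
        relax = None
        if turn + 1 < cyc.n_samples:
            span = cyc.stage_position[turn] - cyc.stage_position[0]
            returned = cyc.stage_position[-1] <= cyc.stage_position[0] + 0.1 * span
            relax = HalfCycle(
                molecule_id=cyc.molecule_id,
                cycle_index=cyc.cycle_index,
                phase="relax",
                time=cyc.time[turn + 1 :],
                stage=cyc.stage_position[turn + 1 :],
                force=cyc.force[turn + 1 :],
                efficiency=e[turn + 1 :],
                partial=not returned,
            )
        out.append((stretch, relax))
    return out


def detect_rupture(
    half: HalfCycle,
    threshold: float = 0.3,
    max_width: int = 3,
    persist: int = 5,
    median_window: int = 3,
) -> list[RuptureEvent]:
    """Find abrupt E transitions in one half-cycle.

    An abrupt transition changes the 3-sample running median by at
    least ``threshold`` within ``max_width`` samples (60 ms at 20 ms
    sampling) and stays beyond the transition midpoint for at least
    ``persist`` samples.  The event force is taken at the sample where
    the smoothed E first crosses the midpoint (E_before + E_after)/2.
    Stretch halves yield 'unfold' events, relax halves 'refold'.
    """
    e = np.asarray(half.efficiency, dtype=float)
    if len(e) < 10:
        raise ValueError("half-cycle must have >= 10 samples")
    finite = np.isfinite(e)
    if not finite.all():
        e = np.interp(np.arange(len(e)), np.flatnonzero(finite), e[finite])
    med = running_median(e, median_window)
    kind = "unfold" if half.phase == "stretch" else "refold"
    n = len(med)
    events: list[RuptureEvent] = []
    i = 0
    while i < n - max_width:
        jumped = None
        for k in range(1, max_width + 1):
            if abs(med[i + k] - med[i]) >= threshold:
                jumped = i + k
                break
        if jumped is None:
            i += 1
            continue
        j = jumped
        if j + persist > n:
            break
        e_before = float(np.median(med[max(0, i - persist + 1) : i + 1]))
        e_after = float(np.median(med[j : j + persist]))
        if abs(e_after - e_before) < threshold:
            i += 1
            continue
        mid = 0.5 * (e_before + e_after)
        sign = np.sign(e_after - e_before)
        if np.any(sign * (med[j : j + persist] - mid) < 0):
            i += 1
            continue
        cross_candidates = np.flatnonzero(sign * (med[i : j + 1] - mid) >= 0)
        cross = i + (int(cross_candidates[0]) if len(cross_candidates) else (j - i))
        events.append(
            RuptureEvent(
                cycle_index=half.cycle_index,
                kind=kind,
                force=float(half.force[cross]),
                e_before=e_before,
                e_after=e_after,
                sample_index=cross,
            )
        )
        i = j + persist
    events.sort(key=lambda ev: ev.force)
    return events


def classify_cycle(
    stretch: HalfCycle,
    events: Sequence[RuptureEvent] | None = None,
    f_max: float = 28.0,
    thresholds: tuple[float, float, float] = (0.15, 0.30, 0.45),
) -> CycleLabel | None:
    """Label a cycle by the lowest running-median E under full load.

    complete: lowest E < 0.15 with an abrupt unfold event; type_I:
    [0.15, 0.30); type_II: [0.30, 0.45); no_unfolding otherwise.
    Cycles that never reach 90% of the maximum force are excluded
    (returns None with a warning).  A gradual decline below 0.15
    without an abrupt event is grouped with type_I (strand-slippage
    pathway).
    """
    if stretch.force.max() < 0.9 * f_max:
        warnings.warn(
            f"{stretch.molecule_id} cycle {stretch.cycle_index} reaches only "
            f"{stretch.force.max():.1f} pN; excluded from classification"
        )
        return None
    if events is None:
        events = detect_rupture(stretch)
    lo, mid, hi = thresholds
    e = stretch.efficiency
    finite = np.isfinite(e)
    med = running_median(e[finite], 5)
    lowest = float(med.min())
    has_abrupt = any(ev.kind == "unfold" for ev in events)
    if lowest < lo:
        label = "complete" if has_abrupt else "type_I"
    elif lowest < mid:
        label = "type_I"
    elif lowest < hi:
        label = "type_II"
    else:
        label = "no_unfolding"
    return CycleLabel(
        molecule_id=stretch.molecule_id,
        cycle_index=stretch.cycle_index,
        label=label,
        lowest_e=lowest,
        events=list(events),
    )


def classify_ensemble(
    cycles: Iterable[PullingCycle],
    corr: CorrectionSpec = CorrectionSpec(),
    f_max: float = 28.0,
) -> tuple[list[CycleLabel], list[tuple[HalfCycle, HalfCycle | None]]]:
    """Segment, detect ruptures and classify a whole cycle collection."""
    halves = segment_cycles(cycles, corr)
    labels = []
    for stretch, relax in halves:
        events = detect_rupture(stretch)
        if relax is not None and not relax.partial and len(relax.efficiency) >= 10:
            events = events + detect_rupture(relax)
        lab = classify_cycle(stretch, events, f_max=f_max)
        if lab is not None:
            labels.append(lab)
    return labels, halves


def switching_stats(
    labels_by_molecule: Mapping[str, Sequence[CycleLabel | str]],
    labels: tuple[str, ...] = LABELS,
) -> SwitchingMatrix:
    """Count ordered consecutive-cycle label pairs per molecule."""
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    n_pairs = 0
    for mol, seq in labels_by_molecule.items():
        names = [s.label if isinstance(s, CycleLabel) else s for s in seq]
        for a, b in zip(names[:-1], names[1:]):
            counts[index[a], index[b]] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise InsufficientDataError("no molecule contributes >= 2 consecutive cycles")
    return SwitchingMatrix(labels=labels, counts=counts)


def mean_E_vs_force(
    halves_by_class: Mapping[str, Sequence[HalfCycle]],
    bin_width: float = 1.0,
    f_range: tuple[float, float] = (0.0, 28.0),
) -> pd.DataFrame:
    """Per-class binned mean E versus force with standard errors.

    Each half-cycle contributes its within-bin mean once; the mean and
    standard error are then taken across cycles, so the SE shrinks as
    1/sqrt(number of cycles).  Bins with no data are omitted; bins with
    one cycle carry an undefined (NaN) SE.
    """
    edges = np.arange(f_range[0], f_range[1] + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for label, halves in halves_by_class.items():
        if len(halves) < 1:
            raise InsufficientDataError(f"class {label}: no cycles")
        per_cycle = np.full((len(halves), len(centers)), np.nan)
        for c, half in enumerate(halves):
            which = np.digitize(half.force, edges) - 1
            ok = (which >= 0) & (which < len(centers)) & np.isfinite(half.efficiency)
            for b in np.unique(which[ok]):
                per_cycle[c, b] = half.efficiency[ok][which[ok] == b].mean()
        for b, fc in enumerate(centers):
            vals = per_cycle[:, b]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "label": label,
                    "force_bin_pN": float(fc),
                    "mean_E": float(vals.mean()),
                    "se_E": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                    "n_cycles": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def rupture_force_table(
    labels: Sequence[CycleLabel],
    class_filter: str | Sequence[str] = "complete",
    kind: str = "unfold",
    f_max: float = 28.0,
) -> tuple[pd.DataFrame, RuptureSamples]:
    """Collect f_unfold (or f_refold) values for the kinetic fit.

    For each selected cycle the largest-delta-E abrupt event of the
    requested kind defines the cycle's rupture force; all events remain
    in the table.  Cycles that stayed folded (``no_unfolding``) enter
    as censored observations at the maximum force, ready for
    :func:`fretforce.dudko_szabo.fit_ds`.
    """
    wanted = {class_filter} if isinstance(class_filter, str) else set(class_filter)
    rows = []
    primary = []
    censored = 0
    for lab in labels:
        if lab.label == "no_unfolding" and kind == "unfold":
            censored += 1
            continue
        if lab.label not in wanted:
            continue
        evs = [ev for ev in lab.events if ev.kind == kind]
        if not evs:
            continue
        best = max(evs, key=lambda ev: ev.delta_e)
        primary.append(best.force)
        for ev in evs:
            rows.append(
                {
                    "molecule_id": lab.molecule_id,
                    "cycle": lab.cycle_index,
                    "kind": ev.kind,
                    "force_pN": ev.force,
                    "delta_E": ev.delta_e,
                    "is_primary": ev is best,
                }
            )
    table = pd.DataFrame(rows, columns=["molecule_id", "cycle", "kind", "force_pN", "delta_E", "is_primary"])
    samples = RuptureSamples(forces=np.asarray(primary), n_censored=censored, f_max=f_max)
    return table, samples
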