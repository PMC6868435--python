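"""Zero-force smFRET pipeline.

Intensity correction and efficiency computation, molecule-level
summaries (first-ten-frame averages), histogramming, donor-only
exclusion, per-variant peak calibration, and constrained Gaussian
mixture decomposition of the folded subpopulations (component centers
and widths fixed, only the weights free).

FRET efficiency is E = I_A' / (I_A' + I_D') with background- and
crosstalk-corrected intensities I_D' = I_D - bg_D and
I_A' = I_A - bg_A - alpha * I_D'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import InsufficientDataError, IntensityTrace

__all__ = [
    "CorrectionSpec",
    "MixtureComponent",
    "MixtureModel",
    "MoleculeSummary",
    "MixtureFit",
    "fret_efficiency",
    "summarize_molecules",
    "summarize_traces",
    "build_histogram",
    "exclude_donor_only",
    "calibrate_components",
    "decompose_mixture",
    "detect_E_transitions",
    "running_median",
]

log = logging.getLogger("fretforce")


@dataclass(frozen=True)
class CorrectionSpec:
    """Background and donor-to-acceptor crosstalk corrections."""

    donor_background: float = 0.0
    acceptor_background: float = 0.0
    crosstalk: float = 0.0  # fraction of corrected donor leaking into acceptor

    def __post_init__(self) -> None:
        if self.donor_background < 0 or self.acceptor_background < 0:
            raise ValueError("backgrounds must be >= 0")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must lie in [0, 1)")


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian subpopulation of the zero-force E histogram."""

    center: float
    width: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.center < 1.2:
            raise ValueError("center must lie in (0, 1.2)")
        if not self.width > 0:
            raise ValueError("width must be > 0")


@dataclass(frozen=True)
class MixtureModel:
    components: tuple[MixtureComponent, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.components) != len(w):
            raise ValueError("components/weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")


@dataclass
class MoleculeSummary:
    """Molecule-level efficiency from the first ten valid frames."""

    molecule_id: str
    e_mean: float
    n_frames_used: int

    def __post_init__(self) -> None:
        if self.n_frames_used > 10 or self.n_frames_used < 1:
            raise ValueError("n_frames_used must be in [1, 10]")
        if not np.isfinite(self.e_mean):
            raise ValueError("e_mean must be finite")


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with edge replication, same length as x."""
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if len(x) < window:
        return np.full_like(x, np.median(x))
    half = window // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    view = np.lib.stride_tricks.sliding_window_view(padded, window)
    return np.median(view, axis=1)


def fret_efficiency(trace: IntensityTrace, corr: CorrectionSpec = CorrectionSpec()) -> np.ndarray:
    """Per-frame FRET efficiency; frames with non-positive total are NaN.

    With zero corrections this is exactly the raw ratio
    I_A / (I_A + I_D).
    """
    i_d = trace.donor - corr.donor_background
    i_a = trace.acceptor - corr.acceptor_background - corr.crosstalk * i_d
    total = i_a + i_d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > 0, i_a / total, np.nan)
    if np.all(np.isnan(e)):
        raise InsufficientDataError(
            f"{trace.molecule_id}: all frames have non-positive corrected intensity"
        )
    return e


def summarize_molecules(
    e_by_molecule: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]],
    n_first: int = 10,
) -> list[MoleculeSummary]:
    """Average the first ``n_first`` valid frames of each molecule."""
    if isinstance(e_by_molecule, Mapping):
        items = e_by_molecule.items()
    else:
        items = e_by_molecule
    out = []
    for mol, e in items:
        valid = np.asarray(e, dtype=float)
        valid = valid[np.isfinite(valid)]
        if len(valid) == 0:
            raise InsufficientDataError(f"{mol}: no valid frames")
        head = valid[:n_first]
        out.append(MoleculeSummary(molecule_id=str(mol), e_mean=float(head.mean()), n_frames_used=len(head)))
    return out


def summarize_traces(
    traces: Sequence[IntensityTrace],
    corr: CorrectionSpec = CorrectionSpec(),
    n_first: int = 10,
) -> list[MoleculeSummary]:
    """Convenience: efficiency + first-frame summary for a trace set."""
    return summarize_molecules(
        ((t.molecule_id, fret_efficiency(t, corr)) for t in traces), n_first=n_first
    )


def build_histogram(
    summaries: Sequence[MoleculeSummary],
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.1, 1.2),
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of molecule-level efficiencies; counts are conserved."""
    if len(summaries) < 1:
        raise InsufficientDataError("no molecule summaries to histogram")
    lo, hi = e_range
    edges = lo + bin_width * np.arange(int(np.ceil((hi - lo) / bin_width)) + 1)
    values = np.clip([s.e_mean for s in summaries], lo, edges[-1] - 1e-12)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def exclude_donor_only(
    summaries: Sequence[MoleculeSummary], threshold: float = 0.1
) -> list[MoleculeSummary]:
    """Drop molecules whose E sits in the acceptor-dark peak near zero."""
    kept = [s for s in summaries if s.e_mean >= threshold]
    log.info(
        "donor-only exclusion at E < %.3g removed %d of %d molecules",
        threshold,
        len(summaries) - len(kept),
        len(summaries),
    )
    return kept


def calibrate_components(
    variant_summaries: Mapping[str, Sequence[MoleculeSummary]],
    min_molecules: int = 30,
    donor_only_threshold: float = 0.1,
) -> list[MixtureComponent]:
    """Fit one Gaussian (MLE: sample mean and sd) per variant's folded peak.

    Each single-position construct (e.g. a G-to-T mutant that pins the
    quadruplex to one register) contributes one labeled component.
    """
    out = []
    for label, summaries in variant_summaries.items():
        kept = exclude_donor_only(summaries, donor_only_threshold)
        if len(kept) < min_molecules:
            raise InsufficientDataError(
                f"construct {label}: {len(kept)} molecules after donor-only "
                f"exclusion; need >= {min_molecules}"
            )
        values = np.array([s.e_mean for s in kept])
        width = float(values.std())
        if width <= 0:
            raise ValueError(f"construct {label}: degenerate zero-width peak")
        out.append(MixtureComponent(center=float(values.mean()), width=width, label=label))
    return out


@dataclass
class MixtureFit:
    """Weights of a fixed-component Gaussian mixture, with uncertainties."""

    components: tuple[MixtureComponent, ...]
    weights: np.ndarray
    weights_se: np.ndarray
    log_likelihood: float
    n_iterations: int
    hard_counts: np.ndarray  # maximum-posterior label counts
    boundary: np.ndarray  # True where a weight collapsed to 0


def decompose_mixture(
    summaries: Sequence[MoleculeSummary],
    components: Sequence[MixtureComponent],
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> MixtureFit:
    """EM for mixture weights with centers and widths held fixed.

    The log-likelihood is asserted non-decreasing at every iteration;
    convergence when the increase falls below ``tol``.  Standard errors
    come from the observed information of the (K-1)-dimensional weight
    parameterization; weights that collapse to zero are reported as
    boundary estimates.
    """
    if len(summaries) == 0:
        raise InsufficientDataError("empty input")
    if len(components) < 2:
        raise ValueError("need >= 2 components")
    centers = np.array([c.center for c in components])
    if len(np.unique(np.round(centers, 12))) != len(centers):
        raise ValueError("component centers must be distinct (identifiability)")
    widths = np.array([c.width for c in components])
    x = np.array([s.e_mean for s in summaries])
    n, K = len(x), len(components)

    # n x K matrix of component densities
    phi = (
        np.exp(-0.5 * ((x[:, None] - centers[None, :]) / widths[None, :]) ** 2)
        / (np.sqrt(2 * np.pi) * widths[None, :])
    )
    w = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        dens = phi @ w
        ll = float(np.sum(np.log(np.maximum(dens, 1e-300))))
        if ll < prev_ll - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev_ll < tol and it > 1:
            break
        prev_ll = ll
        resp = phi * w[None, :] / np.maximum(dens[:, None], 1e-300)
        w = resp.mean(axis=0)
    resp = phi * w[None, :] / np.maximum((phi @ w)[:, None], 1e-300)
    hard = np.bincount(np.argmax(resp, axis=1), minlength=K)

    boundary = w < 1e-6
    se = np.full(K, np.nan)
    free = ~boundary
    if free.sum() >= 2:
        idx = np.flatnonzero(free)
        ref = idx[-1]
        others = idx[:-1]
        dens = phi @ w
        scores = (phi[:, others] - phi[:, [ref]]) / dens[:, None]
        info = scores.T @ scores
        try:
            cov = np.linalg.inv(info)
            se[others] = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se[ref] = float(np.sqrt(max(np.sum(cov), 0.0)))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return MixtureFit(
        components=tuple(components),
        weights=w,
        weights_se=se,
        log_likelihood=prev_ll,
        n_iterations=it,
        hard_counts=hard,
        boundary=boundary,
    )


def detect_E_transitions(
    e: np.ndarray,
    jump_threshold: float = 0.2,
    median_window: int = 3,
    min_persist: int = 3,
) -> tuple[int, list[int]]:
    """Count persistent excursions of the running-median efficiency.

    A transition is a change of the ``median_window``-frame running
    median by more than ``jump_threshold`` that persists for at least
    ``min_persist`` frames; short blinks are rejected by the
    persistence rule.
    """
    e = np.asarray(e, dtype=float)
    if len(e) < 2:
        raise ValueError("series must have length >= 2")
    med = running_median(e[np.isfinite(e)], median_window)
    n = len(med)
    transitions: list[int] = []
    level = med[0]
    i = 1
    while i < n:
        if abs(med[i] - level) > jump_threshold:
            seg = med[i : i + min_persist]
            if len(seg) >= min_persist and np.all(np.abs(seg - level) > jump_threshold):
                transitions.append(i)
                level = float(np.median(seg))
                i += min_persist
                continue
        i += 1
    return len(transitions), transitions
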