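"""Shared data model, tabular trace I/O and result documents.

Traces live in plain TSV files with a one-line header so they stay
diff-able and language-neutral:

* intensity traces: ``molecule_id, frame, donor, acceptor``
* pulling cycles:   ``molecule_id, cycle, t_s, stage_nm, force_pN,
  donor, acceptor, direction``

Result documents are JSON with sorted keys, so two writes of the same
document are byte-identical.  Units are embedded in key names
(e.g. ``dx_dagger_nm``).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KBT_ROOM",
    "GlobalConstants",
    "IntensityTrace",
    "PullingCycle",
    "ResultDocument",
    "SchemaError",
    "TraceValidationError",
    "InsufficientDataError",
    "read_traces",
    "write_traces",
    "read_results",
    "write_results",
    "config_hash",
]

#: Thermal energy in pN*nm at 298 K (assumed room temperature).
KBT_ROOM = 4.11

log = logging.getLogger("fretforce")


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


class TraceValidationError(ValueError):
    """A trace violates a structural invariant (negative counts, ...)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


@dataclass(frozen=True)
class GlobalConstants:
    """Physical constants shared across the pipeline."""

    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        if not self.kBT > 0:
            raise ValueError(f"kBT must be positive, got {self.kBT}")


@dataclass
class IntensityTrace:
    """Two-channel photon-count time trace for one molecule.

    Donor and acceptor are counts per camera frame; ``frame_interval``
    is the integration time per frame in seconds (30 ms in the TIRF
    experiments this models).
    """

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise TraceValidationError(f"{self.molecule_id}: channel series must be 1-D")
        if len(self.donor) != len(self.acceptor) or len(self.donor) < 1:
            raise TraceValidationError(
                f"{self.molecule_id}: donor/acceptor must have equal length >= 1"
            )
        if not self.frame_interval > 0:
            raise TraceValidationError(f"{self.molecule_id}: frame_interval must be > 0")
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise TraceValidationError(f"{self.molecule_id}: negative counts")

    @property
    def n_frames(self) -> int:
        return len(self.donor)


@dataclass
class PullingCycle:
    """One stretch-relax cycle of the fluorescence-force experiment.

    Per-sample time, absolute stage position (nm from the trap origin),
    force, channel counts and a stretch/relax direction flag, at the
    20 ms sampling of the instrument.
    """

    molecule_id: str
    cycle_index: int
    time: np.ndarray
    stage_position: np.ndarray
    force: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "stage_position", "force", "donor", "acceptor"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.direction = np.asarray(self.direction, dtype=object)
        n = len(self.time)
        for name in ("stage_position", "force", "donor", "acceptor", "direction"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError(
                    f"{self.molecule_id} cycle {self.cycle_index}: ragged columns"
                )
        if n < 2 or np.any(np.diff(self.time) <= 0):
            raise TraceValidationError(
                f"{self.molecule_id} cycle {self.cycle_index}: time not strictly increasing"
            )
        if np.any(self.force < 0):
            raise TraceValidationError(
                f"{self.molecule_id} cycle {self.cycle_index}: negative force"
            )
        if np.any(self.donor < 0) or np.any(self.acceptor < 0):
            raise TraceValidationError(
                f"{self.molecule_id} cycle {self.cycle_index}: negative counts"
            )
        bad = set(self.direction) - {"stretch", "relax"}
        if bad:
            raise TraceValidationError(
                f"{self.molecule_id} cycle {self.cycle_index}: bad direction flags {bad}"
            )
        is_relax = self.direction == "relax"
        if is_relax.any():
            first_relax = int(np.argmax(is_relax))
            if np.any(self.direction[first_relax:] == "stretch"):
                raise TraceValidationError(
                    f"{self.molecule_id} cycle {self.cycle_index}: "
                    "stretch samples must precede relax samples"
                )

    @property
    def n_samples(self) -> int:
        return len(self.time)


INTENSITY_COLUMNS = ("molecule_id", "frame", "donor", "acceptor")
PULLING_COLUMNS = (
    "molecule_id",
    "cycle",
    "t_s",
    "stage_nm",
    "force_pN",
    "donor",
    "acceptor",
    "direction",
)


def read_traces(
    path: str | Path,
    kind: str,
    frame_interval: float = 0.03,
) -> list[IntensityTrace] | list[PullingCycle]:
    """Read a trace TSV and return validated, typed records.

    ``kind`` is ``"intensity"`` or ``"pulling"``.  Molecules are grouped
    by ``molecule_id`` (and cycle index for pulling data) in file order.
    Missing columns raise :class:`SchemaError`; invariant violations
    raise :class:`TraceValidationError` citing the molecule.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = INTENSITY_COLUMNS if kind == "intensity" else PULLING_COLUMNS
    if kind not in ("intensity", "pulling"):
        raise ValueError(f"unknown trace kind {kind!r}")
    for col in required:
        if col not in table.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")

    records: list = []
    if kind == "intensity":
        for mol, grp in table.groupby("molecule_id", sort=False):
            grp = grp.sort_values("frame")
            records.append(
                IntensityTrace(
                    molecule_id=str(mol),
                    frame_interval=frame_interval,
                    donor=grp["donor"].to_numpy(),
                    acceptor=grp["acceptor"].to_numpy(),
                )
            )
    else:
        for (mol, cyc), grp in table.groupby(["molecule_id", "cycle"], sort=False):
            records.append(
                PullingCycle(
                    molecule_id=str(mol),
                    cycle_index=int(cyc),
                    time=grp["t_s"].to_numpy(),
                    stage_position=grp["stage_nm"].to_numpy(),
                    force=grp["force_pN"].to_numpy(),
                    donor=grp["donor"].to_numpy(),
                    acceptor=grp["acceptor"].to_numpy(),
                    direction=grp["direction"].to_numpy(),
                )
            )
    log.info("read %d %s record(s) from %s", len(records), kind, path)
    return records


def write_traces(records: Sequence[IntensityTrace] | Sequence[PullingCycle], path: str | Path) -> None:
    """Write traces to TSV; the reader/writer pair is a lossless round trip."""
    path = Path(path)
    frames = []
    for rec in records:
        if isinstance(rec, IntensityTrace):
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": rec.molecule_id,
                        "frame": np.arange(rec.n_frames),
                        "donor": rec.donor,
                        "acceptor": rec.acceptor,
                    }
                )
            )
        elif isinstance(rec, PullingCycle):
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": rec.molecule_id,
                        "cycle": rec.cycle_index,
                        "t_s": rec.time,
                        "stage_nm": rec.stage_position,
                        "force_pN": rec.force,
                        "donor": rec.donor,
                        "acceptor": rec.acceptor,
                        "direction": rec.direction,
                    }
                )
            )
        else:  # pragma: no cover - defensive
            raise TypeError(f"cannot serialize {type(rec)}")
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


@dataclass
class ResultDocument:
    """Serializable record of one pipeline stage's output.

    ``parameters`` holds estimates (units in the key names);
    ``provenance`` records input files, seeds and the configuration
    hash, so a run can be reproduced from the document alone.
    """

    stage: str
    parameters: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, allow_nan=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ResultDocument":
        payload = json.loads(text)
        return cls(**payload)


def write_results(doc: ResultDocument, path: str | Path) -> None:
    """Write a result document as canonical JSON (fixed key order)."""
    Path(path).write_text(doc.to_json())


def read_results(path: str | Path) -> ResultDocument:
    return ResultDocument.from_json(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable SHA-256 hash of a configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()
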