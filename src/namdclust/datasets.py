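"""Ingestion of surface-hopping trajectory ensembles.

A trajectory ensemble lives in a root directory containing subdirectories
``TRAJ1 ... TRAJn``.  Each subdirectory holds

* a concatenated-XYZ geometry series (``dyn.xyz``): repeated blocks of
  atom-count line, comment line carrying ``time = <float> fs``, atom lines;
* a per-frame property table (``properties.csv``) with canonical columns
  ``traj,time,State,Total_Energy,S1[,S2,...],DE21,Hops_S21,Hops_S12,
  Pop1,Pop2[,f_osc_21]``.

An optional single-frame ``geom.xyz`` at the root is the reference geometry
(typically the ground-state minimum) used for RMSD analysis.

Frames are indexed by ``(traj, time)`` with times in femtoseconds; geometry
and property records are merged by an inner join with a 1e-6 fs tolerance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataError,
    EmptyEnsembleError,
    FrameLookupError,
    ParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: absolute tolerance (fs) when matching frame times across tables
TIME_TOL = 1e-6

#: canonical geometry-series filename inside each TRAJ directory
GEOMETRY_FILENAME = "dyn.xyz"

#: canonical property-table filename inside each TRAJ directory
PROPERTIES_FILENAME = "properties.csv"

#: mandatory property columns (at least one state energy S1 additionally)
MANDATORY_PROPERTY_COLUMNS = ("State", "Total_Energy")

_TRAJ_PATTERN = re.compile(r"^TRAJ(\d+)$")
_TIME_PATTERN = re.compile(r"time\s*=\s*([-+0-9.eEdD]+)")


def _round_time(t: float) -> float:
    """Canonical frame-time key: rounded to the merge tolerance."""
    return round(float(t), 6)


@dataclass(frozen=True)
class Geometry:
    """A molecular geometry: element labels plus Cartesian coordinates in Å."""

    labels: tuple[str, ...]
    coords: np.ndarray  # shape (n_atoms, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DataError(f"coords must have shape (n_atoms, 3), got {coords.shape}")
        if len(self.labels) != coords.shape[0]:
            raise DataError(
                f"{len(self.labels)} labels but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 1:
            raise DataError("a geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise DataError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.labels, coords)


@dataclass
class EnsembleDataset:
    """Merged ensemble of trajectory frames.

    ``geometries`` maps ``(traj, time)`` to :class:`Geometry`;
    ``properties`` is a DataFrame indexed by the same ``(traj, time)`` keys
    (sorted), one row per frame.  All frames share one atom-label sequence.
    """

    geometries: dict[tuple[int, float], Geometry]
    properties: pd.DataFrame
    atom_labels: tuple[str, ...]
    reference: Geometry | None = None

    @property
    def keys(self) -> list[tuple[int, float]]:
        return list(self.properties.index)

    @property
    def n_frames(self) -> int:
        return len(self.properties)

    @property
    def n_trajs(self) -> int:
        return len({traj for traj, _ in self.properties.index})

    def select_frame(self, traj: int, time: float) -> Geometry:
        """Return the geometry of trajectory ``traj`` at ``time`` fs.

        Times are matched within :data:`TIME_TOL`; a missing key raises
        :class:`FrameLookupError` reporting the nearest available time.
        """
        key = (int(traj), _round_time(time))
        if key in self.geometries:
            return self.geometries[key]
        times = np.array([t for tr, t in self.geometries if tr == int(traj)])
        if times.size == 0:
            raise FrameLookupError(f"no frames for trajectory {traj}")
        nearest = times[np.argmin(np.abs(times - time))]
        if abs(nearest - time) <= TIME_TOL:
            return self.geometries[(int(traj), _round_time(nearest))]
        raise FrameLookupError(
            f"no frame at (traj={traj}, time={time} fs); nearest available "
            f"time is {nearest} fs"
        )


def discover_trajectories(root_dir: str | Path) -> list[int]:
    """Return sorted integer ids of TRAJ<k> subdirectories holding a geometry series.

    Non-matching directory names are ignored with a log line; a TRAJ<k>
    directory without a geometry file is skipped.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise DataError(f"root directory does not exist: {root}")
    ids: list[int] = []
    for child in sorted(root.iterdir()):
        if not child.is_dir():
            continue
        m = _TRAJ_PATTERN.match(child.name)
        if m is None:
            logger.info("ignoring non-trajectory directory %s", child.name)
            continue
        if not (child / GEOMETRY_FILENAME).is_file():
            logger.info("skipping %s: no %s", child.name, GEOMETRY_FILENAME)
            continue
        ids.append(int(m.group(1)))
    return sorted(ids)


def read_xyz_trajectory(path: str | Path) -> list[tuple[float, Geometry]]:
    """Parse a concatenated-XYZ geometry series.

    Every block starts with the atom count, then a comment line carrying the
    time stamp as ``time = <float> fs``, then one ``element x y z`` line per
    atom (coordinates in Å).  All frames must share the same atom count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[tuple[float, Geometry]] = []
    pos = 0
    frame_idx = 0
    n_expected: int | None = None
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}: frame {frame_idx}: malformed atom-count line "
                f"{lines[pos]!r}"
            ) from exc
        if n_expected is None:
            n_expected = n_atoms
        elif n_atoms != n_expected:
            raise ParseError(
                f"{path}: frame {frame_idx} declares {n_atoms} atoms, "
                f"previous frames had {n_expected}"
            )
        if pos + 1 + n_atoms >= len(lines) + 1 and pos + 1 + n_atoms > len(lines):
            raise ParseError(f"{path}: frame {frame_idx}: truncated block")
        comment = lines[pos + 1]
        m = _TIME_PATTERN.search(comment)
        if m is None:
            raise ParseError(
                f"{path}: frame {frame_idx}: comment line lacks a "
                f"'time = <float> fs' stamp: {comment!r}"
            )
        time_fs = float(m.group(1).replace("d", "e").replace("D", "e"))
        labels: list[str] = []
        coords = np.empty((n_atoms, 3))
        for i in range(n_atoms):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame_idx}: malformed atom line "
                    f"{lines[pos + 2 + i]!r}"
                )
            labels.append(parts[0])
            try:
                coords[i] = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: frame {frame_idx}: unparseable coordinate in "
                    f"{lines[pos + 2 + i]!r}"
                ) from exc
        frames.append((time_fs, Geometry(tuple(labels), coords)))
        pos += 2 + n_atoms
        frame_idx += 1
    return frames


def read_xyz(path: str | Path) -> Geometry:
    """Read a single-frame XYZ file (the comment line may carry anything)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        n_atoms = int(lines[0].strip())
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed atom-count line") from exc
    labels, coords = [], np.empty((n_atoms, 3))
    for i in range(n_atoms):
        parts = lines[2 + i].split()
        labels.append(parts[0])
        coords[i] = [float(x) for x in parts[1:4]]
    return Geometry(tuple(labels), coords)


def write_xyz_trajectory(
    path: str | Path, frames: Iterable[tuple[float, Geometry]]
) -> None:
    """Write a concatenated-XYZ series in the layout :func:`read_xyz_trajectory` reads."""
    with open(path, "w") as fh:
        for time_fs, geom in frames:
            fh.write(f"{geom.n_atoms}\n")
            fh.write(f"time = {time_fs:.4f} fs\n")
            for lab, (x, y, z) in zip(geom.labels, geom.coords):
                fh.write(f"{lab:<3s} {x:16.10f} {y:16.10f} {z:16.10f}\n")


def read_properties(traj_dir: str | Path) -> pd.DataFrame:
    """Read the per-frame property table of one trajectory directory.

    Returns a DataFrame with a ``time`` column (fs) and the canonical
    property columns.  Hop flags (``Hops_S21``/``Hops_S12``) use 0 for
    no-hop and 1 for a hop at that frame; missing flag columns are treated
    as all-zero.
    """
    traj_dir = Path(traj_dir)
    path = traj_dir / PROPERTIES_FILENAME
    if not path.is_file():
        raise DataError(f"property table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_PROPERTY_COLUMNS if c not in df.columns]
    if "time" not in df.columns:
        missing.append("time")
    if not any(re.fullmatch(r"S\d+", c) for c in df.columns):
        missing.append("S1")
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory columns: {', '.join(sorted(missing))}"
        )
    for flag in ("Hops_S21", "Hops_S12"):
        if flag not in df.columns:
            df[flag] = 0
        bad = ~df[flag].isin((0, 1))
        if bad.any():
            raise SchemaError(f"{path}: column {flag} must contain only 0/1")
    for col in df.columns:
        if col.startswith("Pop"):
            vals = df[col].to_numpy(dtype=float)
            if np.any((vals < -1e-9) | (vals > 1 + 1e-9)):
                raise SchemaError(f"{path}: population column {col} outside [0, 1]")
    df["time"] = df["time"].map(_round_time)
    return df


def assemble_ensemble(
    geoms: Mapping[int, Sequence[tuple[float, Geometry]]],
    props: Mapping[int, pd.DataFrame],
    reference: Geometry | None = None,
) -> EnsembleDataset:
    """Merge per-trajectory geometry series and property tables.

    Inner join on ``(traj, time)`` with :data:`TIME_TOL` tolerance; frames
    present on only one side are dropped (count logged).  All geometries
    must share one atom-label sequence.
    """
    geom_map: dict[tuple[int, float], Geometry] = {}
    atom_labels: tuple[str, ...] | None = None
    for traj, series in geoms.items():
        for time_fs, geom in series:
            if atom_labels is None:
                atom_labels = geom.labels
            elif geom.labels != atom_labels:
                raise DataError(
                    f"trajectory {traj} at {time_fs} fs: atom labels differ "
                    f"from the ensemble's"
                )
            geom_map[(int(traj), _round_time(time_fs))] = geom

    prop_rows = []
    for traj, df in props.items():
        df = df.copy()
        df["traj"] = int(traj)
        df["time"] = df["time"].map(_round_time)
        prop_rows.append(df)
    prop_df = (
        pd.concat(prop_rows, ignore_index=True)
        if prop_rows
        else pd.DataFrame(columns=["traj", "time"])
    )
    prop_df = prop_df.set_index(["traj", "time"]).sort_index()

    keys = sorted(set(geom_map) & set(prop_df.index))
    dropped = (len(geom_map) - len(keys)) + (len(prop_df) - len(keys))
    if dropped:
        logger.warning("dropped %d frames missing from one side of the join", dropped)
    if not keys:
        raise EmptyEnsembleError("no frames survived the geometry/property join")
    merged = prop_df.loc[keys]
    merged = merged[~merged.index.duplicated()]
    geometries = {k: geom_map[k] for k in keys}
    if reference is not None and atom_labels is not None:
        if reference.labels != atom_labels:
            raise DataError("reference geometry atom labels differ from ensemble's")
    return EnsembleDataset(
        geometries=geometries,
        properties=merged,
        atom_labels=atom_labels or (),
        reference=reference,
    )


def load_ensemble(root_dir: str | Path) -> EnsembleDataset:
    """Discover, parse, and merge all trajectories under ``root_dir``.

    Reads ``geom.xyz`` at the root as the reference geometry when present.
    """
    root = Path(root_dir)
    ids = discover_trajectories(root)
    if not ids:
        raise EmptyEnsembleError(f"no TRAJ<k> directories with geometries in {root}")
    geoms: dict[int, list[tuple[float, Geometry]]] = {}
    props: dict[int, pd.DataFrame] = {}
    for traj in ids:
        traj_dir = root / f"TRAJ{traj}"
        geoms[traj] = read_xyz_trajectory(traj_dir / GEOMETRY_FILENAME)
        props[traj] = read_properties(traj_dir)
    ref_path = root / "geom.xyz"
    reference = read_xyz(ref_path) if ref_path.is_file() else None
    return assemble_ensemble(geoms, props, reference=reference)


def write_dataset_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a frame-indexed table as CSV with ``traj,time`` leading columns.

    Floats are printed with 6 decimals so a write/read round trip is the
    identity to 1e-6.
    """
    df = table.copy()
    if isinstance(df.index, pd.MultiIndex):
        df = df.reset_index()
        df.columns = ["traj", "time", *df.columns[2:]]
    cols = list(df.columns)
    if cols[:2] != ["traj", "time"]:
        raise DataError("table must be keyed by leading (traj, time) columns")
    df.to_csv(path, index=False, float_format="%.6f")


def read_dataset_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_dataset_csv`, restoring the frame index."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["traj", "time"]:
        raise SchemaError(f"{path}: expected leading traj,time columns")
    df["traj"] = df["traj"].astype(int)
    return df.set_index(["traj", "time"]).sort_index()
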