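"""Synthetic surface-hopping ensembles with planted structure.

The generator writes the same on-disk layout the ingestion module reads
(``TRAJ<k>/dyn.xyz`` + ``TRAJ<k>/properties.csv`` + a root ``geom.xyz``)
from closed-form kinematic trajectories, so every pipeline stage can be
tested against exact ground truth without any external dataset:

* a harmonic **stretch** of one bond (the analogue of the ring–CH2 bond of
  a fulvene-like chromophore) moves a rigid atom group along the bond axis;
* a harmonic **torsion** rotates part of the molecule about that bond in a
  configurable fraction of trajectories;
* latent **conformer classes** are planted per trajectory as static bond /
  torsion offsets, mimicking compact, bond-stretched and 90°-rotated
  populations;
* **hop flags** mark frames where the oscillatory part of the stretched
  bond is within δ of its per-cycle maximum — the geometry where real
  surface-hopping trajectories reach the intersection seam — with hop
  events alternating forward/back across successive cycles;
* the **energy gap** is linear in the bond stretch with Gaussian noise,
  gap = g0 − a·s(t) + ε, so stretched classes carry distinctly smaller gaps.

Ground-truth class labels and hop keys are written to ``truth.json``.
Trajectories are kinematic rather than integrated dynamics: the planted
structure is exact and free of numerical drift.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Geometry, write_xyz_trajectory
from .exceptions import ConfigError, DataError

__all__ = [
    "StretchMode",
    "TorsionMode",
    "ClassSpec",
    "SynthConfig",
    "make_template",
    "simulate_ensemble",
    "ground_truth",
]


# ---------------------------------------------------------------------------
# molecular templates
# ---------------------------------------------------------------------------

def make_template(name: str, n: int | None = None) -> Geometry:
    """Deterministic template geometries.

    ``fulvene_like``
        12 atoms: a planar five-membered carbon ring with an exocyclic CH2
        group (atom order: ring C0–C4, exocyclic C5, ring H6–H9, CH2
        H10–H11).
    ``ring6_planar``
        ideal planar hexagon of carbons, side 1.4 Å.
    ``chain`` / ``chain(n)``
        an n-atom zig-zag carbon chain (default n = 4).
    """
    m = re.fullmatch(r"chain\((\d+)\)", name)
    if m:
        name, n = "chain", int(m.group(1))
    if name == "fulvene_like":
        return _fulvene_like()
    if name == "ring6_planar":
        angles = np.arange(6) * math.pi / 3.0
        radius = 1.4  # hexagon side == circumradius
        coords = np.stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1
        )
        return Geometry(("C",) * 6, coords)
    if name == "chain":
        n = 4 if n is None else int(n)
        if n < 2:
            raise ConfigError("chain template needs n >= 2")
        coords = np.zeros((n, 3))
        for i in range(n):
            # zig-zag with 1.5 Å steps; never collinear
            coords[i] = [1.2 * i, 0.9 * (i % 2), 0.1 * (i % 3)]
        return Geometry(("C",) * n, coords)
    raise ConfigError(f"unknown template {name!r}")


def _fulvene_like() -> Geometry:
    ring_r = 1.4 / (2.0 * math.sin(math.pi / 5.0))  # pentagon side 1.4 Å
    angles = np.arange(5) * 2.0 * math.pi / 5.0
    ring = np.stack(
        [ring_r * np.cos(angles), ring_r * np.sin(angles), np.zeros(5)], axis=1
    )
    c5 = ring[0] + np.array([1.35, 0.0, 0.0])  # exocyclic carbon along +x
    ring_h = []
    for i in range(1, 5):
        u = ring[i] / np.linalg.norm(ring[i])
        ring_h.append(ring[i] + 1.08 * u)
    h_a = c5 + 1.08 * np.array([math.cos(math.pi / 3), math.sin(math.pi / 3), 0.0])
    h_b = c5 + 1.08 * np.array([math.cos(-math.pi / 3), math.sin(-math.pi / 3), 0.0])
    coords = np.vstack([ring, c5, np.array(ring_h), h_a, h_b])
    labels = ("C",) * 6 + ("H",) * 6
    return Geometry(labels, coords)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StretchMode:
    """Harmonic stretch of bond (i, j): the ``moving`` atoms translate along
    the i→j axis by s(t) = offset + amplitude·(1 − cos(2πt/period + φ))/2."""

    bond: tuple[int, int] = (0, 5)
    amplitude: float = 0.25  # Å, peak oscillatory elongation
    period: float = 15.0  # fs
    moving: tuple[int, ...] = (5, 10, 11)


@dataclass(frozen=True)
class TorsionMode:
    """Harmonic torsion about the stretch bond axis applied to ``moving``
    atoms, active in a ``fraction`` of trajectories."""

    quad: tuple[int, int, int, int] = (1, 0, 5, 10)
    amplitude: float = 20.0  # degrees
    period: float = 30.0  # fs
    fraction: float = 0.3
    moving: tuple[int, ...] = (10, 11)


@dataclass(frozen=True)
class ClassSpec:
    """A latent conformer class: its share of trajectories and its static
    geometric signature (bond elongation in Å, torsion offset in degrees)."""

    proportion: float
    bond_offset: float = 0.0
    torsion_offset: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic ensemble.

    Defaults mirror a walkthrough-scale surface-hopping set: 50
    trajectories of 60 fs at a 0.1 fs step, a fulvene-like 12-atom
    molecule, three conformer classes (compact / bond-stretched /
    90°-rotated, the rotated class rare), hops flagged within
    ``hop_delta`` Å of each stretch-cycle maximum, and a gap model
    gap(eV) = gap0 − gap_slope·stretch + N(0, gap_noise²).
    """

    template: str = "fulvene_like"
    n_trajs: int = 50
    n_steps: int = 600  # frames beyond t=0; 60 fs at dt=0.1
    dt: float = 0.1  # fs
    stretch: StretchMode = field(default_factory=StretchMode)
    torsion: TorsionMode = field(default_factory=TorsionMode)
    hop_delta: float = 0.005  # Å window below the per-cycle stretch maximum
    gap0: float = 3.8  # eV, gap at the unstretched reference
    gap_slope: float = 4.5  # eV/Å
    gap_noise: float = 0.1  # eV
    classes: tuple[ClassSpec, ...] = (
        ClassSpec(0.45, 0.0, 0.0),
        ClassSpec(0.45, 0.35, 0.0),
        ClassSpec(0.10, 0.0, 90.0),
    )
    noise: float = 0.02  # Å, per-coordinate Gaussian jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.stretch.amplitude < 0 or self.torsion.amplitude < 0:
            raise ConfigError("mode amplitudes must be non-negative")
        total = sum(c.proportion for c in self.classes)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"class proportions must sum to 1, got {total}")

    @classmethod
    def well_separated(
        cls, seed: int = 0, n_trajs: int = 15, n_steps: int = 80
    ) -> "SynthConfig":
        """Three conformer classes separated far beyond the within-class spread.

        The class signatures (0.6 Å bond elongation; 90° torsion) dwarf the
        within-class variation (0.08 Å oscillation amplitude, 0.02 Å
        coordinate jitter), giving a separation of well over five
        within-class standard deviations in descriptor space — the regime
        where every clustering algorithm should recover the planted
        partition essentially perfectly.
        """
        return cls(
            n_trajs=n_trajs,
            n_steps=n_steps,
            dt=0.1,
            stretch=StretchMode(amplitude=0.08, period=15.0),
            torsion=TorsionMode(fraction=0.0),
            classes=(
                ClassSpec(0.4, 0.0, 0.0),
                ClassSpec(0.4, 0.6, 0.0),
                ClassSpec(0.2, 0.0, 90.0),
            ),
            noise=0.02,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _rotate_about_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rodrigues rotation of points about a line through ``origin``."""
    u = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    p = coords - origin
    return (
        origin
        + p * c
        + np.cross(u, p) * s
        + np.outer(p @ u, u) * (1.0 - c)
    )


def _frame_geometry(
    template: Geometry,
    cfg: SynthConfig,
    stretch_value: float,
    torsion_value: float,
    jitter: np.ndarray,
) -> Geometry:
    coords = template.coords.copy()
    i, j = cfg.stretch.bond
    axis = template.coords[j] - template.coords[i]
    axis = axis / np.linalg.norm(axis)
    if torsion_value != 0.0:
        moving = list(cfg.torsion.moving)
        coords[moving] = _rotate_about_axis(
            coords[moving], template.coords[i], axis, torsion_value
        )
    if stretch_value != 0.0:
        coords[list(cfg.stretch.moving)] += stretch_value * axis
    return Geometry(template.labels, coords + jitter)


def simulate_ensemble(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write a synthetic ensemble under ``out_dir`` and return its path.

    Produces ``TRAJ1..TRAJn`` (each with ``dyn.xyz`` and
    ``properties.csv``), the reference ``geom.xyz`` (the unperturbed
    template), and ``truth.json`` holding the planted per-trajectory class
    labels and the hop frame keys.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    template = make_template(cfg.template)
    n_atoms = template.n_atoms
    for group in (cfg.stretch.moving, cfg.torsion.moving, cfg.stretch.bond):
        if any(not 0 <= a < n_atoms for a in group):
            raise ConfigError("mode atom indices outside the template")

    rng = np.random.default_rng(cfg.seed)
    proportions = np.array([c.proportion for c in cfg.classes])
    class_of_traj = {
        traj: int(rng.choice(len(cfg.classes), p=proportions))
        for traj in range(1, cfg.n_trajs + 1)
    }
    torsion_active = {
        traj: bool(rng.random() < cfg.torsion.fraction)
        for traj in range(1, cfg.n_trajs + 1)
    }
    times = np.round(np.arange(cfg.n_steps + 1) * cfg.dt, 6)
    hop_keys: list[tuple[int, float]] = []

    for traj in range(1, cfg.n_trajs + 1):
        cls = cfg.classes[class_of_traj[traj]]
        phase_s = float(rng.uniform(0.0, 2.0 * math.pi))
        phase_t = float(rng.uniform(0.0, 2.0 * math.pi))
        # oscillatory stretch s_osc in [0, amplitude]
        theta = 2.0 * math.pi * times / cfg.stretch.period + phase_s
        s_osc = cfg.stretch.amplitude * 0.5 * (1.0 - np.cos(theta))
        stretch = cls.bond_offset + s_osc
        torsion = np.full_like(times, cls.torsion_offset)
        if torsion_active[traj] and cfg.torsion.amplitude > 0:
            torsion = torsion + cfg.torsion.amplitude * np.sin(
                2.0 * math.pi * times / cfg.torsion.period + phase_t
            )
        # hop rule: within hop_delta of the per-cycle oscillation maximum,
        # alternating forward/back hops across successive cycles
        near_max = s_osc >= cfg.stretch.amplitude - cfg.hop_delta
        cycle = np.floor((theta - math.pi) / (2.0 * math.pi) + 0.5).astype(int)
        hop_fwd = np.zeros_like(times, dtype=int)
        hop_back = np.zeros_like(times, dtype=int)
        for idx in np.nonzero(near_max)[0]:
            if cycle[idx] % 2 == 0:
                hop_fwd[idx] = 1
            else:
                hop_back[idx] = 1
            hop_keys.append((traj, float(times[idx])))

        gap = cfg.gap0 - cfg.gap_slope * stretch + rng.normal(
            0.0, cfg.gap_noise, size=times.shape
        )
        gap = np.clip(gap, 0.01, None)
        s1 = -230.0 + 0.002 * rng.standard_normal(times.shape)
        s2 = s1 + gap / 27.211386  # eV -> hartree
        pop2 = np.clip(1.0 - times / (2.0 * times[-1] if times[-1] > 0 else 1.0), 0, 1)
        pop1 = 1.0 - pop2
        state = np.where(pop2 >= 0.5, 2, 1)

        frames = []
        for f, t in enumerate(times):
            jitter = rng.normal(0.0, cfg.noise, size=(n_atoms, 3))
            frames.append(
                (
                    float(t),
                    _frame_geometry(
                        template, cfg, float(stretch[f]), float(torsion[f]), jitter
                    ),
                )
            )
        traj_dir = out / f"TRAJ{traj}"
        traj_dir.mkdir(exist_ok=True)
        write_xyz_trajectory(traj_dir / "dyn.xyz", frames)
        pd.DataFrame(
            {
                "traj": traj,
                "time": times,
                "State": state,
                "Total_Energy": -230.5 + 0.0005 * rng.standard_normal(times.shape),
                "S1": s1,
                "S2": s2,
                "DE21": gap,
                "Hops_S21": hop_fwd,
                "Hops_S12": hop_back,
                "Pop1": pop1,
                "Pop2": pop2,
            }
        ).to_csv(traj_dir / "properties.csv", index=False, float_format="%.8f")

    write_xyz_trajectory(out / "_ref_tmp.xyz", [(0.0, template)])
    (out / "_ref_tmp.xyz").rename(out / "geom.xyz")
    truth = {
        "class_of_traj": {str(k): v for k, v in class_of_traj.items()},
        "torsion_active": {str(k): v for k, v in torsion_active.items()},
        "hops": [[traj, t] for traj, t in hop_keys],
        "config": {
            "template": cfg.template,
            "n_trajs": cfg.n_trajs,
            "n_steps": cfg.n_steps,
            "dt": cfg.dt,
            "seed": cfg.seed,
            "classes": [asdict(c) for c in cfg.classes],
            "stretch": asdict(cfg.stretch),
            "torsion": asdict(cfg.torsion),
            "hop_delta": cfg.hop_delta,
            "gap0": cfg.gap0,
            "gap_slope": cfg.gap_slope,
            "gap_noise": cfg.gap_noise,
            "noise": cfg.noise,
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out


def ground_truth(out_dir: str | Path) -> dict:
    """Load the planted ground truth written by :func:`simulate_ensemble`.

    Returns a dict with ``class_of_traj`` (int → class index), ``hops``
    (list of (traj, time) keys) and the generating ``config``.
    """
    path = Path(out_dir) / "truth.json"
    if not path.is_file():
        raise DataError(f"ground-truth file not found: {path}")
    raw = json.loads(path.read_text())
    raw["class_of_traj"] = {int(k): int(v) for k, v in raw["class_of_traj"].items()}
    raw["hops"] = [(int(t), float(x)) for t, x in raw["hops"]]
    return raw


def frame_class_labels(keys, class_of_traj: dict[int, int]) -> np.ndarray:
    """Planted class label per frame key (a frame inherits its trajectory's class)."""
    return np.array([class_of_traj[int(traj)] for traj, _ in keys], dtype=int)
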