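"""Translation/rotation-invariant geometric descriptors.

Four descriptor families turn a Cartesian geometry into a fixed-length
vector suitable for embedding and clustering:

* **R2**: the strict lower triangle of the interatomic Euclidean distance
  matrix, flattened row-major; variants ``inverse`` (1/R), ``delta``
  (R(t) − R(ref)) and ``re`` (R(ref)/R(t)).
* **Z-matrix**: internal coordinates — bond lengths (Å), bond angles and
  dihedrals (degrees) over a connectivity chain; plus a delta variant
  against a reference with optional tanh/sigmoid squashing.
* **Cremer–Pople**: generalized ring-puckering coordinates (amplitudes
  q_m, phases φ_m; total amplitude Q and spherical angles θ, φ for
  six-membered rings).
* **SOAP** (see :mod:`namdclust.soap`).

:func:`descriptor_dataset` applies one family uniformly over an ensemble
and returns a frame-indexed feature table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import EnsembleDataset, Geometry
from .exceptions import ConfigError, DataError

__all__ = [
    "pairwise_distance_vector",
    "pairwise_distance_names",
    "r2_variant",
    "bond_angle",
    "dihedral_angle",
    "ZMatrixRecord",
    "default_connectivity",
    "zmatrix",
    "zmatrix_to_cartesian",
    "zmatrix_names",
    "delta_zmatrix",
    "PuckeringParams",
    "cremer_pople",
    "descriptor_dataset",
    "DESCRIPTOR_CHOICES",
]


# ---------------------------------------------------------------------------
# R2 family
# ---------------------------------------------------------------------------

def pairwise_distance_vector(g: Geometry) -> np.ndarray:
    """All pairwise interatomic distances, strict lower triangle row-major.

    For n atoms the vector has length n(n−1)/2, ordered
    (1,0), (2,0), (2,1), (3,0), ... — i.e. rows i of the distance matrix,
    columns j < i.
    """
    if g.n_atoms < 2:
        raise DataError("pairwise distances need at least 2 atoms")
    diff = g.coords[:, None, :] - g.coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    i, j = np.tril_indices(g.n_atoms, k=-1)
    return dmat[i, j]


def pairwise_distance_names(n_atoms: int) -> list[str]:
    """Column names ``R_i_j`` (i > j, 0-based) matching the R2 vector order."""
    i, j = np.tril_indices(n_atoms, k=-1)
    return [f"R_{a}_{b}" for a, b in zip(i, j)]


def r2_variant(
    v: np.ndarray, v_ref: np.ndarray | None, variant: str
) -> np.ndarray:
    """Feature-engineered variants of an R2 vector.

    ``inverse`` → 1/R; ``delta`` → R(t) − R(ref); ``re`` → R(ref)/R(t).
    """
    v = np.asarray(v, dtype=float)
    if variant == "inverse":
        if np.any(v <= 0):
            raise DataError("inverse variant requires strictly positive distances")
        return 1.0 / v
    if variant in ("delta", "re"):
        if v_ref is None:
            raise ConfigError(f"variant {variant!r} requires a reference vector")
        v_ref = np.asarray(v_ref, dtype=float)
        if v.shape != v_ref.shape:
            raise DataError("R2 vector and reference have different lengths")
        if variant == "delta":
            return v - v_ref
        if np.any(v <= 0):
            raise DataError("re variant requires strictly positive distances")
        return v_ref / v
    raise ConfigError(f"unknown R2 variant {variant!r}")


# ---------------------------------------------------------------------------
# internal coordinates
# ---------------------------------------------------------------------------

def bond_angle(g: Geometry, i: int, j: int, k: int) -> float:
    """Angle i–j–k with vertex at j, in degrees within [0, 180]."""
    if len({i, j, k}) != 3:
        raise DataError("bond angle needs three distinct atoms")
    u = g.coords[i] - g.coords[j]
    v = g.coords[k] - g.coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DataError("coincident atoms in bond angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(g: Geometry, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i–j–k–l in degrees, right-handed convention, in (−180, 180].

    φ = atan2((n1×n2)·b̂2, n1·n2) with b1 = r_j−r_i, b2 = r_k−r_j,
    b3 = r_l−r_k, n1 = b1×b2, n2 = b2×b3.
    """
    if len({i, j, k, l}) != 4:
        raise DataError("dihedral needs four distinct atoms")
    b1 = g.coords[j] - g.coords[i]
    b2 = g.coords[k] - g.coords[j]
    b3 = g.coords[l] - g.coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-12:
        raise DataError("collinear backbone atoms in dihedral")
    phi = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    if phi <= -180.0:
        phi += 360.0
    return phi


@dataclass(frozen=True)
class ZMatrixRecord:
    """Internal-coordinate record.

    ``connectivity[i]`` (for atom i ≥ 1, 0-based) is the reference triplet
    ``(bond, angle, dihedral)`` of earlier atom indices, with −1 where the
    coordinate is undefined (first three atoms).  For n ≥ 4 atoms the record
    carries n−1 bonds (Å), n−2 angles and n−3 dihedrals (degrees), i.e.
    3n−6 features in total.
    """

    connectivity: tuple[tuple[int, int, int], ...]
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.connectivity) + 1

    def vector(self) -> np.ndarray:
        return np.concatenate([self.bonds, self.angles, self.dihedrals])


def default_connectivity(n_atoms: int) -> tuple[tuple[int, int, int], ...]:
    """Sequential chain: atom i references atoms i−1 (bond), i−2 (angle), i−3 (dihedral)."""
    return tuple(
        (i - 1, i - 2 if i >= 2 else -1, i - 3 if i >= 3 else -1)
        for i in range(1, n_atoms)
    )


def _validate_connectivity(
    conn: Sequence[Sequence[int]], n_atoms: int
) -> tuple[tuple[int, int, int], ...]:
    if len(conn) != n_atoms - 1:
        raise DataError(
            f"connectivity must define atoms 1..{n_atoms - 1}, got {len(conn)} entries"
        )
    out = []
    for offset, refs in enumerate(conn, start=1):
        b, a, d = (int(x) for x in refs)
        for slot, ref in (("bond", b), ("angle", a), ("dihedral", d)):
            required = {"bond": 1, "angle": 2, "dihedral": 3}[slot]
            if offset >= required and not (0 <= ref < offset):
                raise DataError(
                    f"atom {offset}: {slot} reference {ref} must point to an "
                    f"earlier atom"
                )
        out.append((b, a, d))
    return tuple(out)


def zmatrix(
    g: Geometry, connectivity: Sequence[Sequence[int]] | None = None
) -> ZMatrixRecord:
    """Internal coordinates of ``g`` over the given (or default chain) connectivity."""
    n = g.n_atoms
    if n < 2:
        raise DataError("a Z-matrix needs at least 2 atoms")
    conn = (
        default_connectivity(n)
        if connectivity is None
        else _validate_connectivity(connectivity, n)
    )
    bonds, angles, dihedrals = [], [], []
    for i, (b, a, d) in enumerate(conn, start=1):
        bonds.append(float(np.linalg.norm(g.coords[i] - g.coords[b])))
        if i >= 2:
            angles.append(bond_angle(g, i, b, a))
        if i >= 3:
            dihedrals.append(dihedral_angle(g, i, b, a, d))
    return ZMatrixRecord(conn, np.array(bonds), np.array(angles), np.array(dihedrals))


def zmatrix_to_cartesian(rec: ZMatrixRecord) -> np.ndarray:
    """Rebuild Cartesian coordinates from a Z-matrix (NeRF atom placement).

    The absolute orientation is arbitrary (atom 0 at the origin, atom 1 on
    +x, atom 2 in the xy plane); re-deriving the Z-matrix over the same
    connectivity reproduces the record.
    """
    n = rec.n_atoms
    coords = np.zeros((n, 3))
    for i, (b, a, d) in enumerate(rec.connectivity, start=1):
        r = rec.bonds[i - 1]
        if i == 1:
            coords[i] = coords[b] + np.array([r, 0.0, 0.0])
            continue
        theta = math.radians(rec.angles[i - 2])
        if i == 2:
            u = coords[a] - coords[b]
            u /= np.linalg.norm(u)
            # place in the xy plane
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords[i] = coords[b] + r * (math.cos(theta) * u + math.sin(theta) * perp)
            continue
        phi = math.radians(rec.dihedrals[i - 3])
        bc = coords[b] - coords[a]
        bc /= np.linalg.norm(bc)
        ab = coords[a] - coords[d]
        n1 = np.cross(ab, bc)
        nn1 = np.linalg.norm(n1)
        if nn1 < 1e-10:
            raise DataError(f"atom {i}: collinear reference frame in reconstruction")
        n1 /= nn1
        m = np.cross(n1, bc)
        d2 = np.array(
            [
                -r * math.cos(theta),
                r * math.sin(theta) * math.cos(phi),
                r * math.sin(theta) * math.sin(phi),
            ]
        )
        coords[i] = coords[b] + d2[0] * bc + d2[1] * m + d2[2] * n1
    return coords


def zmatrix_names(n_atoms: int) -> list[str]:
    """Feature names ``R<i>``, ``A<i>``, ``D<i>`` (i = defining atom, 0-based)."""
    return (
        [f"R{i}" for i in range(1, n_atoms)]
        + [f"A{i}" for i in range(2, n_atoms)]
        + [f"D{i}" for i in range(3, n_atoms)]
    )


def wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Smallest signed angular difference, mapped into (−180, 180] degrees."""
    wrapped = np.mod(np.asarray(delta, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(np.isclose(wrapped, -180.0), 180.0, wrapped)


def delta_zmatrix(
    z: ZMatrixRecord, z_ref: ZMatrixRecord, transform: str = "none"
) -> np.ndarray:
    """Difference of two Z-matrices sharing one connectivity.

    Bond deltas are in Å; angular deltas are wrapped to the smallest signed
    difference in (−180, 180] degrees.  ``transform='tanh'`` applies tanh,
    ``'sig'`` the logistic 1/(1+e^−x), elementwise to the deltas with bonds
    in Å and angular deltas in radians (so ±180° maps to ±π and does not
    saturate).
    """
    if z.connectivity != z_ref.connectivity:
        raise DataError("Z-matrices have different connectivity")
    db = z.bonds - z_ref.bonds
    da = wrap_angle(z.angles - z_ref.angles)
    dd = wrap_angle(z.dihedrals - z_ref.dihedrals)
    if transform == "none":
        return np.concatenate([db, da, dd])
    scaled = np.concatenate([db, np.radians(da), np.radians(dd)])
    if transform == "tanh":
        return np.tanh(scaled)
    if transform == "sig":
        return 1.0 / (1.0 + np.exp(-scaled))
    raise ConfigError(f"unknown delta-Z-matrix transform {transform!r}")


# ---------------------------------------------------------------------------
# Cremer–Pople ring puckering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PuckeringParams:
    """Generalized ring-puckering coordinates of an N-membered ring.

    ``z`` are the out-of-plane displacements (Å, summing to zero) relative
    to the mean plane; ``q`` / ``phi`` map mode index m (2 ≤ m ≤ ⌊N/2⌋) to
    puckering amplitude (Å) and phase (degrees; absent for m = N/2, whose
    amplitude is signed); ``Q`` is the total amplitude with Q² = Σ z_j².
    For even N, ``theta`` is the polar angle measured from the q_{N/2} pole
    (cos θ = q_{N/2}/Q) and ``phi_angle`` = φ_2; for a planar ring (Q = 0)
    both angles are reported as 0.  The N−3 independent coordinates are the
    q_m/φ_m set.
    """

    z: np.ndarray
    q: dict[int, float]
    phi: dict[int, float]
    Q: float
    theta: float | None
    phi_angle: float | None

    @property
    def n_ring(self) -> int:
        return len(self.z)


def cremer_pople(g: Geometry, ring_atoms: Sequence[int]) -> PuckeringParams:
    """Cremer–Pople puckering parameters of the ring ``ring_atoms`` (ordered).

    Standard construction: translate the ring to its geometric center, take
    the mean plane normal n̂ = (R′ × R″)/|R′ × R″| with
    R′ = Σ r_j sin(2πj/N) and R″ = Σ r_j cos(2πj/N), project out-of-plane
    displacements z_j = r_j · n̂, then form amplitudes/phases from the
    discrete Fourier sums of z_j.  Atom index 0 of ``ring_atoms`` defines
    the phase origin j = 0.
    """
    idx = list(ring_atoms)
    N = len(idx)
    if N < 4:
        raise DataError("Cremer–Pople needs a ring of at least 4 atoms")
    if len(set(idx)) != N:
        raise DataError("ring atoms must be distinct")
    r = g.coords[idx].astype(float)
    r = r - r.mean(axis=0)
    j = np.arange(N)
    rp = (r * np.sin(2 * np.pi * j / N)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2 * np.pi * j / N)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    nn = np.linalg.norm(normal)
    if nn < 1e-10:
        raise DataError("degenerate (collinear) ring: mean plane undefined")
    normal /= nn
    z = r @ normal

    q: dict[int, float] = {}
    phi: dict[int, float] = {}
    for m in range(2, (N - 1) // 2 + 1):
        qc = math.sqrt(2.0 / N) * float((z * np.cos(2 * np.pi * m * j / N)).sum())
        qs = -math.sqrt(2.0 / N) * float((z * np.sin(2 * np.pi * m * j / N)).sum())
        amp = math.hypot(qc, qs)
        q[m] = amp
        phi[m] = math.degrees(math.atan2(qs, qc)) % 360.0 if amp > 1e-12 else 0.0
    if N % 2 == 0:
        q[N // 2] = math.sqrt(1.0 / N) * float((z * (-1.0) ** j).sum())
    Q = float(np.sqrt((z**2).sum()))

    theta = phi_angle = None
    if N % 2 == 0 and N >= 6:
        if Q > 1e-12:
            theta = math.degrees(math.acos(np.clip(q[N // 2] / Q, -1.0, 1.0)))
        else:
            theta = 0.0
        phi_angle = phi.get(2, 0.0)
    return PuckeringParams(z=z, q=q, phi=phi, Q=Q, theta=theta, phi_angle=phi_angle)


# ---------------------------------------------------------------------------
# ensemble-level feature tables
# ---------------------------------------------------------------------------

DESCRIPTOR_CHOICES = (
    "r2",
    "inv_r2",
    "delta_r2",
    "re",
    "zmat",
    "delta_zmat",
    "tanh_zmat",
    "sig_zmat",
    "soap",
    "cremer_pople",
)


def _cp_feature_row(g: Geometry, ring_atoms: Sequence[int]) -> tuple[list[str], list[float]]:
    p = cremer_pople(g, ring_atoms)
    N = p.n_ring
    if N == 6:
        return ["Q", "theta", "phi"], [p.Q, p.theta or 0.0, p.phi_angle or 0.0]
    names: list[str] = []
    vals: list[float] = []
    for m in sorted(p.q):
        names.append(f"q{m}")
        vals.append(p.q[m])
        if m in p.phi:
            names.append(f"phi{m}")
            vals.append(p.phi[m])
    names.append("Q")
    vals.append(p.Q)
    return names, vals


def descriptor_dataset(
    ens: EnsembleDataset,
    descriptor: str,
    reference: Geometry | None = None,
    connectivity: Sequence[Sequence[int]] | None = None,
    ring_atoms: Sequence[int] | None = None,
    soap_params: "object | None" = None,
) -> pd.DataFrame:
    """Apply one descriptor uniformly over an ensemble.

    Returns a DataFrame with one row per frame, indexed by ``(traj, time)``.
    Referenced variants (``delta_r2``, ``re``, ``delta_zmat``, ``tanh_zmat``,
    ``sig_zmat``) use ``reference`` or, failing that, the ensemble's own
    reference geometry.
    """
    if descriptor not in DESCRIPTOR_CHOICES:
        raise ConfigError(
            f"unknown descriptor {descriptor!r}; choose from {DESCRIPTOR_CHOICES}"
        )
    if ens.n_frames == 0:
        raise DataError("empty ensemble")
    ref = reference if reference is not None else ens.reference
    needs_ref = descriptor in ("delta_r2", "re", "delta_zmat", "tanh_zmat", "sig_zmat")
    if needs_ref and ref is None:
        raise ConfigError(f"descriptor {descriptor!r} requires a reference geometry")

    keys = ens.keys
    n_atoms = len(ens.atom_labels)
    rows: list[np.ndarray | list[float]] = []

    if descriptor in ("r2", "inv_r2", "delta_r2", "re"):
        names = pairwise_distance_names(n_atoms)
        v_ref = pairwise_distance_vector(ref) if needs_ref else None
        variant = {"inv_r2": "inverse", "delta_r2": "delta", "re": "re"}.get(descriptor)
        for key in keys:
            v = pairwise_distance_vector(ens.geometries[key])
            rows.append(v if variant is None else r2_variant(v, v_ref, variant))
    elif descriptor in ("zmat", "delta_zmat", "tanh_zmat", "sig_zmat"):
        names = zmatrix_names(n_atoms)
        conn = connectivity if connectivity is not None else default_connectivity(n_atoms)
        z_ref = zmatrix(ref, conn) if needs_ref else None
        transform = {"tanh_zmat": "tanh", "sig_zmat": "sig"}.get(descriptor, "none")
        for key in keys:
            z = zmatrix(ens.geometries[key], conn)
            rows.append(
                z.vector() if descriptor == "zmat" else delta_zmatrix(z, z_ref, transform)
            )
    elif descriptor == "cremer_pople":
        if ring_atoms is None:
            raise ConfigError("cremer_pople descriptor requires ring_atoms")
        names = None
        for key in keys:
            nm, vals = _cp_feature_row(ens.geometries[key], ring_atoms)
            names = nm
            rows.append(vals)
    else:  # soap
        from .soap import SOAPParams, soap_feature_names, soap_power_spectrum

        params = soap_params if soap_params is not None else SOAPParams.for_labels(
            ens.atom_labels
        )
        names = soap_feature_names(params)
        for key in keys:
            rows.append(soap_power_spectrum(ens.geometries[key], params))

    table = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=pd.MultiIndex.from_tuples(keys, names=["traj", "time"]),
        columns=names,
    )
    if not np.all(np.isfinite(table.to_numpy())):
        raise DataError("descriptor table contains non-finite values")
    return table
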