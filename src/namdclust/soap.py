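"""Smooth Overlap of Atomic Positions (SOAP) power spectrum.

Each atomic environment is represented by a Gaussian-smeared neighbor
density per chemical species,

    rho_Z(r) = sum_{i in Z} exp(-|r - R_i|^2 / (2 sigma^2)),

expanded in orthonormal radial basis functions g_n(r) and real spherical
harmonics Y_lm:

    c^Z_nlm = <g_n Y_lm | rho_Z>.

The rotationally invariant partial power spectrum combines the expansion
coefficients of two species channels,

    p(Z1, Z2, n, n', l) = pi * sqrt(8 / (2l + 1)) * sum_m c^Z1_nlm c^Z2_n'lm,

and per-frame vectors are either concatenated per atom or averaged over
atomic centers (molecule-level descriptor).

Implementation notes
--------------------
* Radial basis: polynomials (r_cut - r)^(n+2), n = 1..n_max, orthonormalized
  through the analytic overlap matrix (Loewdin, S^(-1/2)).
* The angular integral of a displaced Gaussian is analytic via the plane-wave
  style expansion  exp(r.R/sigma^2) = sum_lm 4 pi i_l(rR/sigma^2) Y_lm Y_lm,
  with i_l the modified spherical Bessel function; only the radial integral
  is evaluated numerically (Gauss-Legendre on [0, r_cut]).
* The central atom contributes to its own species density (l = 0 channel).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y, spherical_in

from .datasets import Geometry
from .exceptions import ConfigError, DataError

__all__ = ["SOAPParams", "soap_power_spectrum", "soap_feature_names"]

_N_QUAD = 128  # Gauss-Legendre points for the radial integrals


@dataclass(frozen=True)
class SOAPParams:
    """SOAP hyperparameters.

    species
        Ordered tuple of element symbols defining the density channels.
    r_cut
        Environment cutoff radius, Å.
    n_max, l_max
        Number of radial basis functions and maximum spherical-harmonic
        degree.
    sigma_atom
        Width of the atomic Gaussians, Å.
    aggregation
        ``"averaged"`` (mean over atomic centers, one vector per frame) or
        ``"per-atom"`` (concatenation over centers).
    """

    species: tuple[str, ...]
    r_cut: float = 6.0
    n_max: int = 8
    l_max: int = 6
    sigma_atom: float = 0.5
    aggregation: str = "averaged"

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(dict.fromkeys(self.species)))
        if self.n_max < 1:
            raise ConfigError("n_max must be >= 1")
        if self.l_max < 0:
            raise ConfigError("l_max must be >= 0")
        if self.r_cut <= 0:
            raise ConfigError("r_cut must be positive")
        if self.sigma_atom <= 0:
            raise ConfigError("sigma_atom must be positive")
        if self.aggregation not in ("averaged", "per-atom"):
            raise ConfigError("aggregation must be 'averaged' or 'per-atom'")

    @classmethod
    def for_labels(cls, labels, **kwargs) -> "SOAPParams":
        """Parameters with the species set taken from an atom-label sequence."""
        return cls(species=tuple(sorted(set(labels))), **kwargs)

    @property
    def n_features(self) -> int:
        s = len(self.species)
        per_l = self.n_max * (self.n_max + 1) // 2  # same-species n <= n'
        cross = self.n_max * self.n_max
        pairs = s * per_l + (s * (s - 1) // 2) * cross
        return pairs * (self.l_max + 1)


@lru_cache(maxsize=16)
def _radial_basis(n_max: int, r_cut: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal polynomial radial basis evaluated on a quadrature grid.

    Returns (nodes, weights, G) with G[n, q] = g_n(r_q); the g_n are
    Loewdin-orthonormalized combinations of phi_n(r) = (r_cut - r)^(n+2).
    """
    # analytic overlaps S_nm = int_0^c (c-r)^(n+m+4) r^2 dr
    S = np.empty((n_max, n_max))
    for a in range(1, n_max + 1):
        for b in range(1, n_max + 1):
            p = a + b + 4
            S[a - 1, b - 1] = 2.0 * r_cut ** (p + 3) / ((p + 1) * (p + 2) * (p + 3))
    evals, evecs = np.linalg.eigh(S)
    W = evecs @ np.diag(evals**-0.5) @ evecs.T  # S^(-1/2)
    x, w = np.polynomial.legendre.leggauss(_N_QUAD)
    nodes = 0.5 * r_cut * (x + 1.0)
    weights = 0.5 * r_cut * w
    phi = np.array([(r_cut - nodes) ** (n + 2) for n in range(1, n_max + 1)])
    return nodes, weights, W @ phi


def _real_sph_harm(l_max: int, unit_vecs: np.ndarray) -> np.ndarray:
    """Real spherical harmonics Y_lm for each row of ``unit_vecs``.

    Returns array of shape (n_vec, (l_max+1)^2) ordered (l, m) with
    m = -l..l.  Built from the complex harmonics by the standard real
    combination.
    """
    x, y, z = unit_vecs[:, 0], unit_vecs[:, 1], unit_vecs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((unit_vecs.shape[0], (l_max + 1) ** 2))
    col = 0
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                out[:, col] = ylm.real
            elif m > 0:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * ylm.real
            else:
                out[:, col] = np.sqrt(2.0) * (-1.0) ** m * ylm.imag
            col += 1
    return out


def _expansion_coefficients(
    center: np.ndarray,
    neighbors: np.ndarray,
    params: SOAPParams,
) -> np.ndarray:
    """c_nlm = <g_n Y_lm | rho> for one density channel around one center.

    ``neighbors`` holds the absolute positions of the channel's atoms
    (the center itself included when it belongs to the channel).
    Returns array of shape (n_max, (l_max+1)^2).
    """
    nodes, weights, G = _radial_basis(params.n_max, params.r_cut)
    sig2 = params.sigma_atom**2
    c = np.zeros((params.n_max, (params.l_max + 1) ** 2))
    if neighbors.size == 0:
        return c
    disp = neighbors - center
    dist = np.linalg.norm(disp, axis=1)
    keep = dist <= params.r_cut
    disp, dist = disp[keep], dist[keep]
    if disp.shape[0] == 0:
        return c

    central = dist < 1e-9
    # off-center neighbors: full angular expansion
    if np.any(~central):
        d = dist[~central]
        units = disp[~central] / d[:, None]
        Y = _real_sph_harm(params.l_max, units)  # (n_nb, n_lm)
        # radial kernel K[l, nb, q] = i_l(r R / sig2) * exp(-(r^2+R^2)/(2 sig2))
        x = np.einsum("q,n->nq", nodes, d) / sig2  # (n_nb, n_quad)
        damp = np.exp(-(nodes[None, :] ** 2 + d[:, None] ** 2) / (2.0 * sig2))
        r2w = weights * nodes**2
        for l in range(params.l_max + 1):
            il = spherical_in(l, x)
            # I[n, nb] = int g_n(r) r^2 i_l exp(...) dr
            I = np.einsum("mq,nq,q->mn", G, il * damp, r2w)
            cols = slice(l * l, (l + 1) * (l + 1))
            c[:, cols] += 4.0 * np.pi * I @ Y[:, cols]
    # central contribution: only l = 0 survives (Y_00 = 1/sqrt(4 pi))
    n_central = int(np.count_nonzero(central))
    if n_central:
        r2w = weights * nodes**2
        I0 = G @ (np.exp(-(nodes**2) / (2.0 * sig2)) * r2w)
        c[:, 0] += n_central * np.sqrt(4.0 * np.pi) * I0
    return c


def soap_power_spectrum(g: Geometry, params: SOAPParams) -> np.ndarray:
    """SOAP partial power spectrum of a geometry.

    Per atomic center, the species-pair power spectrum
    p(Z1, Z2, n, n', l) = pi sqrt(8/(2l+1)) sum_m c^Z1_nlm c^Z2_n'lm is
    computed over the Gaussian neighbor density within ``r_cut``; the
    per-center vectors are averaged (``aggregation='averaged'``) or
    concatenated (``'per-atom'``).  Feature order matches
    :func:`soap_feature_names`.
    """
    unknown = set(g.labels) - set(params.species)
    if unknown:
        raise DataError(
            f"elements {sorted(unknown)} not in SOAP species {params.species}"
        )
    positions = {z: g.coords[[i for i, lab in enumerate(g.labels) if lab == z]]
                 for z in params.species}
    n_lm = (params.l_max + 1) ** 2
    per_center = []
    for a in range(g.n_atoms):
        center = g.coords[a]
        coeffs = {
            z: _expansion_coefficients(center, positions[z], params)
            for z in params.species
        }
        feats = []
        for zi, z1 in enumerate(params.species):
            for z2 in params.species[zi:]:
                c1, c2 = coeffs[z1], coeffs[z2]
                for l in range(params.l_max + 1):
                    cols = slice(l * l, (l + 1) * (l + 1))
                    # M[n, n'] = sum_m c1_nlm c2_n'lm
                    M = c1[:, cols] @ c2[:, cols].T
                    pref = np.pi * np.sqrt(8.0 / (2 * l + 1))
                    if z1 == z2:
                        iu = np.triu_indices(params.n_max)
                        feats.append(pref * M[iu])
                    else:
                        feats.append(pref * M.ravel())
        per_center.append(np.concatenate(feats))
    mat = np.asarray(per_center)
    if params.aggregation == "averaged":
        return mat.mean(axis=0)
    return mat.ravel()


def soap_feature_names(params: SOAPParams) -> list[str]:
    """Stable feature names ``soap_<Z1>_<Z2>_n<i>_n<j>_l<k>`` matching the vector order.

    For ``aggregation='per-atom'`` the per-center blocks are prefixed with
    the center index.
    """
    base: list[str] = []
    for zi, z1 in enumerate(params.species):
        for z2 in params.species[zi:]:
            for l in range(params.l_max + 1):
                if z1 == z2:
                    for n in range(params.n_max):
                        for n2 in range(n, params.n_max):
                            base.append(f"soap_{z1}_{z2}_n{n}_n{n2}_l{l}")
                else:
                    for n in range(params.n_max):
                        for n2 in range(params.n_max):
                            base.append(f"soap_{z1}_{z2}_n{n}_n{n2}_l{l}")
    if params.aggregation == "averaged":
        return base
    raise ConfigError(
        "per-atom feature names depend on the geometry; use aggregation='averaged' "
        "for frame-level tables"
    )
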