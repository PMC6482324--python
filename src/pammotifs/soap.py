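"""Smooth-overlap atomic-environment descriptors for C-alpha centres.

Each C-alpha environment is the Gaussian-smeared density of the C, N
and O atoms within a cutoff, weighted by a smooth cutoff function.  The
density is expanded per species in orthonormal radial functions times
spherical harmonics; summing the expansion products over the harmonic
order m gives the rotationally invariant power spectrum, whose scalar
product is the overlap kernel between two environments.

Implementation notes: the radial functions are Loewdin-orthonormalised
polynomials (r_cut - r)^(n+2); the expansion integrals use the closed
form of a Gaussian against spherical harmonics (modified spherical
Bessel weights) with fixed Gauss-Legendre radial quadrature, in a
numerically stable exponent-scaled form.  The central atom itself is
not part of its own environment.

Descriptor dimensionality is reduced in two stages: farthest-point
selection of informative components (columns), then PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.special import ive, sph_harm_y
from sklearn.decomposition import PCA

from .pamm import fps_select
from .structures import ProteinStructure, ResidueKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SoapConfig:
    """Parameters of the atomic-environment descriptor.

    cutoff:
        environment radius in Angstrom; 6.0 spans several neighbouring
        residues along a protein backbone.
    gaussian_width:
        smearing of each atom's density, Angstrom.
    n_max, l_max:
        radial basis size and angular band limit.
    species:
        ordered element list contributing to the density.
    cutoff_transition:
        width of the smooth cosine decay ending at the cutoff.
    """

    cutoff: float = 6.0
    gaussian_width: float = 0.5
    n_max: int = 8
    l_max: int = 6
    species: tuple[str, ...] = ("C", "N", "O")
    cutoff_transition: float = 0.5
    n_quad: int = 64

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.gaussian_width <= 0:
            raise ValueError("cutoff and gaussian_width must be positive")
        if self.n_max < 1 or self.l_max < 0:
            raise ValueError("n_max >= 1 and l_max >= 0 required")


@dataclass
class SoapVector:
    """Power-spectrum components of one C-alpha environment."""

    center_residue: ResidueKey
    components: np.ndarray


def component_labels(config: SoapConfig) -> list[tuple[str, int, str, int, int]]:
    """(species, n, species', n', l) index of each power-spectrum entry."""
    pairs = []
    sp = config.species
    for qi in range(len(sp) * config.n_max):
        for qj in range(qi, len(sp) * config.n_max):
            a, n = divmod(qi, config.n_max)
            b, m = divmod(qj, config.n_max)
            for l in range(config.l_max + 1):
                pairs.append((sp[a], n + 1, sp[b], m + 1, l))
    return pairs


def _radial_basis(config: SoapConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature nodes/weights and orthonormal radial functions R_n(r_q)."""
    rc = config.cutoff
    nodes, weights = np.polynomial.legendre.leggauss(config.n_quad)
    r = 0.5 * rc * (nodes + 1.0)
    w = 0.5 * rc * weights
    n_idx = np.arange(1, config.n_max + 1)
    # overlap of (rc - r)^(n+2) under the r^2 measure, closed form
    npm = n_idx[:, None] + n_idx[None, :]
    S = 2.0 * rc ** (npm + 7) / ((npm + 5) * (npm + 6) * (npm + 7))
    vals, vecs = eigh(S)
    if vals.min() <= 0:
        raise ValueError("radial overlap matrix not positive definite")
    S_inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
    phi = (rc - r[None, :]) ** (n_idx[:, None] + 2)  # (n_max, Q)
    R = S_inv_sqrt @ phi
    return r, w, R


def _cutoff_weight(r: np.ndarray, config: SoapConfig) -> np.ndarray:
    rc, width = config.cutoff, config.cutoff_transition
    inner = rc - width
    out = np.ones_like(r)
    trans = (r > inner) & (r < rc)
    out[trans] = 0.5 * (1.0 + np.cos(np.pi * (r[trans] - inner) / width))
    out[r >= rc] = 0.0
    return out


def _environment_power_spectrum(
    rel_positions: np.ndarray,
    elements: list[str],
    config: SoapConfig,
    radial: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> np.ndarray:
    """Power spectrum of one environment given neighbour displacements."""
    r_q, w_q, R = radial
    sigma2 = config.gaussian_width**2
    n_sp = len(config.species)
    n_max, l_max = config.n_max, config.l_max

    # per-species complex expansion coefficients c[alpha, n, l, m]
    coeffs = np.zeros((n_sp, n_max, l_max + 1, 2 * l_max + 1), dtype=complex)
    if rel_positions.shape[0]:
        r_i = np.linalg.norm(rel_positions, axis=1)
        keep = (r_i < config.cutoff) & (r_i > 1e-12)
        rel_positions = rel_positions[keep]
        elements = [e for e, k in zip(elements, keep) if k]
        r_i = r_i[keep]
    if rel_positions.shape[0]:
        fc = _cutoff_weight(r_i, config)
        theta = np.arccos(np.clip(rel_positions[:, 2] / r_i, -1.0, 1.0))
        phi_az = np.arctan2(rel_positions[:, 1], rel_positions[:, 0])
        norm = 4.0 * np.pi * (2.0 * np.pi * sigma2) ** -1.5

        # stable Gaussian-times-Bessel radial weight, (l, Q, N)
        x = np.clip(r_q[:, None] * r_i[None, :] / sigma2, 1e-300, None)
        gauss = np.exp(-((r_q[:, None] - r_i[None, :]) ** 2) / (2.0 * sigma2))
        pref = np.sqrt(np.pi / (2.0 * x)) * gauss
        B = np.stack(
            [pref * ive(l + 0.5, x) for l in range(l_max + 1)]
        )  # (l, Q, N)
        # radial integrals I[n, l, N] = sum_q w_q r_q^2 R_n(q) B[l, q, N]
        Rq2 = R * (w_q * r_q**2)[None, :]
        I = np.einsum("nq,lqN->nlN", Rq2, B)

        species_index = {s: i for i, s in enumerate(config.species)}
        sp_of = np.array([species_index[e] for e in elements])
        for l in range(l_max + 1):
            m = np.arange(-l, l + 1)
            Y = sph_harm_y(
                l, m[:, None], theta[None, :], phi_az[None, :]
            )  # (2l+1, N)
            ang = np.conj(Y) * fc[None, :]
            for a in range(n_sp):
                mask = sp_of == a
                if not mask.any():
                    continue
                coeffs[a, :, l, : 2 * l + 1] += norm * np.einsum(
                    "nN,mN->nm", I[:, l, mask], ang[:, mask]
                )

    # contract over m: p[(a n) <= (b n'), l] with sqrt(2) off-diagonal weight
    q = coeffs.reshape(n_sp * n_max, l_max + 1, 2 * l_max + 1)
    out = []
    for qi in range(n_sp * n_max):
        for qj in range(qi, n_sp * n_max):
            factor = 1.0 if qi == qj else np.sqrt(2.0)
            for l in range(l_max + 1):
                val = np.sum(q[qi, l, : 2 * l + 1] * np.conj(q[qj, l, : 2 * l + 1]))
                out.append(
                    factor * np.pi * np.sqrt(8.0 / (2 * l + 1)) * float(val.real)
                )
    return np.array(out)


def compute_soap(
    structure: ProteinStructure, config: SoapConfig = SoapConfig()
) -> list[SoapVector]:
    """Power-spectrum vector for every C-alpha atom of a structure.

    Neighbours are all atoms of the configured species within the
    cutoff, across the whole structure.  A C-alpha with no neighbours
    yields the zero vector (warned).
    """
    radial = _radial_basis(config)
    species = set(config.species)
    neighbor_atoms = [a for a in structure.atoms if a.element in species]
    positions = (
        np.array([a.position for a in neighbor_atoms])
        if neighbor_atoms
        else np.zeros((0, 3))
    )
    elements = [a.element for a in neighbor_atoms]

    vectors: list[SoapVector] = []
    for residues in structure.chains().values():
        for res in residues:
            ca = res.atom("CA")
            if ca is None:
                continue
            if positions.shape[0]:
                rel = positions - ca.position
                dist = np.linalg.norm(rel, axis=1)
                near = (dist < config.cutoff) & (dist > 1e-12)
                rel_near = rel[near]
                elems_near = [e for e, k in zip(elements, near) if k]
            else:
                rel_near = np.zeros((0, 3))
                elems_near = []
            if not len(elems_near):
                logger.warning(
                    "C-alpha %s has no neighbours within %.1f A; zero vector",
                    res.key,
                    config.cutoff,
                )
            vectors.append(
                SoapVector(
                    center_residue=res.key,
                    components=_environment_power_spectrum(
                        rel_near, elems_near, config, radial
                    ),
                )
            )
    return vectors


def soap_matrix(vectors: list[SoapVector]) -> np.ndarray:
    return np.stack([v.components for v in vectors])


def soap_kernel(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap kernel between two power spectra (their scalar product)."""
    return float(np.dot(a, b))


# ---------------------------------------------------------------------------
# dimensionality reduction


def fps_components(matrix: np.ndarray, n_keep: int, seed: int) -> np.ndarray:
    """Farthest-point selection of descriptor components (columns).

    Each component is represented by its value profile across the
    sample environments; separation is the (squared) Euclidean distance
    between profiles, so duplicated columns are never both selected
    before all distinct ones.
    """
    matrix = np.asarray(matrix, dtype=float)
    nonzero = int(np.sum(np.ptp(matrix, axis=0) > 0))
    if n_keep > matrix.shape[1]:
        raise ValueError("n_keep exceeds the number of components")
    if n_keep > max(nonzero, 1):
        raise ValueError(
            f"n_keep={n_keep} exceeds the {nonzero} non-constant component(s)"
        )
    idx = fps_select(matrix.T, n_keep, seed)
    return np.sort(idx)


@dataclass
class PcaReducer:
    """Centered principal-component projection, persistable as text."""

    mean: np.ndarray
    components: np.ndarray  # (d, n_features)
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T

    def save(self, path: str | Path) -> None:
        lines = ["# pammotifs-pca 1"]
        lines.append("# mean " + " ".join(repr(float(v)) for v in self.mean))
        lines.append(
            "# evr " + " ".join(repr(float(v)) for v in self.explained_variance_ratio)
        )
        for row in self.components:
            lines.append(" ".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PcaReducer":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0] != "# pammotifs-pca 1":
            raise ValueError(f"{path}: not a pammotifs-pca file")
        mean = evr = None
        rows = []
        for line in lines[1:]:
            if line.startswith("# mean "):
                mean = np.array([float(v) for v in line.split()[2:]])
            elif line.startswith("# evr "):
                evr = np.array([float(v) for v in line.split()[2:]])
            elif line.strip() and not line.startswith("#"):
                rows.append([float(v) for v in line.split()])
        return cls(
            mean=mean, components=np.array(rows), explained_variance_ratio=evr
        )


def fit_pca(matrix: np.ndarray, d: int) -> tuple[PcaReducer, np.ndarray]:
    """Centered PCA to ``d`` components, ordered by explained variance."""
    matrix = np.asarray(matrix, dtype=float)
    if d > min(matrix.shape):
        raise ValueError(f"d={d} exceeds the data rank bound {min(matrix.shape)}")
    pca = PCA(n_components=d, svd_solver="full")
    reduced = pca.fit_transform(matrix)
    rank = np.linalg.matrix_rank(matrix - matrix.mean(axis=0))
    if d > rank:
        raise ValueError(f"d={d} exceeds the data rank {rank}")
    reducer = PcaReducer(
        mean=pca.mean_,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    return reducer, reduced
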