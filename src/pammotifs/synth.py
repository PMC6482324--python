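"""Synthetic inputs with known ground truth.

Every stage of the pipeline is testable without downloads through three
generator families:

* planted Gaussian mixtures (optionally periodic) with known component
  labels, for mode-recovery checks;
* toy polypeptide backbones built by internal-coordinate (NeRF) chain
  growth at prescribed (phi, psi), with carbonyl O and amide H at ideal
  geometry, so dihedral extraction and hydrogen-bond detection have
  exact targets;
* isolated donor/hydrogen/acceptor groups at prescribed distances, so
  triplet enumeration and filtering have countable ground truth.

All generators are seeded and bit-reproducible; structures can be
written as standard fixed-column PDB text and re-parsed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hbonds import HBFlavor
from .pamm import FeatureMatrix
from .structures import AtomRecord, ProteinStructure

logger = logging.getLogger(__name__)

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.000
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0
OMEGA_TRANS = 180.0


# ---------------------------------------------------------------------------
# planted mixtures


@dataclass
class MixtureSpec:
    """A planted Gaussian mixture with optional periodic dimensions."""

    means: list[np.ndarray]
    covariances: list[np.ndarray]
    weights: np.ndarray
    n_samples: int
    periodicity: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = [np.asarray(m, dtype=float) for m in self.means]
        self.covariances = [np.asarray(c, dtype=float) for c in self.covariances]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.means) != len(self.covariances) or len(self.means) != len(
            self.weights
        ):
            raise ValueError("means, covariances and weights must align")
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        for c in self.covariances:
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError as exc:
                raise ValueError("covariance not positive definite") from exc


def sample_mixture(spec: MixtureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Seeded draws plus the true component label of every sample."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.means)
    labels = rng.choice(k, size=spec.n_samples, p=spec.weights)
    d = spec.means[0].shape[0]
    X = np.empty((spec.n_samples, d))
    for comp in range(k):
        mask = labels == comp
        n_comp = int(mask.sum())
        if n_comp:
            chol = np.linalg.cholesky(spec.covariances[comp])
            X[mask] = spec.means[comp] + rng.standard_normal((n_comp, d)) @ chol.T
    return FeatureMatrix(X, periodicity=spec.periodicity), labels


# ---------------------------------------------------------------------------
# internal-coordinate backbone construction


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d with |cd| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-12:
        raise ValueError("reference atoms are collinear")
    n /= norm_n
    m = np.cross(n, bc_hat)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m + d_local[2] * n


@dataclass
class BackboneSpec:
    """A toy polypeptide: per-residue (phi, psi) targets plus noise."""

    phi_psi_sequence: list[tuple[float, float]]
    label_sequence: list[str] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    chain_id: str = "A"
    residue_name: str = "ALA"

    @property
    def n_residues(self) -> int:
        return len(self.phi_psi_sequence)


def build_backbone(spec: BackboneSpec) -> ProteinStructure:
    """Grow an ideal-geometry backbone at the prescribed dihedrals.

    The chain carries N, CA, C, O per residue plus the amide H from
    residue 2 on (the N-terminus has no placed H, as in deposited
    structures).  With zero noise, extracted (phi, psi) equal the
    targets to machine precision.  phi of residue 1 and psi of the last
    residue do not influence the backbone but psi of the last residue
    still orients its carbonyl O.
    """
    n_res = spec.n_residues
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    for phi, psi in spec.phi_psi_sequence:
        if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
            raise ValueError("phi/psi targets must lie in (-180, 180]")
    if spec.label_sequence is not None and len(spec.label_sequence) != n_res:
        raise ValueError("label_sequence length mismatch")

    N = [np.zeros(3)]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    theta = math.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])]
    for i in range(1, n_res):
        psi_prev = spec.phi_psi_sequence[i - 1][1]
        N.append(place_atom(N[-1], CA[-1], C[-1], BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(place_atom(CA[-1], C[-1], N[-1], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS))
        phi_i = spec.phi_psi_sequence[i][0]
        C.append(place_atom(C[i - 1], N[-1], CA[-1], BOND_CA_C, ANGLE_N_CA_C, phi_i))

    O = []
    for i in range(n_res):
        psi_i = spec.phi_psi_sequence[i][1]
        tors = psi_i + 180.0
        if tors > 180.0:
            tors -= 360.0
        O.append(place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, tors))
    H: dict[int, np.ndarray] = {}
    for i in range(1, n_res):
        H[i] = place_atom(O[i - 1], C[i - 1], N[i], BOND_N_H, ANGLE_C_N_H, 180.0)

    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []

    def add(name: str, element: str, pos: np.ndarray, resnum: int) -> None:
        if spec.noise_sigma > 0:
            pos = pos + rng.normal(scale=spec.noise_sigma, size=3)
        atoms.append(
            AtomRecord(
                element=element,
                name=name,
                position=pos,
                occupancy=1.0,
                altloc="",
                residue_key=(spec.chain_id, resnum, ""),
                residue_name=spec.residue_name,
                is_hetero=False,
            )
        )

    for i in range(n_res):
        resnum = i + 1
        add("N", "N", N[i], resnum)
        if i in H:
            add("H", "H", H[i], resnum)
        add("CA", "C", CA[i], resnum)
        add("C", "C", C[i], resnum)
        add("O", "O", O[i], resnum)
    return ProteinStructure(structure_id="synthetic", resolution=1.0, atoms=atoms)


# ---------------------------------------------------------------------------
# hydrogen-bond toys


def build_hb_toy(
    geometries: list[tuple],
    spacing: float = 20.0,
) -> ProteinStructure:
    """Isolated donor/H/acceptor groups at prescribed distances.

    Each geometry is ``(d_DA, d_AH, d_DH, flavor)`` or
    ``(d_DA, d_AH, d_DH, angle_ADH, flavor)``; the three distances fix
    the triangle, so the donor-centred angle is implied — a prescribed
    angle inconsistent with the distances beyond 1e-6 degrees raises.
    Groups sit ``spacing`` Angstrom apart so no cross-group triplet can
    pass the reach filter.  Donor and acceptor go into different
    residues; the structure passes the standard selection rules by
    construction.
    """
    atoms: list[AtomRecord] = []
    for gi, geom in enumerate(geometries):
        if len(geom) == 4:
            d_da, d_ah, d_dh, flavor = geom
            angle = None
        elif len(geom) == 5:
            d_da, d_ah, d_dh, angle, flavor = geom
        else:
            raise ValueError("geometry must have 4 or 5 entries")
        flavor = flavor if isinstance(flavor, HBFlavor) else HBFlavor.parse(flavor)
        if min(d_da, d_ah, d_dh) <= 0:
            raise ValueError(f"geometry {gi}: distances must be positive")
        cos_theta = (d_da**2 + d_dh**2 - d_ah**2) / (2.0 * d_da * d_dh)
        if abs(cos_theta) <= 1.0 + 1e-9:
            cos_theta = min(1.0, max(-1.0, cos_theta))
        else:
            raise ValueError(
                f"geometry {gi}: distances {d_da, d_ah, d_dh} violate the "
                "triangle inequality"
            )
        theta = math.degrees(math.acos(cos_theta))
        if angle is not None and abs(angle - theta) > 1e-6:
            raise ValueError(
                f"geometry {gi}: prescribed angle {angle} inconsistent with "
                f"the distance-implied {theta:.6f}"
            )
        off = np.array([0.0, 0.0, gi * spacing])
        d_pos = off
        h_pos = off + np.array([d_dh, 0.0, 0.0])
        a_pos = off + d_da * np.array(
            [math.cos(math.radians(theta)), math.sin(math.radians(theta)), 0.0]
        )
        base = 2 * gi + 1

        def rec(element: str, name: str, pos: np.ndarray, resnum: int) -> AtomRecord:
            return AtomRecord(
                element=element,
                name=name,
                position=pos,
                occupancy=1.0,
                altloc="",
                residue_key=("A", resnum, ""),
                residue_name="GLY",
                is_hetero=False,
            )

        atoms.append(rec(flavor.donor_element, flavor.donor_element, d_pos, base))
        atoms.append(rec("H", "H", h_pos, base))
        atoms.append(
            rec(flavor.acceptor_element, flavor.acceptor_element, a_pos, base + 1)
        )
    return ProteinStructure(structure_id="hb-toy", resolution=1.0, atoms=atoms)


# ---------------------------------------------------------------------------
# labelled angular data


def labeled_ramachandran(
    class_modes: list[tuple[str, tuple[float, float], float, float]],
    n: int,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Periodic Gaussian draws per secondary-structure class.

    ``class_modes`` rows are (code, (phi, psi) centre, sigma in degrees,
    weight).  Returns the angular features (period 360) and the true
    class code of every sample.
    """
    codes = [c for c, *_ in class_modes]
    weights = np.array([w for *_, w in class_modes], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(len(class_modes), size=n, p=weights)
    X = np.empty((n, 2))
    for i, (code, center, sigma, _w) in enumerate(class_modes):
        mask = which == i
        X[mask] = np.asarray(center) + rng.normal(scale=sigma, size=(int(mask.sum()), 2))
    labels = np.array([codes[i] for i in which], dtype=object)
    return FeatureMatrix(X, periodicity=np.array([360.0, 360.0])), labels


def labeled_chain(
    class_modes: list[tuple[str, tuple[float, float], float, float]],
    n_residues: int,
    mean_run_length: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A residue chain with run-structured labels and per-class angles.

    Labels follow a Markov chain that stays in the current class with
    probability 1 - 1/mean_run_length, emulating secondary-structure
    segments; each residue's (phi, psi) is a periodic Gaussian draw
    from its class mode.  Returns the (n, 2) angle array and the label
    per residue.
    """
    codes = [c for c, *_ in class_modes]
    weights = np.array([w for *_, w in class_modes], dtype=float)
    weights = weights / weights.sum()
    stay = 1.0 - 1.0 / max(mean_run_length, 1.0)
    rng = np.random.default_rng(seed)
    states = np.empty(n_residues, dtype=int)
    states[0] = rng.choice(len(codes), p=weights)
    for i in range(1, n_residues):
        if rng.random() < stay or len(codes) == 1:
            states[i] = states[i - 1]
        else:  # a switch always changes class, so runs average mean_run_length
            others = np.array([k for k in range(len(codes)) if k != states[i - 1]])
            p = weights[others] / weights[others].sum()
            states[i] = rng.choice(others, p=p)
    X = np.empty((n_residues, 2))
    for k, (_code, center, sigma, _w) in enumerate(class_modes):
        mask = states == k
        X[mask] = np.asarray(center) + rng.normal(scale=sigma, size=(int(mask.sum()), 2))
    X = (X + 180.0) % 360.0 - 180.0
    labels = np.array([codes[s] for s in states], dtype=object)
    return X, labels


def chain_windows(
    angles: np.ndarray, labels: np.ndarray, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack w consecutive residues into 2w-dim windows, centre-labelled."""
    if w % 2 == 0 or w < 1:
        raise ValueError("w must be odd")
    n = angles.shape[0]
    half = w // 2
    rows = [angles[i - half : i + half + 1].ravel() for i in range(half, n - half)]
    return np.array(rows), np.asarray(labels[half : n - half])


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write fixed-column PDB text (with the resolution REMARK)."""
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION.    {structure.resolution:.2f} ANGSTROMS."
        )
    serial = 0
    for atom in structure.atoms:
        serial += 1
        name = atom.name
        if len(atom.element) == 1 and len(name) < 4:
            name = f" {name}"
        chain, resnum, icode = atom.residue_key
        record = "HETATM" if atom.is_hetero else "ATOM  "
        x, y, z = atom.position
        lines.append(
            f"{record}{serial:5d} {name:<4s}{atom.altloc or ' ':1s}"
            f"{atom.residue_name:<3s} {chain:1s}{resnum:4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
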