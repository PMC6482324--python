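"""Backbone dihedral angles and consecutive-residue window features.

phi of residue i is the torsion C(i-1)-N(i)-CA(i)-C(i); psi is
N(i)-CA(i)-C(i)-N(i+1).  Chain termini and residues flanking a chain
break (peptide C-N distance above 2.5 A, or missing backbone atoms)
are marked incomplete rather than fabricated.  Windows of w consecutive
complete residues give 2w-dimensional angular features (period 360 in
every dimension) for mode clustering and supervised baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pamm import FeatureMatrix
from .structures import ProteinStructure, ResidueKey, ResidueView

logger = logging.getLogger(__name__)

#: peptide-bond C-N distance above which consecutive residues are a break
CHAIN_BREAK_CN = 2.5


def dihedral_angle(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
) -> float:
    """Signed torsion angle of four points, degrees in (-180, 180].

    IUPAC convention: looking down the p2->p3 bond, the angle is
    positive when p4 rotates clockwise from p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if (
        np.linalg.norm(n1) < 1e-10 * max(np.linalg.norm(b1) * norm_b2, 1e-30)
        or np.linalg.norm(n2) < 1e-10 * max(np.linalg.norm(b3) * norm_b2, 1e-30)
    ):
        raise ValueError("collinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


@dataclass
class DihedralRecord:
    """Ramachandran angles of one residue; incomplete at termini/breaks."""

    residue_key: ResidueKey
    residue_name: str
    phi: float | None
    psi: float | None

    @property
    def complete(self) -> bool:
        return self.phi is not None and self.psi is not None


@dataclass
class DihedralWindow:
    """(phi, psi) angles of w consecutive residues, centred."""

    center_residue: ResidueKey
    angles: np.ndarray  # (2w,) phi1, psi1, phi2, psi2, ...
    label: str | None = None


def _backbone(res: ResidueView):
    return res.atom("N"), res.atom("CA"), res.atom("C")


def extract_phi_psi(
    structure: ProteinStructure, break_distance: float = CHAIN_BREAK_CN
) -> list[DihedralRecord]:
    """Per-residue (phi, psi) records for every chain of a structure."""
    records: list[DihedralRecord] = []
    for residues in structure.chains().values():
        n_res = len(residues)
        bb = [_backbone(r) for r in residues]
        linked = []  # linked[i]: residue i-1 -> i peptide bond intact
        for i in range(n_res):
            if i == 0:
                linked.append(False)
                continue
            c_prev = bb[i - 1][2]
            n_cur = bb[i][0]
            ok = (
                c_prev is not None
                and n_cur is not None
                and float(np.linalg.norm(c_prev.position - n_cur.position))
                <= break_distance
            )
            linked.append(ok)
        for i, res in enumerate(residues):
            n_i, ca_i, c_i = bb[i]
            phi = psi = None
            if n_i and ca_i and c_i:
                if i > 0 and linked[i] and bb[i - 1][2] is not None:
                    try:
                        phi = dihedral_angle(
                            bb[i - 1][2].position,
                            n_i.position,
                            ca_i.position,
                            c_i.position,
                        )
                    except ValueError:
                        phi = None
                if i + 1 < n_res and linked[i + 1] and bb[i + 1][0] is not None:
                    try:
                        psi = dihedral_angle(
                            n_i.position,
                            ca_i.position,
                            c_i.position,
                            bb[i + 1][0].position,
                        )
                    except ValueError:
                        psi = None
            records.append(
                DihedralRecord(
                    residue_key=res.key, residue_name=res.name, phi=phi, psi=psi
                )
            )
    return records


def build_windows(
    records: list[DihedralRecord],
    w: int = 1,
    labels: dict[ResidueKey, str] | None = None,
) -> list[DihedralWindow]:
    """Windows of ``w`` consecutive complete residues (w in {1, 3, 5}).

    Residues are consecutive when they are adjacent in the record list,
    share a chain, and all are complete — incomplete records (termini,
    breaks) interrupt the run, so no window spans a gap.  The optional
    label map attaches the centre residue's class.
    """
    if w not in (1, 3, 5):
        raise ValueError("window size must be 1, 3 or 5")
    windows: list[DihedralWindow] = []
    half = w // 2
    for start in range(len(records) - w + 1):
        run = records[start : start + w]
        if not all(r.complete for r in run):
            continue
        if len({r.residue_key[0] for r in run}) != 1:
            continue
        center = run[half]
        angles = np.array([v for r in run for v in (r.phi, r.psi)], dtype=float)
        windows.append(
            DihedralWindow(
                center_residue=center.residue_key,
                angles=angles,
                label=labels.get(center.residue_key) if labels else None,
            )
        )
    return windows


def windows_to_features(windows: list[DihedralWindow]) -> FeatureMatrix:
    """Stack windows into an angular FeatureMatrix (period 360 per dim)."""
    if not windows:
        raise ValueError("no windows to stack")
    X = np.stack([w.angles for w in windows])
    d = X.shape[1]
    names = []
    for i in range(d // 2):
        names += [f"phi{i + 1}", f"psi{i + 1}"]
    return FeatureMatrix(X, periodicity=np.full(d, 360.0), dim_names=names)


def dihedral_table(records: list[DihedralRecord], structure_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "structure_id": structure_id,
            "chain": r.residue_key[0],
            "resnum": r.residue_key[1],
            "resname": r.residue_name,
            "phi": r.phi if r.phi is not None else np.nan,
            "psi": r.psi if r.psi is not None else np.nan,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["structure_id", "chain", "resnum", "resname", "phi", "psi"]
    )
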