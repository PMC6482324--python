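"""Hydrogen-bond triplet enumeration, geometric filters, and the
Kabsch–Sander electrostatic energy.

A putative hydrogen bond is a donor–hydrogen–acceptor triplet where the
donor and acceptor are N or O; four flavors exist depending on which
element plays which role.  No covalent-bond information is used to
prune candidates — covalently bound and intra-residue triplets are kept
deliberately and left to the downstream probabilistic analysis to
recognise as separate motifs.

The geometric pre-filter keeps triplets with d_DH + d_AH <= 4.5 A and
d_DH < d_AH; the second rule removes the donor/acceptor relabelling
redundancy between mirrored flavors.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import AtomRecord, ProteinStructure

logger = logging.getLogger(__name__)

#: d_DH + d_AH bound (Angstrom) applied by the triplet filter
REACH_SUM = 4.5

#: Kabsch–Sander coupling constant q1*q2*f = 0.42*0.20*332 kcal*A/mol
KS_COUPLING = 27.888

#: energy threshold below which a (C=O, N-H) pair counts as hydrogen bonded
KS_HB_THRESHOLD = -0.5

#: distances below this guard make the 1/r energy meaningless
KS_SINGULAR_GUARD = 0.5


class HBFlavor(Enum):
    """The four donor/acceptor element combinations."""

    NHN = ("N", "N")
    NHO = ("N", "O")
    OHO = ("O", "O")
    OHN = ("O", "N")

    @property
    def donor_element(self) -> str:
        return self.value[0]

    @property
    def acceptor_element(self) -> str:
        return self.value[1]

    def __str__(self) -> str:  # e.g. "N-H...O"
        return f"{self.donor_element}-H...{self.acceptor_element}"

    @classmethod
    def parse(cls, text: str) -> "HBFlavor":
        norm = "".join(c for c in text.upper() if c in "NOH")
        for fl in cls:
            if norm in (fl.name, fl.donor_element + "H" + fl.acceptor_element):
                return fl
        raise ValueError(f"unknown hydrogen-bond flavor {text!r}")


@dataclass
class HBTriplet:
    """A donor–hydrogen–acceptor candidate with its distance descriptors."""

    donor: AtomRecord
    hydrogen: AtomRecord
    acceptor: AtomRecord
    flavor: HBFlavor
    d_DA: float
    d_AH: float
    d_DH: float
    angle_ADH: float  # degrees, at the donor between donor->acceptor and donor->H


def _angle_adh(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    """Angle at the donor between the acceptor and hydrogen directions."""
    u = acceptor - donor
    v = hydrogen - donor
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def enumerate_triplets(
    atoms: list[AtomRecord], flavor: HBFlavor, reach: float = REACH_SUM
) -> list[HBTriplet]:
    """All triplets of the given flavor with d_DH + d_AH <= ``reach``.

    Neighbour search uses a KD-tree around each hydrogen with radius
    ``reach``, which cannot miss any triplet satisfying the sum bound
    (each leg is individually <= reach).  Donor and acceptor must be
    distinct atoms; the hydrogen is distinct by element.
    """
    donors = [a for a in atoms if a.element == flavor.donor_element]
    acceptors = [a for a in atoms if a.element == flavor.acceptor_element]
    hydrogens = [a for a in atoms if a.element == "H"]
    if not donors or not acceptors or not hydrogens:
        return []
    d_pos = np.array([a.position for a in donors])
    a_pos = np.array([a.position for a in acceptors])
    d_tree = cKDTree(d_pos)
    a_tree = cKDTree(a_pos)

    triplets: list[HBTriplet] = []
    for h in hydrogens:
        near_d = d_tree.query_ball_point(h.position, reach)
        near_a = a_tree.query_ball_point(h.position, reach)
        if not near_d or not near_a:
            continue
        for di in sorted(near_d):
            donor = donors[di]
            d_dh = float(np.linalg.norm(donor.position - h.position))
            for ai in sorted(near_a):
                acceptor = acceptors[ai]
                if acceptor is donor:
                    continue
                d_ah = float(np.linalg.norm(acceptor.position - h.position))
                if d_dh + d_ah > reach:
                    continue
                d_da = float(np.linalg.norm(acceptor.position - donor.position))
                triplets.append(
                    HBTriplet(
                        donor=donor,
                        hydrogen=h,
                        acceptor=acceptor,
                        flavor=flavor,
                        d_DA=d_da,
                        d_AH=d_ah,
                        d_DH=d_dh,
                        angle_ADH=_angle_adh(
                            donor.position, h.position, acceptor.position
                        ),
                    )
                )
    return triplets


def filter_triplets(triplets: list[HBTriplet], reach: float = REACH_SUM) -> list[HBTriplet]:
    """Keep triplets with d_DH + d_AH <= reach and d_DH < d_AH (strict).

    The tie d_DH == d_AH (measure zero on real data) is discarded on
    both role assignments and logged.
    """
    kept = []
    ties = 0
    for t in triplets:
        if t.d_DH + t.d_AH > reach:
            continue
        if t.d_DH == t.d_AH:
            ties += 1
            continue
        if t.d_DH > t.d_AH:
            continue
        kept.append(t)
    if ties:
        logger.info("discarded %d triplet(s) with d_DH == d_AH exactly", ties)
    return kept


def triplet_table(triplets: list[HBTriplet], structure_id: str = "") -> pd.DataFrame:
    """Tabulate triplets with the residue metadata the similarity
    restrictions need."""
    rows = []
    for t in triplets:
        rows.append(
            {
                "structure_id": structure_id,
                "flavor": t.flavor.name,
                "donor_name": t.donor.name,
                "hydrogen_name": t.hydrogen.name,
                "acceptor_name": t.acceptor.name,
                "donor_chain": t.donor.residue_key[0],
                "donor_resnum": t.donor.residue_key[1],
                "acceptor_chain": t.acceptor.residue_key[0],
                "acceptor_resnum": t.acceptor.residue_key[1],
                "d_DA": t.d_DA,
                "d_AH": t.d_AH,
                "d_DH": t.d_DH,
                "angle_ADH": t.angle_ADH,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "flavor",
            "donor_name",
            "hydrogen_name",
            "acceptor_name",
            "donor_chain",
            "donor_resnum",
            "acceptor_chain",
            "acceptor_resnum",
            "d_DA",
            "d_AH",
            "d_DH",
            "angle_ADH",
        ],
    )


# ---------------------------------------------------------------------------
# Kabsch–Sander backbone quadruplets


@dataclass
class DsspQuadruplet:
    """A backbone (C=O, N-H) pair with the four inter-group distances."""

    n_atom: AtomRecord
    h_atom: AtomRecord
    c_atom: AtomRecord
    o_atom: AtomRecord
    d_ON: float
    d_CH: float
    d_OH: float
    d_CN: float
    energy: float  # kcal/mol


def kabsch_sander_energy(
    d_ON: float, d_CH: float, d_OH: float, d_CN: float
) -> float:
    """Electrostatic hydrogen-bond energy of a (C=O, N-H) pair, kcal/mol.

    E = 27.888 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN); pairs with
    E < -0.5 kcal/mol are conventionally counted as hydrogen bonds.
    Distances at or below the 0.5 A guard are physically singular and
    raise.
    """
    ds = (d_ON, d_CH, d_OH, d_CN)
    if any(d <= KS_SINGULAR_GUARD for d in ds):
        raise ValueError(f"singular quadruplet distances {ds}")
    return KS_COUPLING * (1.0 / d_ON + 1.0 / d_CH - 1.0 / d_OH - 1.0 / d_CN)


def quadruplet_to_features(quad: DsspQuadruplet) -> tuple[float, float]:
    """Map a quadruplet to (d_AH, d_DA) = (O...H, N...O) distances."""
    return quad.d_OH, quad.d_ON


def build_dssp_quadruplets(
    structure: ProteinStructure,
    min_occupancy: float = 0.95,
    max_d_on: float | None = None,
) -> list[DsspQuadruplet]:
    """All backbone (C=O, N-H) pairs with every atom at or above the
    occupancy threshold.

    Intra-residue and directly bonded pairs are *not* excluded — the
    probabilistic analysis downstream handles them.  ``max_d_on`` caps
    the N...O distance for large structures (None keeps every pair).
    Singular geometries (any distance <= 0.5 A) are skipped and logged.
    """
    co_groups = []
    nh_groups = []
    for residues in structure.chains().values():
        for res in residues:
            c, o = res.atom("C"), res.atom("O")
            if c and o and min(c.occupancy, o.occupancy) >= min_occupancy:
                co_groups.append((c, o))
            n, h = res.atom("N"), res.atom("H")
            if n and h and min(n.occupancy, h.occupancy) >= min_occupancy:
                nh_groups.append((n, h))
    quads: list[DsspQuadruplet] = []
    skipped = 0
    for (c, o), (n, h) in itertools.product(co_groups, nh_groups):
        d_on = float(np.linalg.norm(o.position - n.position))
        if max_d_on is not None and d_on > max_d_on:
            continue
        d_ch = float(np.linalg.norm(c.position - h.position))
        d_oh = float(np.linalg.norm(o.position - h.position))
        d_cn = float(np.linalg.norm(c.position - n.position))
        try:
            energy = kabsch_sander_energy(d_on, d_ch, d_oh, d_cn)
        except ValueError:
            skipped += 1
            continue
        quads.append(
            DsspQuadruplet(
                n_atom=n,
                h_atom=h,
                c_atom=c,
                o_atom=o,
                d_ON=d_on,
                d_CH=d_ch,
                d_OH=d_oh,
                d_CN=d_cn,
                energy=energy,
            )
        )
    if skipped:
        logger.info("skipped %d singular (C=O, N-H) pair(s)", skipped)
    return quads
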