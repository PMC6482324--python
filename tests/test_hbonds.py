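"""Triplet enumeration, geometric filters and the Kabsch-Sander energy."""

import itertools

import numpy as np
import pytest

from pammotifs.hbonds import (
    HBFlavor,
    HBTriplet,
    KS_COUPLING,
    build_dssp_quadruplets,
    enumerate_triplets,
    filter_triplets,
    kabsch_sander_energy,
    quadruplet_to_features,
)
from pammotifs.structures import AtomRecord
from pammotifs.synth import build_hb_toy


def _atom(element, pos, resnum=1, name=None):
    return AtomRecord(
        element=element,
        name=name or element,
        position=np.asarray(pos, dtype=float),
        occupancy=1.0,
        altloc="",
        residue_key=("A", resnum, ""),
        residue_name="ALA",
        is_hetero=False,
    )


def brute_force_triplets(atoms, flavor, reach=4.5):
    """Independent cubic-loop oracle for enumeration."""
    out = []
    for d, h, a in itertools.product(atoms, atoms, atoms):
        if d.element != flavor.donor_element or h.element != "H":
            continue
        if a.element != flavor.acceptor_element or a is d:
            continue
        d_dh = np.linalg.norm(d.position - h.position)
        d_ah = np.linalg.norm(a.position - h.position)
        if d_dh + d_ah <= reach:
            out.append((id(d), id(h), id(a)))
    return set(out)


class TestEnumerateTriplets:
    def test_single_collinear_triplet(self):
        atoms = [
            _atom("N", [0, 0, 0]),
            _atom("H", [1.0, 0, 0]),
            _atom("O", [2.9, 0, 0], resnum=2),
        ]
        trips = enumerate_triplets(atoms, HBFlavor.NHO)
        assert len(trips) == 1
        t = trips[0]
        assert t.d_DH == pytest.approx(1.0)
        assert t.d_AH == pytest.approx(1.9)
        assert t.d_DA == pytest.approx(2.9)
        assert t.angle_ADH == pytest.approx(0.0, abs=1e-9)

    def test_role_swap_before_filter(self):
        atoms = [
            _atom("N", [0, 0, 0]),
            _atom("H", [1.0, 0, 0]),
            _atom("O", [2.9, 0, 0], resnum=2),
        ]
        swapped = enumerate_triplets(atoms, HBFlavor.OHN)
        assert len(swapped) == 1
        assert swapped[0].d_DH == pytest.approx(1.9)
        assert swapped[0].d_AH == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        atoms = (
            [_atom("N", rng.uniform(0, 6, 3), resnum=i + 1) for i in range(3)]
            + [_atom("O", rng.uniform(0, 6, 3), resnum=i + 4) for i in range(3)]
            + [_atom("H", rng.uniform(0, 6, 3), resnum=i + 7) for i in range(4)]
        )
        for flavor in HBFlavor:
            got = {
                (id(t.donor), id(t.hydrogen), id(t.acceptor))
                for t in enumerate_triplets(atoms, flavor)
            }
            assert got == brute_force_triplets(atoms, flavor)

    def test_triangle_inequality_holds(self):
        rng = np.random.default_rng(3)
        atoms = [
            _atom(e, rng.uniform(0, 5, 3), resnum=i + 1)
            for i, e in enumerate(["N", "N", "O", "O", "H", "H", "H"])
        ]
        for flavor in HBFlavor:
            for t in enumerate_triplets(atoms, flavor):
                assert t.d_DA <= t.d_DH + t.d_AH + 1e-12
                assert t.d_DH <= t.d_DA + t.d_AH + 1e-12
                assert t.d_AH <= t.d_DA + t.d_DH + 1e-12


def _triplet(d_dh, d_ah, flavor=HBFlavor.NHO):
    donor = _atom(flavor.donor_element, [0, 0, 0])
    h = _atom("H", [d_dh, 0, 0])
    acceptor = _atom(flavor.acceptor_element, [d_dh + d_ah, 0, 0], resnum=2)
    return HBTriplet(
        donor=donor,
        hydrogen=h,
        acceptor=acceptor,
        flavor=flavor,
        d_DA=d_dh + d_ah,
        d_AH=d_ah,
        d_DH=d_dh,
        angle_ADH=0.0,
    )


class TestFilterTriplets:
    @pytest.mark.parametrize(
        "d_dh,d_ah,kept",
        [
            (1.0, 2.0, True),  # sum 3.0, ordered
            (2.5, 2.1, False),  # donor-H longer than acceptor-H
            (2.0, 2.6, False),  # sum 4.6 over the reach bound
            (2.0, 2.0, False),  # exact tie discarded
        ],
    )
    def test_filter_rules(self, d_dh, d_ah, kept):
        out = filter_triplets([_triplet(d_dh, d_ah)])
        assert (len(out) == 1) == kept

    def test_flavor_swap_duality(self):
        """Any non-tied geometry survives for exactly one role assignment."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            d_dh, d_ah = rng.uniform(0.8, 2.2, 2)
            if d_dh + d_ah > 4.5 or d_dh == d_ah:
                continue
            fwd = filter_triplets([_triplet(d_dh, d_ah, HBFlavor.NHO)])
            rev = filter_triplets([_triplet(d_ah, d_dh, HBFlavor.OHN)])
            assert len(fwd) + len(rev) == 1


class TestKabschSander:
    def test_equal_distances_cancel(self):
        assert kabsch_sander_energy(2.0, 2.0, 2.0, 2.0) == 0.0

    def test_plug_in_arithmetic(self):
        d = (2.92, 3.86, 1.92, 4.01)
        expected = KS_COUPLING * (1 / d[0] + 1 / d[1] - 1 / d[2] - 1 / d[3])
        assert kabsch_sander_energy(*d) == pytest.approx(expected, abs=1e-12)
        # canonical backbone geometry is strongly bonded
        assert kabsch_sander_energy(*d) < -0.5

    def test_randomized_quadruplets_match_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            d = rng.uniform(0.6, 6.0, 4)
            oracle = 27.888 * (1 / d[0] + 1 / d[1] - 1 / d[2] - 1 / d[3])
            assert kabsch_sander_energy(*d) == pytest.approx(oracle, abs=1e-12)

    def test_singular_guard(self):
        with pytest.raises(ValueError):
            kabsch_sander_energy(0.4, 2.0, 2.0, 2.0)


class TestQuadruplets:
    def test_feature_mapping_is_identity(self):
        quads = None
        from pammotifs.synth import BackboneSpec, build_backbone

        st = build_backbone(BackboneSpec(phi_psi_sequence=[(-57.0, -47.0)] * 8))
        quads = build_dssp_quadruplets(st)
        assert quads, "helix should yield backbone (C=O, N-H) pairs"
        for q in quads:
            d_ah, d_da = quadruplet_to_features(q)
            assert d_ah == pytest.approx(q.d_OH)
            assert d_da == pytest.approx(q.d_ON)
            # distances recomputed from coordinates
            assert d_ah == pytest.approx(
                float(np.linalg.norm(q.o_atom.position - q.h_atom.position))
            )
            assert d_da == pytest.approx(
                float(np.linalg.norm(q.o_atom.position - q.n_atom.position))
            )

    def test_helix_contains_bonded_pairs(self):
        from pammotifs.synth import BackboneSpec, build_backbone

        st = build_backbone(BackboneSpec(phi_psi_sequence=[(-57.0, -47.0)] * 12))
        quads = build_dssp_quadruplets(st)
        energies = [q.energy for q in quads]
        assert min(energies) < -0.5  # the i,i+4 helical hydrogen bond

    def test_occupancy_rule(self):
        from pammotifs.synth import BackboneSpec, build_backbone

        st = build_backbone(BackboneSpec(phi_psi_sequence=[(-57.0, -47.0)] * 6))
        n_all = len(build_dssp_quadruplets(st, min_occupancy=0.95))
        # raising the bar above the fixture's occupancy of 1.0 removes all
        assert n_all > 0
        low = [
            AtomRecord(
                element=a.element,
                name=a.name,
                position=a.position,
                occupancy=0.9,
                altloc=a.altloc,
                residue_key=a.residue_key,
                residue_name=a.residue_name,
                is_hetero=a.is_hetero,
            )
            for a in st.atoms
        ]
        st_low = type(st)(st.structure_id, st.resolution, low)
        assert build_dssp_quadruplets(st_low, min_occupancy=0.95) == []


class TestHbToyEndToEnd:
    def test_counts_match_brute_force(self, hb_toy_structure):
        from conftest import TOY_GEOMETRIES

        atoms = hb_toy_structure.atoms
        for flavor in HBFlavor:
            enumerated = enumerate_triplets(atoms, flavor)
            got = {
                (id(t.donor), id(t.hydrogen), id(t.acceptor)) for t in enumerated
            }
            assert got == brute_force_triplets(atoms, flavor)
            kept = filter_triplets(enumerated)
            expected = sum(
                1 for g in TOY_GEOMETRIES if HBFlavor.parse(g[3]) is flavor
            )
            assert len(kept) == expected

    def test_distances_recovered(self, hb_toy_structure):
        from conftest import TOY_GEOMETRIES

        recovered = []
        for flavor in HBFlavor:
            for t in filter_triplets(enumerate_triplets(hb_toy_structure.atoms, flavor)):
                recovered.append((t.d_DA, t.d_AH, t.d_DH, flavor.name))
        assert len(recovered) == len(TOY_GEOMETRIES)
        for d_da, d_ah, d_dh, flavor in TOY_GEOMETRIES:
            match = min(
                recovered,
                key=lambda r: abs(r[0] - d_da) + abs(r[1] - d_ah) + abs(r[2] - d_dh),
            )
            assert match[0] == pytest.approx(d_da, abs=1e-6)
            assert match[1] == pytest.approx(d_ah, abs=1e-6)
            assert match[2] == pytest.approx(d_dh, abs=1e-6)
            assert match[3] == flavor
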