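import numpy as np
import pytest

from termddg.contacts import (
    ContactEngine,
    NoContactsError,
    contact_potential,
    expected_pair_counts,
    freedom_propensities,
)
from termddg.rotamers import Rotamer, RotamerLibrary
from termddg.structure_io import (
    AA_INDEX,
    AMINO_ACIDS,
    AminoAcidDistribution,
    database_from_structures,
)
from termddg.synthetic import PHI_PSI, build_backbone_chain, random_sequence


def make_minilib(reach=2.0):
    """Two-rotamer-per-aa mini library: a single pseudo-atom pointing in
    two directions, identical across amino acids (Gly empty)."""
    rotamers = {}
    for aa in AMINO_ACIDS:
        if aa == "G":
            rotamers[aa] = [Rotamer((), np.empty((0, 3)), 1.0)]
        else:
            rotamers[aa] = [
                Rotamer(("X",), np.array([[0.0, -reach, 0.0]]), 0.5),
                Rotamer(("X",), np.array([[0.0, -reach, 1.0]]), 0.5),
            ]
    return RotamerLibrary(rotamers)


class TestPlaceRotamer:
    def test_gly_never_clashes(self, helix30, lib):
        eng = ContactEngine(helix30, lib)
        rot = lib["G"][0]
        placed = eng.place_rotamer(10, "G", rot)
        assert placed is not None and placed.shape == (0, 3)

    def test_isolated_rotamer_not_clash(self, lib, rng):
        pp = np.tile(PHI_PSI["strand"], (4, 1))
        chain = build_backbone_chain(pp, "AAAA")
        eng = ContactEngine(chain, lib)
        placed = eng.place_rotamer(1, "S", lib["S"][0])
        assert placed is not None

    def test_constructed_overlap_is_clash(self, helix30):
        # rotamer atom engineered to sit ~1 A from a distant backbone atom
        eng_probe = ContactEngine(helix30, make_minilib())
        target = helix30.residues[20].coords[1]  # CA of residue 20
        res5 = helix30.residues[5]
        # canonical-frame coordinate that lands near the residue-20 CA
        from termddg.rotamers import CANONICAL_BACKBONE
        from termddg.structure_io import superpose_transform

        rot_m, t = superpose_transform(CANONICAL_BACKBONE, res5.coords[:3])
        local = (target - t) @ rot_m  # inverse-map the clash point
        clash_rot = Rotamer(("X",), local[None, :], 1.0)
        assert eng_probe.place_rotamer(5, "A", clash_rot) is None

    def test_neighbors_excluded_from_clash(self, helix30):
        # an atom right on top of residue i+1's backbone must NOT clash
        from termddg.rotamers import CANONICAL_BACKBONE
        from termddg.structure_io import superpose_transform

        eng = ContactEngine(helix30, make_minilib())
        res5 = helix30.residues[5]
        target = helix30.residues[6].coords[0]
        rot_m, t = superpose_transform(CANONICAL_BACKBONE, res5.coords[:3])
        local = (target - t) @ rot_m
        assert eng.place_rotamer(5, "A", Rotamer(("X",), local[None, :], 1.0)) is not None


class TestContactDegree:
    def test_far_apart_zero(self, rng, lib):
        pp = np.tile([180.0, 180.0], (40, 1))
        chain = build_backbone_chain(pp, random_sequence(40, rng))
        eng = ContactEngine(chain, lib)
        assert eng.contact_degree(2, 37) == 0.0

    def test_adjacent_rejected(self, helix30, lib):
        eng = ContactEngine(helix30, lib)
        with pytest.raises(ValueError):
            eng.contact_degree(10, 11)
        with pytest.raises(ValueError):
            eng.contact_degree(10, 10)

    def test_symmetry(self, helix30, lib):
        eng = ContactEngine(helix30, lib)
        for i, j in [(10, 14), (5, 9), (3, 20)]:
            assert abs(eng.contact_degree(i, j) - eng.contact_degree(j, i)) < 1e-12

    def test_brute_force_oracle(self, rng):
        """Vectorized degree equals the explicit double sum over all
        (aa, aa, rotamer, rotamer) combinations."""
        minilib = make_minilib(reach=3.0)
        pp = np.tile(PHI_PSI["strand"], (10, 1))
        chain = build_backbone_chain(pp, random_sequence(10, rng))
        bg = AminoAcidDistribution(np.linspace(1, 2, 20) / np.linspace(1, 2, 20).sum())
        eng = ContactEngine(chain, minilib, bg)
        i, j = 3, 6
        got = eng.contact_degree(i, j)

        from scipy.spatial.distance import cdist

        num = den = 0.0
        for aa_a in AMINO_ACIDS:
            for ra in minilib[aa_a]:
                pa = eng.place_rotamer(i, aa_a, ra)
                if pa is None:
                    continue
                for aa_b in AMINO_ACIDS:
                    for rb in minilib[aa_b]:
                        pb = eng.place_rotamer(j, aa_b, rb)
                        if pb is None:
                            continue
                        w = bg[aa_a] * ra.prob * bg[aa_b] * rb.prob
                        den += w
                        if len(pa) and len(pb) and cdist(pa, pb).min() < 3.0:
                            num += w
        assert got == pytest.approx(num / den, abs=1e-9)

    def test_rigid_invariance(self, helix30, lib, rng):
        from termddg.structure_io import BackboneStructure, Residue

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = BackboneStructure(
            "A",
            [Residue(r.aa, r.coords @ rot.T + 5.0, r.author_number) for r in helix30.residues],
            "moved",
        )
        e1 = ContactEngine(helix30, lib)
        e2 = ContactEngine(moved, lib)
        assert e1.contact_degree(10, 14) == pytest.approx(e2.contact_degree(10, 14), abs=1e-9)
        assert e1.freedom(10) == pytest.approx(e2.freedom(10), abs=1e-9)


class TestContactSet:
    def test_helix_contacts_recompute(self, helix30, lib):
        eng = ContactEngine(helix30, lib)
        cs = eng.contact_set(15)
        assert cs, "mid-helix position should have contacts"
        for j in cs:
            assert eng.contact_degree(15, j) > 0.02
        # sorted by descending degree
        degs = [eng.contact_degree(15, j) for j in cs]
        assert degs == sorted(degs, reverse=True)

    def test_exact_threshold_excluded(self, helix30, lib, monkeypatch):
        eng = ContactEngine(helix30, lib)
        monkeypatch.setattr(eng, "contact_degree", lambda i, j: 0.02)
        assert eng.contact_set(15, threshold=0.02) == []

    def test_isolated_extremes_empty(self, rng, lib):
        pp = np.tile([180.0, 180.0], (8, 1))
        chain = build_backbone_chain(pp, "G" * 8)  # glycines: no side chains at all
        eng = ContactEngine(chain, make_minilib(reach=0.5))
        assert eng.contact_set(4) == []


class TestFreedom:
    def test_isolated_dipeptide_full_freedom(self, lib):
        pp = np.tile(PHI_PSI["strand"], (2, 1))
        chain = build_backbone_chain(pp, "AA")
        eng = ContactEngine(chain, lib)
        assert eng.freedom(0) == pytest.approx(1.0)

    def test_bounds(self, helix30, lib):
        eng = ContactEngine(helix30, lib)
        assert all(0.0 <= eng.freedom(i) <= 1.0 for i in range(0, 30, 5))

    def test_caged_position_gly_ala_floor(self, rng):
        """A position with every non-empty rotamer clashing retains exactly
        the weight of the empty (Gly) rotamer."""
        minilib = make_minilib(reach=2.0)
        # fold a chain so tight every pseudo-atom placement clashes: use an
        # artificial structure whose backbone fills the space around res 5
        pp = np.tile(PHI_PSI["helix"], (30, 1))
        chain = build_backbone_chain(pp, random_sequence(30, rng))
        bg = AminoAcidDistribution.uniform()
        eng = ContactEngine(chain, minilib, bg, clash_cutoff=50.0)  # everything clashes
        # only Gly's empty rotamer survives (it cannot clash)
        assert eng.freedom(5) == pytest.approx(bg["G"], abs=1e-12)


class TestFreedomPropensities:
    def test_polyleu_bins_favor_leu(self, lib, rng):
        pp = np.tile(PHI_PSI["helix"], (40, 1))
        db = database_from_structures([build_backbone_chain(pp, "L" * 40, source_id="pl")])
        ft = freedom_propensities(db, lib, n_bins=10)
        # populated bins put the max propensity on L
        counts_cols = [b for b in range(10) if not np.allclose(ft.propensity[:, b], db.background.freq)]
        assert counts_cols
        for b in counts_cols:
            assert np.argmax(ft.propensity[:, b]) == AA_INDEX["L"]

    def test_columns_normalized(self, lib, helix30):
        db = database_from_structures([helix30])
        ft = freedom_propensities(db, lib, n_bins=10)
        assert np.allclose(ft.propensity.sum(axis=0), 1.0)

    def test_hand_tally_two_bins(self, lib, monkeypatch, helix30):
        db = database_from_structures([helix30])
        # force freedom values: first half 0.1 (bin 0), second half 0.9 (bin 1)
        monkeypatch.setattr(
            ContactEngine, "freedom", lambda self, i: 0.1 if i < 15 else 0.9
        )
        ft = freedom_propensities(db, lib, n_bins=2)
        seq = helix30.sequence
        for half, b in ((seq[:15], 0), (seq[15:], 1)):
            counts = np.array([half.count(a) for a in AMINO_ACIDS]) + 1.0
            assert np.allclose(ft.propensity[:, b], counts / counts.sum())


class TestContactPotential:
    def test_uniform_propensity_reduction(self):
        """With P(a|F) = 1/20 everywhere, N_exp = N * (2 - I[a=b]) / 400."""
        uni = np.full(20, 1 / 20)
        n_exp = expected_pair_counts([(uni, uni)] * 30)
        expect = 30 * (2 - np.eye(20)) / 400
        assert np.allclose(n_exp, expect)

    def test_mass_conservation(self, rng):
        """Summing N_exp over unordered pairs returns the contact count."""
        cols = []
        for _ in range(17):
            a = rng.random(20) + 0.01
            b = rng.random(20) + 0.01
            cols.append((a / a.sum(), b / b.sum()))
        n_exp = expected_pair_counts(cols)
        total = np.triu(n_exp).sum()
        assert total == pytest.approx(17.0, abs=1e-6)

    def test_symmetric_and_zero_when_obs_equals_exp(self, helix30, lib):
        db = database_from_structures([helix30])
        pot = contact_potential(db, lib)
        for b in range(pot.j_hat.shape[0]):
            assert np.allclose(pot.j_hat[b], pot.j_hat[b].T, atol=1e-12)
        # cells where n_obs == n_exp give exactly 0 through the pseudocounts
        mask = np.isclose(pot.n_obs, pot.n_exp)
        assert np.allclose(pot.j_hat[mask], 0.0, atol=1e-9)

    def test_hand_computation_uniform(self, rng):
        """30 contacts with uniform propensities: J matches -ln of the
        pseudocounted ratio computed by hand."""
        uni = np.full(20, 1 / 20)
        n_exp = expected_pair_counts([(uni, uni)] * 30)
        # plant N_obs: 10 AL contacts, 20 GG contacts
        n_obs = np.zeros((20, 20))
        n_obs[AA_INDEX["A"], AA_INDEX["L"]] = n_obs[AA_INDEX["L"], AA_INDEX["A"]] = 10
        n_obs[AA_INDEX["G"], AA_INDEX["G"]] = 20
        j = -np.log((n_obs + 1) / (n_exp + 1))
        al = -np.log(11 / (30 * 2 / 400 + 1))
        gg = -np.log(21 / (30 * 1 / 400 + 1))
        assert j[AA_INDEX["A"], AA_INDEX["L"]] == pytest.approx(al, abs=1e-9)
        assert j[AA_INDEX["G"], AA_INDEX["G"]] == pytest.approx(gg, abs=1e-9)

    def test_no_contacts_raises(self, rng):
        pp = np.tile([180.0, 180.0], (35, 1))
        chain = build_backbone_chain(pp, "G" * 35, source_id="pg")
        db = database_from_structures([chain])
        with pytest.raises(NoContactsError):
            contact_potential(db, make_minilib(reach=0.2))
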