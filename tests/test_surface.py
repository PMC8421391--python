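"""SASA, interdomain burial, solvation energy, and contact listing."""

import numpy as np
import pytest

from hingekit import (Selection, cumulative_bsa_difference, interdomain_bsa,
                      peptide_bsa_profile, sasa, solvation_energy,
                      interdomain_contacts)
from hingekit.structures import StructureError
from hingekit.surface import _bsa_between, contact_difference
from hingekit import synth


def carbon_pair(d):
    return synth._pseudo_chain(np.array([[0.0, 0, 0], [d, 0, 0]]), "A")


class TestSASA:
    def test_isolated_atom_analytic_sphere(self):
        s = synth._pseudo_chain(np.zeros((1, 3)), "A")
        res = sasa(s)   # carbon r=1.70, probe 1.4
        assert res.total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        res = sasa(carbon_pair(100.0))
        single = sasa(synth._pseudo_chain(np.zeros((1, 3)), "A")).total
        assert res.total == pytest.approx(2 * single, rel=1e-9)

    def test_two_sphere_cap_closed_form(self):
        # equal spheres R = r + probe at separation d < 2R lose a cap of
        # height h = R - d/2 each: A = 2(4 pi R^2 - 2 pi R h)
        R = 1.7 + 1.4
        for d in (2.0, 3.0, 4.5):
            res = sasa(carbon_pair(d))
            h = R - d / 2
            analytic = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * h)
            assert res.total == pytest.approx(analytic, rel=0.02)

    def test_monotone_decrease_on_approach(self):
        totals = [sasa(carbon_pair(d)).total for d in (7.0, 5.0, 4.0, 3.0, 2.0)]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_point_density_convergence(self, peptide_complex):
        s = peptide_complex.extras["closed"]
        lo = sasa(s, points_per_atom=960).total
        hi = sasa(s, points_per_atom=1920).total
        assert abs(hi - lo) / hi < 0.005

    def test_agrees_with_independent_implementation(self):
        # cross-check against biotite's Shrake-Rupley on matching radii
        import biotite.structure as struc
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(30, 3)) * 4
        s = synth._pseudo_chain(coords, "A")
        mine = sasa(s, points_per_atom=960).total
        arr = struc.AtomArray(30)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, 31)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii="Single").sum()
        assert mine == pytest.approx(float(ref), rel=0.01)

    def test_unknown_element_needs_radius(self):
        s = synth._pseudo_chain(np.zeros((1, 3)), "A")
        s.element = np.array(["Xx"], dtype=object)
        with pytest.raises(StructureError):
            sasa(s)
        assert sasa(s, allow_default_radius=True).total > 0


class TestInterdomainBSA:
    def test_far_groups_zero(self):
        b = synth.make_peptide_complex(atoms_per_globule=30, seed=5)
        open_ = b.extras["open"]    # lid 100 A away
        part = b.extras["partition"]
        res = interdomain_bsa(open_, part, split=(("body",), ("lid",)),
                              points_per_atom=240)
        assert res.total == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_atom_difference_oracle(self):
        rng = np.random.default_rng(61)
        a = synth._pseudo_chain(rng.normal(size=(15, 3)) * 3, "B")
        bb = synth._pseudo_chain(rng.normal(size=(15, 3)) * 3 + [5.5, 0, 0], "L")
        s = a.concat(bb)
        part = synth.receptor_partition()
        res = interdomain_bsa(s, part, split=(("body",), ("lid",)))
        # oracle: explicit three SASA evaluations
        oracle = (sasa(a).total + sasa(bb).total - sasa(s).total)
        assert res.total == pytest.approx(oracle, rel=1e-9)
        assert res.total > 0
        # per-residue burials sum to the total
        assert sum(res.per_residue.values()) == pytest.approx(res.total, rel=1e-9)

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(67)
        a = synth._pseudo_chain(rng.normal(size=(12, 3)) * 3, "B")
        bb = synth._pseudo_chain(rng.normal(size=(12, 3)) * 3 + [5.0, 0, 0], "L")
        s = a.concat(bb)
        part = synth.receptor_partition()
        r1 = interdomain_bsa(s, part, split=(("body",), ("lid",)))
        r2 = interdomain_bsa(s, part, split=(("lid",), ("body",)))
        assert r1.total == pytest.approx(r2.total, rel=1e-12)

    def test_one_sided_halves(self):
        rng = np.random.default_rng(71)
        a = synth._pseudo_chain(rng.normal(size=(10, 3)) * 3, "B")
        bb = synth._pseudo_chain(rng.normal(size=(10, 3)) * 3 + [5.0, 0, 0], "L")
        s = a.concat(bb)
        part = synth.receptor_partition()
        full = interdomain_bsa(s, part, split=(("body",), ("lid",)))
        half = interdomain_bsa(s, part, split=(("body",), ("lid",)), one_sided=True)
        assert half.total == pytest.approx(full.total / 2, rel=1e-12)

    def test_zero_iff_beyond_probe_reach(self):
        # BSA becomes exactly zero once separation exceeds r_i + r_j + 2*probe
        reach = 1.7 + 1.7 + 2 * 1.4
        part = synth.receptor_partition()
        for d, expect_zero in ((reach + 0.2, True), (reach - 0.5, False)):
            a = synth._pseudo_chain(np.zeros((1, 3)), "B")
            bb = synth._pseudo_chain(np.array([[d, 0.0, 0.0]]), "L")
            res = interdomain_bsa(a.concat(bb), part, split=(("body",), ("lid",)))
            assert (res.total == pytest.approx(0.0, abs=1e-9)) is expect_zero


class TestPeptideProfiles:
    def test_planned_contacts_only(self, peptide_complex):
        b = peptide_complex
        part = b.extras["partition"]
        prof = peptide_bsa_profile(b.extras["closed"], Selection("Q"), part,
                                   split=(("body",), ("lid",)), conformer="closed",
                                   points_per_atom=240)
        lid = prof.group_b
        assert np.all(lid[:7] == pytest.approx(0.0, abs=1e-9))
        assert np.all(lid[7:] > 10.0)

    def test_open_variant_zero_lid_burial(self, peptide_complex):
        b = peptide_complex
        prof = peptide_bsa_profile(b.extras["open"], Selection("Q"),
                                   b.extras["partition"],
                                   split=(("body",), ("lid",)), conformer="open",
                                   points_per_atom=240)
        assert np.all(prof.group_b == pytest.approx(0.0, abs=1e-9))

    def test_cumulative_difference_shape_and_telescoping(self, peptide_complex):
        b = peptide_complex
        part = b.extras["partition"]
        kw = dict(split=(("body",), ("lid",)), points_per_atom=240)
        closed = peptide_bsa_profile(b.extras["closed"], Selection("Q"), part,
                                     conformer="closed", **kw)
        open_ = peptide_bsa_profile(b.extras["open"], Selection("Q"), part,
                                    conformer="open", **kw)
        cum = cumulative_bsa_difference(closed, open_)
        # flat over the N-terminal residues, then rising
        assert np.all(np.abs(cum[:7]) < 1e-6)
        assert cum[-1] > cum[6]
        assert np.all(np.diff(cum) >= -1e-9)
        # telescoping identity
        assert cum[-1] == pytest.approx((closed.total - open_.total).sum(), rel=1e-12)

    def test_identical_profiles_flat_zero(self, peptide_complex):
        b = peptide_complex
        prof = peptide_bsa_profile(b.extras["closed"], Selection("Q"),
                                   b.extras["partition"],
                                   split=(("body",), ("lid",)), points_per_atom=60)
        np.testing.assert_allclose(cumulative_bsa_difference(prof, prof), 0.0)

    def test_single_step_difference(self):
        from hingekit.surface import BSAProfile
        keys = [("Q", i, "") for i in range(1, 11)]
        base = BSAProfile(keys, np.zeros(10), np.zeros(10), "open")
        bumped = BSAProfile(keys, np.zeros(10),
                            np.eye(10)[8] * 10.0, "closed")
        cum = cumulative_bsa_difference(bumped, base)
        np.testing.assert_allclose(cum[:8], 0.0)
        np.testing.assert_allclose(cum[8:], 10.0)

    def test_length_mismatch_raises(self):
        from hingekit.surface import BSAProfile
        a = BSAProfile([("Q", 1, "")], np.zeros(1), np.zeros(1))
        b = BSAProfile([("Q", 1, ""), ("Q", 2, "")], np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            cumulative_bsa_difference(a, b)


class TestSolvationEnergy:
    def test_no_interface_gives_zero_delta(self):
        b = synth.make_peptide_complex(atoms_per_globule=25, seed=13)
        part = b.extras["partition"]
        en = solvation_energy(b.extras["open"], part, split=(("body",), ("lid",)),
                              points_per_atom=240)
        assert en.delta == pytest.approx(0.0, abs=1e-9)

    def test_burying_carbon_surface_is_stabilizing(self):
        rng = np.random.default_rng(73)
        a = synth._pseudo_chain(rng.normal(size=(15, 3)) * 3, "B")
        bb = synth._pseudo_chain(rng.normal(size=(15, 3)) * 3 + [5.0, 0, 0], "L")
        s = a.concat(bb)
        en = solvation_energy(s, synth.receptor_partition(),
                              split=(("body",), ("lid",)))
        assert en.delta < 0   # hydrophobic stabilization on association

    def test_long_peptide_adds_closure_stabilization(self, peptide_complex):
        # closure with a lid-bridging peptide is more stabilizing than the
        # same closure measured without the peptide
        b = peptide_complex
        part = b.extras["partition"]
        kw = dict(split=(("body",), ("lid",)), points_per_atom=240)
        closed = b.extras["closed"]
        with_pep = solvation_energy(closed, part, **kw)
        bare = solvation_energy(closed.subset(closed.chain != "Q"), part, **kw)
        assert with_pep.delta < bare.delta


class TestContacts:
    def test_far_groups_empty(self):
        b = synth.make_peptide_complex(atoms_per_globule=25, seed=19)
        bare_open = b.extras["open"]
        ca, cb = interdomain_contacts(bare_open.subset(bare_open.chain != "Q"),
                                      b.extras["partition"],
                                      split=(("body",), ("lid",)))
        assert ca == [] and cb == []

    def test_constructed_contacts_found_and_symmetric(self):
        # two single-atom chains at 3.5 A plus a distant third residue
        a = synth._pseudo_chain(np.array([[0.0, 0, 0], [50.0, 0, 0]]), "B")
        bb = synth._pseudo_chain(np.array([[3.5, 0.0, 0.0]]), "L")
        s = a.concat(bb)
        ca, cb = interdomain_contacts(s, synth.receptor_partition(),
                                      split=(("body",), ("lid",)), cutoff=4.0)
        assert [k[1] for k in ca] == [1]
        assert len(cb) == 1

    def test_closed_minus_open_difference(self, peptide_complex):
        b = peptide_complex
        part = b.extras["partition"]
        kw = dict(split=(("body",), ("lid",)), cutoff=4.5)
        closed = interdomain_contacts(b.extras["closed"], part, **kw)
        open_ = interdomain_contacts(b.extras["open"], part, **kw)
        gained = contact_difference(closed, open_)
        # peptide residues 8-10 ride with the body side and touch the lid
        assert {k[1] for k in gained[0] if k[0] == "Q"} == {8, 9, 10}
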