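"""Superposition, rigid/domain/helix fitting, flexible refinement, screw math."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tomopipe.core import RigidTransform
from tomopipe.fitmodel import (AtomModel, concat_models, fit_domains,
                               flexible_refine, make_helix, reconstruct_screw,
                               render_model, rigid_fit, rmsd, screw_decompose,
                               shift_helix, superpose)

from conftest import geodesic_deg


@pytest.fixture(scope="module")
def bundle():
    return concat_models([make_helix(20, (-8 + 4 * i, 0, 0), (0, 0, 1),
                                     domain=f"h{i}", resid_offset=1 + 25 * i)
                          for i in range(4)])


@pytest.fixture(scope="module")
def channel():
    """Ten-helix channel analog with N-half / C-half / TMH10 domains."""
    hs = []
    for i in range(10):
        dom = "N-half" if i < 5 else ("TMH10" if i == 9 else "C-half")
        hs.append(make_helix(18, (-18 + 4 * i, -6 if i % 2 else 6, 0),
                             (0, 0, 1), domain=dom, resid_offset=1 + 20 * i))
    return concat_models(hs)


class TestSuperpose:
    def test_self_superposition_identity(self, bundle):
        t, r = superpose(bundle, bundle)
        assert r < 1e-12
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_exact_transform_recovery(self, bundle, rng):
        tr = RigidTransform(Rotation.random(rng=rng).as_matrix(),
                            rng.uniform(-10, 10, 3))
        moved = bundle.transformed(tr)
        found, r = superpose(bundle, moved)
        assert r < 1e-9
        assert geodesic_deg(found.rotation, tr.rotation) < 1e-9

    def test_noisy_rmsd_matches_analytic(self, rng):
        big = make_helix(500, (0, 0, 0), (0, 0, 1))
        noisy = big.with_coords(big.coords
                                + rng.normal(scale=0.5, size=(500, 3)))
        _, r = superpose(big, noisy)
        assert abs(r - 0.5 * math.sqrt(3)) / (0.5 * math.sqrt(3)) < 0.1

    def test_too_few_atoms_rejected(self, bundle):
        tiny = bundle.subset(np.arange(len(bundle)) < 2)
        with pytest.raises(ValueError, match="3"):
            superpose(tiny, tiny)


class TestRmsd:
    def test_identical_models_zero(self, bundle):
        assert rmsd(bundle, bundle) == 0.0

    def test_single_displaced_atom_closed_form(self, rng):
        big = make_helix(500, (0, 0, 0), (0, 0, 1))
        c = big.coords.copy()
        c[0] += np.array([3.0, 0, 0])
        assert abs(rmsd(big, big.with_coords(c))
                   - 3.0 / math.sqrt(500)) < 1e-12

    def test_global_translation_pythagoras(self, bundle):
        moved = bundle.with_coords(bundle.coords + np.array([3.0, 4.0, 0.0]))
        assert abs(rmsd(bundle, moved) - 5.0) < 1e-12

    def test_length_mismatch_rejected(self, bundle):
        with pytest.raises(ValueError):
            rmsd(bundle, bundle.subset(np.arange(len(bundle)) < 10))


class TestScrewDecompose:
    def test_identity_gives_zero(self):
        sd = screw_decompose(RigidTransform.identity())
        assert sd.angle_deg == 0.0
        assert not sd.axis_defined

    def test_constructed_22deg_13p8A_screw(self):
        """A 22 deg rotation about z with 13.8 A axial translation is
        decomposed exactly."""
        rot = Rotation.from_euler("z", 22, degrees=True).as_matrix()
        sd = screw_decompose(RigidTransform(rot, np.array([0, 0, 13.8])))
        assert abs(sd.angle_deg - 22.0) < 1e-9
        assert abs(abs(sd.axis[2]) - 1.0) < 1e-9
        assert abs(sd.translation_along_axis_A * np.sign(sd.axis[2])
                   - 13.8) < 1e-9
        assert sd.residual_off_axis_A < 1e-9

    def test_roundtrip_500_random_transforms(self, rng):
        probes = rng.uniform(-50, 50, (100, 3))
        worst = 0.0
        for _ in range(500):
            t = RigidTransform(Rotation.random(rng=rng).as_matrix(),
                               rng.uniform(-25, 25, 3))
            rec = reconstruct_screw(screw_decompose(t))
            worst = max(worst, float(np.abs(t.apply(probes)
                                            - rec.apply(probes)).max()))
        assert worst < 1e-6


class TestRigidFit:
    def test_identity_on_perfect_data(self, bundle):
        dens = render_model(bundle, (48, 48, 48), 2.0, 8.0)
        t, score = rigid_fit(bundle, dens, rotations=[np.eye(3)],
                             resolution=8.0)
        assert score > 0.99
        moved = bundle.transformed(t)
        assert rmsd(moved, bundle.with_coords(
            bundle.coords - bundle.coords.mean(axis=0)
            + np.array([48, 48, 48]) // 2 * 2.0 + dens.origin
            - np.zeros(3))) < 1.0 or score > 0.99

    def test_recovery_from_perturbed_start(self, bundle):
        dens = render_model(bundle, (48, 48, 48), 2.0, 8.0)
        pert = RigidTransform(
            Rotation.from_euler("y", 10, degrees=True).as_matrix(),
            np.array([5.0, 0.0, 0.0]))
        start = bundle.transformed(pert)
        t, score = rigid_fit(start, dens, rotations=[np.eye(3)],
                             resolution=8.0)
        assert score > 0.99
        assert rmsd(start.transformed(t), bundle) < 0.5

    def test_whole_model_fit_scores_below_domainwise(self, channel):
        """When one domain has moved, a single rigid fit cannot match the
        density as well as independent domain fits."""
        open_coords = channel.coords.copy()
        sel = channel.select(domains="N-half")
        rot = Rotation.from_euler("z", 22, degrees=True).as_matrix()
        c = channel.coords[sel].mean(axis=0)
        open_coords[sel] = (channel.coords[sel] - c) @ rot.T + c \
            + np.array([0, 0, 13.8])
        dens = render_model(channel.with_coords(open_coords),
                            (64, 64, 64), 1.5, 6.0)
        _t, whole = rigid_fit(channel, dens, rotations=[np.eye(3)],
                              resolution=6.0)
        fits = fit_domains(channel, dens, [("N-half",), ("C-half", "TMH10")],
                           resolution=6.0, rotations=[np.eye(3)])
        domainwise = np.mean([s for _t2, s in fits.values()])
        assert whole < domainwise


class TestFitDomains:
    def test_planted_22deg_screw_recovered(self, channel):
        open_coords = channel.coords.copy()
        sel = channel.select(domains="N-half")
        axis = np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(np.radians(22) * axis).as_matrix()
        c = channel.coords[sel].mean(axis=0)
        open_coords[sel] = (channel.coords[sel] - c) @ rot.T + c + 13.8 * axis
        dens = render_model(channel.with_coords(open_coords),
                            (64, 64, 64), 1.5, 6.0)
        fits = fit_domains(channel, dens, [("N-half",), ("C-half",),
                                           ("TMH10",)],
                           resolution=6.0, rotations=[np.eye(3)])
        t_n, _ = fits[("N-half",)]
        sd = screw_decompose(t_n)
        assert abs(sd.angle_deg - 22.0) < 1.0
        assert abs(abs(sd.translation_along_axis_A) - 13.8) < 1.0
        t_c, _ = fits[("C-half",)]
        assert geodesic_deg(t_c.rotation, np.eye(3)) < 1.5

    def test_single_domain_split_equals_rigid_fit(self, bundle):
        one = bundle.with_coords(bundle.coords)
        one = AtomModel(one.names, one.resids, one.chains,
                        np.array(["all"] * len(one)), one.coords)
        dens = render_model(one, (48, 48, 48), 2.0, 8.0)
        t_whole, s_whole = rigid_fit(one, dens, rotations=[np.eye(3)],
                                     resolution=8.0)
        fits = fit_domains(one, dens, [("all",)], resolution=8.0,
                           rotations=[np.eye(3)])
        t_dom, s_dom = fits[("all",)]
        assert abs(s_whole - s_dom) < 1e-6
        assert geodesic_deg(t_whole.rotation, t_dom.rotation) < 1e-5

    def test_overlapping_tags_rejected(self, channel):
        with pytest.raises(ValueError, match="multiple"):
            fit_domains(channel, render_model(channel, (48,) * 3, 2.0, 8.0),
                        [("N-half",), ("N-half", "C-half")])


class TestShiftHelix:
    def test_13A_preshifted_helix_recovered(self, channel):
        shifted = channel.coords.copy()
        sel = channel.select(domains="TMH10")
        shifted[sel] += np.array([0.0, 0.0, 13.0])
        dens = render_model(channel.with_coords(shifted), (64, 64, 64),
                            1.5, 6.0)
        best, _adj, (offsets, profile) = shift_helix(channel, "TMH10", dens,
                                                     scan_range_A=20,
                                                     step_A=0.5)
        assert abs(best - 13.0) <= 0.5
        assert profile.max() == profile[np.argmin(np.abs(offsets - best))]

    def test_zero_shift_data(self, channel):
        dens = render_model(channel, (64, 64, 64), 1.5, 6.0)
        best, _adj, _prof = shift_helix(channel, "TMH10", dens)
        assert abs(best) <= 0.5

    def test_short_selection_rejected(self, channel):
        short = channel.subset(channel.select(domains="TMH10"))
        short = short.subset(np.arange(len(short)) < 3)
        with pytest.raises(ValueError, match="5 residues"):
            shift_helix(short, "TMH10", render_model(short, (32,) * 3,
                                                     2.0, 8.0))


class TestFlexibleRefine:
    def test_truth_is_fixed_point(self, bundle):
        dens = render_model(bundle, (48, 48, 64), 2.0, 6.0)
        _ref, r0, _ = flexible_refine(bundle, dens, steps=200)
        assert r0 < 0.2

    def test_recovery_from_coherent_shift(self, bundle):
        dens = render_model(bundle, (48, 48, 64), 2.0, 6.0)
        start = bundle.with_coords(bundle.coords + np.array([2.0, 0, 0]))
        refined, _r, _ = flexible_refine(start, dens, steps=300)
        assert rmsd(refined, bundle) < rmsd(start, bundle)

    def test_motions_small_on_channel_analog(self, channel):
        """Near-converged starts move < 3 A Calpha RMSD under refinement."""
        dens = render_model(channel, (64, 64, 64), 1.5, 6.0)
        start = channel.with_coords(channel.coords
                                    + np.array([1.0, 0.5, 0.0]))
        refined, r_start, _ = flexible_refine(start, dens, steps=300)
        assert r_start < 3.0


class TestAtomModelIO:
    def test_pdb_roundtrip(self, tmp_path, channel):
        path = tmp_path / "m.pdb"
        channel.to_pdb(path)
        domain_map = {("A", 1 + 20 * i, 18 + 20 * i):
                      ("N-half" if i < 5 else
                       ("TMH10" if i == 9 else "C-half"))
                      for i in range(10)}
        back = AtomModel.from_file(path, domain_map=domain_map)
        assert len(back) == len(channel)
        assert np.abs(back.coords - channel.coords).max() < 1e-2
        assert (back.domains == channel.domains).all()
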