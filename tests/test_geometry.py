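import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgpflex import geometry, synthetic
from pgpflex.ensemble_io import resolve_selection
from pgpflex.geometry import (
    B_FACTOR_PREFACTOR,
    DistanceTrace,
    center_of_mass,
    com_distance_trace,
    contact_count_trace,
    pair_distance,
    pooled_histogram,
    rmsd_to_template,
    rmsf,
    rmsf_to_bfactor,
    superpose,
)

from conftest import build_ensemble


def cloud_ensemble(rng, n_atoms=50, n_frames=1, elements=("C", "N", "O", "S")):
    specs = [("CA", "ALA", i + 1, "A", elements[i % len(elements)])
             for i in range(n_atoms)]
    coords = rng.normal(0, 5, size=(n_frames, n_atoms, 3))
    return build_ensemble(specs, coords)


def kabsch_rmsd(x, y):
    """Independent minimal-RMSD oracle (plain Kabsch, no library)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    C = xc.T @ yc
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    S[-1] *= d
    e0 = (xc ** 2).sum() + (yc ** 2).sum()
    return math.sqrt(max(e0 - 2 * S.sum(), 0.0) / len(x))


class TestCenterOfMass:
    def test_two_equal_mass_atoms(self):
        ens = build_ensemble([("CA", "ALA", 1, "A", "C"), ("CA", "ALA", 2, "A", "C")],
                             [[[0, 0, 0], [2, 0, 0]]])
        np.testing.assert_allclose(center_of_mass(ens, "chain A", 0), [1, 0, 0])

    def test_single_atom_identity(self):
        ens = build_ensemble([("CA", "ALA", 1, "A", "C")], [[[1.5, -2.0, 3.0]]])
        np.testing.assert_allclose(center_of_mass(ens, "resid 1", 0), [1.5, -2.0, 3.0])

    def test_mass_weighted_matches_brute_force(self, rng):
        ens = cloud_ensemble(rng)
        got = center_of_mass(ens, "chain A", 0, weighting="mass")
        m = ens.masses
        expected = (m[:, None] * ens.coords[0]).sum(axis=0) / m.sum()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_geometric_weighting_is_plain_centroid(self, rng):
        ens = cloud_ensemble(rng)
        got = center_of_mass(ens, "chain A", 0, weighting="geometric")
        np.testing.assert_allclose(got, ens.coords[0].mean(axis=0), atol=1e-12)


class TestComDistanceTrace:
    def test_identical_selections_give_zero(self, hinged):
        ens, _ = hinged
        tr = com_distance_trace(ens, "chain A", "chain A")
        np.testing.assert_allclose(tr.d, 0.0, atol=1e-12)

    def test_three_four_five(self):
        ens = build_ensemble([("CA", "ALA", 1, "A", "C"), ("CA", "ALA", 2, "A", "C")],
                             [[[0, 0, 0], [3, 4, 0]]])
        tr = com_distance_trace(ens, "resid 1", "resid 2")
        np.testing.assert_allclose(tr.d, [5.0])

    def test_planted_signal_recovered_within_noise_bound(self, hinged):
        ens, manifest = hinged
        tr = com_distance_trace(ens, "chain A", "chain B")
        planted = np.array(manifest["planted_distance"])
        sigma = manifest["thermal_sigma"]
        n = manifest["n_atoms_per_domain"]
        bound = 3.0 * sigma * math.sqrt(2.0 / n)
        assert np.abs(tr.d - planted).max() <= bound

    def test_invariant_under_per_frame_rigid_motion(self, hinged, rng):
        ens, _ = hinged
        moved = ens.coords.copy()
        for f in range(ens.n_frames):
            axis = rng.normal(size=3)
            angle = rng.uniform(0, 2 * math.pi)
            R = _rotation(axis, angle)
            moved[f] = moved[f] @ R.T + rng.normal(0, 50, size=3)
        ens2 = build_ensemble(
            [(a.name, a.resname, a.resid, a.chain, a.element) for a in ens.atoms],
            moved)
        t1 = com_distance_trace(ens, "chain A", "chain B")
        t2 = com_distance_trace(ens2, "chain A", "chain B")
        np.testing.assert_allclose(t1.d, t2.d, atol=1e-8)


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


class TestPooledHistogram:
    def test_constant_trace_single_bin(self):
        tr = DistanceTrace(frame_index=np.arange(5), d=np.full(5, 40.0),
                           label_a="a", label_b="b")
        h = pooled_histogram([tr])
        assert np.count_nonzero(h.p) == 1
        assert h.mean == 40.0
        assert h.bin_width == pytest.approx(0.1)

    def test_pooled_mean_is_arithmetic_mean_of_trace_means(self):
        t1 = DistanceTrace(frame_index=np.arange(4), d=np.full(4, 39.0),
                           label_a="a", label_b="b")
        t2 = DistanceTrace(frame_index=np.arange(4), d=np.full(4, 41.0),
                           label_a="a", label_b="b")
        assert pooled_histogram([t1, t2]).mean == pytest.approx(40.0)

    def test_edge_sample_goes_to_upper_bin(self):
        tr = DistanceTrace(frame_index=np.arange(1), d=np.array([0.2]),
                           label_a="a", label_b="b")
        h = pooled_histogram([tr], bin_width=0.1)
        i = np.flatnonzero(h.p)[0]
        assert h.bin_edges[i] == pytest.approx(0.2)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.floats(0.1, 99.0), min_size=1, max_size=40),
                    min_size=1, max_size=4))
    def test_mass_conservation_and_brute_force_mean(self, samples):
        traces = [DistanceTrace(frame_index=np.arange(len(s)), d=np.array(s),
                                label_a="a", label_b="b") for s in samples]
        h = pooled_histogram(traces)
        assert abs(h.p.sum() - 1.0) <= 1e-12
        pooled = np.concatenate([np.array(s) for s in samples])
        assert h.mean == pytest.approx(pooled.mean(), abs=1e-12)
        assert h.n_samples == pooled.size

    def test_discard_first_frames(self):
        tr = DistanceTrace(frame_index=np.arange(4),
                           d=np.array([100.0, 1.0, 1.0, 1.0]),
                           label_a="a", label_b="b")
        h = pooled_histogram([tr], discard_first=1)
        assert h.mean == pytest.approx(1.0)


class TestSuperposeAndRmsf:
    def _translated_frames(self, rng, n_frames=5):
        base = rng.normal(0, 4, size=(12, 3))
        coords = np.stack([base + rng.normal(0, 20, size=3) for _ in range(n_frames)])
        specs = [("CA", "ALA", i + 1, "A", "C") for i in range(12)]
        return build_ensemble(specs, coords)

    def test_pure_translations_collapse(self, rng):
        ens = self._translated_frames(rng)
        fit = superpose(ens, "chain A")
        spread = fit.coords - fit.coords.mean(axis=0)
        assert np.abs(spread).max() < 1e-8

    def test_pure_rotations_collapse(self, rng):
        base = rng.normal(0, 4, size=(12, 3))
        frames = [base]
        for _ in range(4):
            frames.append(base @ _rotation(rng.normal(size=3),
                                           rng.uniform(0, 2 * math.pi)).T)
        specs = [("CA", "ALA", i + 1, "A", "C") for i in range(12)]
        ens = build_ensemble(specs, np.stack(frames))
        fit = superpose(ens, "chain A")
        spread = fit.coords - fit.coords.mean(axis=0)
        assert np.abs(spread).max() < 1e-8

    def test_collinear_fit_set_is_error(self):
        specs = [("CA", "ALA", i + 1, "A", "C") for i in range(3)]
        coords = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]] * 2, dtype=float)
        ens = build_ensemble(specs, coords)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(ens, "chain A")

    def test_static_ensemble_rmsf_zero(self, rng):
        base = rng.normal(0, 4, size=(8, 3))
        specs = [("CA", "ALA", i + 1, "A", "C") for i in range(8)]
        ens = build_ensemble(specs, np.stack([base, base]))
        prof = rmsf(ens, "chain A")
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_two_frame_displacement_closed_form(self):
        specs = [("CA", "ALA", 1, "A", "C")]
        d = 0.7
        ens = build_ensemble(specs, [[[+d, 0, 0]], [[-d, 0, 0]]])
        prof = rmsf(ens, "resid 1")
        assert prof.rmsf[0] == pytest.approx(d)

    def test_isotropic_jitter_approaches_sigma_sqrt3(self, rng):
        sigma = 0.4
        coords = rng.normal(0, sigma, size=(10_000, 1, 3))
        ens = build_ensemble([("CA", "ALA", 1, "A", "C")], coords)
        prof = rmsf(ens, "resid 1")
        assert prof.rmsf[0] == pytest.approx(sigma * math.sqrt(3), rel=0.02)

    def test_rmsf_needs_two_frames(self, rng):
        ens = cloud_ensemble(rng, n_frames=1)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(ens, "chain A")

    def test_rmsf_invariant_to_frame_order(self, hinged):
        ens, _ = hinged
        fit = superpose(ens, "chain A and name CA")
        prof = rmsf(fit, "chain A and name CA")
        perm = np.random.default_rng(0).permutation(ens.n_frames)
        ens2 = build_ensemble(
            [(a.name, a.resname, a.resid, a.chain, a.element) for a in ens.atoms],
            fit.coords[perm])
        prof2 = rmsf(ens2, "chain A and name CA")
        np.testing.assert_allclose(prof.rmsf, prof2.rmsf, atol=1e-10)


class TestBFactors:
    def test_ratio_is_exactly_8pi2_over_3(self, rng):
        from pgpflex.geometry import RMSFProfile
        prof = RMSFProfile(chain=["A"] * 20, resid=list(range(20)),
                           rmsf=rng.uniform(0, 3, size=20))
        theta = rmsf_to_bfactor(prof)
        mask = prof.rmsf > 0
        np.testing.assert_allclose(theta.theta[mask] / prof.rmsf[mask] ** 2,
                                   B_FACTOR_PREFACTOR, atol=1e-12)

    def test_zero_maps_to_zero_and_doubling_quadruples(self):
        from pgpflex.geometry import RMSFProfile
        p1 = RMSFProfile(chain=["A"], resid=[1], rmsf=np.array([1.0]))
        p2 = RMSFProfile(chain=["A"], resid=[1], rmsf=np.array([2.0]))
        p0 = RMSFProfile(chain=["A"], resid=[1], rmsf=np.array([0.0]))
        assert rmsf_to_bfactor(p0).theta[0] == 0.0
        assert rmsf_to_bfactor(p1).theta[0] == pytest.approx(8 * math.pi ** 2 / 3)
        assert rmsf_to_bfactor(p2).theta[0] == pytest.approx(
            4 * rmsf_to_bfactor(p1).theta[0])


class TestRmsdToTemplate:
    def test_template_equals_frame_gives_zero(self, rng):
        ens = cloud_ensemble(rng, n_atoms=9)
        sel = resolve_selection(ens, "chain A")
        tr = rmsd_to_template(ens, sel, ens.coords[0])
        assert tr.d[0] == pytest.approx(0.0, abs=1e-8)

    def test_rotation_invariance(self, rng):
        ens = cloud_ensemble(rng, n_atoms=9)
        sel = resolve_selection(ens, "chain A")
        R = _rotation([0.3, -1.0, 0.7], 1.1)
        tr = rmsd_to_template(ens, sel, ens.coords[0] @ R.T + np.array([5, 6, 7]))
        assert tr.d[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_kabsch_oracle(self, rng):
        ens = cloud_ensemble(rng, n_atoms=9, n_frames=6)
        sel = resolve_selection(ens, "chain A")
        template = rng.normal(0, 5, size=(9, 3))
        tr = rmsd_to_template(ens, sel, template)
        for f in range(6):
            assert tr.d[f] == pytest.approx(
                kabsch_rmsd(template, ens.coords[f]), abs=1e-8)

    def test_fitted_rmsd_never_exceeds_raw_rmsd(self, rng):
        ens = cloud_ensemble(rng, n_atoms=9, n_frames=6)
        sel = resolve_selection(ens, "chain A")
        template = rng.normal(0, 5, size=(9, 3))
        tr = rmsd_to_template(ens, sel, template)
        for f in range(6):
            raw = math.sqrt(((ens.coords[f] - template) ** 2).sum(axis=1).mean())
            assert tr.d[f] <= raw + 1e-12


class TestPairDistanceAndContacts:
    def test_unit_distance_and_symmetry(self):
        ens = build_ensemble([("CB", "ALA", 613, "A", "C"),
                              ("CB", "ALA", 1258, "B", "C")],
                             [[[0, 0, 0], [0, 0, 1]]])
        d1 = pair_distance(ens, "resid 613", "resid 1258")
        d2 = pair_distance(ens, "resid 1258", "resid 613")
        assert d1 == pytest.approx(1.0)
        assert d1 == d2

    def test_multi_atom_spec_is_error(self, rng):
        ens = cloud_ensemble(rng)
        with pytest.raises(ValueError, match="exactly 1"):
            pair_distance(ens, "chain A", "resid 1")

    def test_far_probe_counts_zero(self):
        ens = build_ensemble([("C1", "OLA", 1, "L", "C"),
                              ("CA", "ALA", 300, "A", "C")],
                             [[[100, 0, 0], [0, 0, 0]]])
        cc = contact_count_trace(ens, "chain L", "chain A")
        assert cc.count[0] == 0

    def test_boundary_inside_cutoff(self):
        ens = build_ensemble([("C1", "OLA", 1, "L", "C"),
                              ("CA", "ALA", 300, "A", "C")],
                             [[[3.9, 0, 0], [0, 0, 0]]])
        cc = contact_count_trace(ens, "chain L", "chain A", cutoff=4.0)
        assert cc.count[0] == 1

    def test_matches_brute_force_double_loop(self, rng):
        n_probe, n_site = 30, 25
        specs = ([("C1", "OLA", i + 1, "L", "C") for i in range(n_probe)]
                 + [("CA", "ALA", i + 1, "A", "C") for i in range(n_site)])
        coords = rng.uniform(0, 15, size=(3, n_probe + n_site, 3))
        ens = build_ensemble(specs, coords)
        cc = contact_count_trace(ens, "chain L", "chain A", cutoff=4.0)
        for f in range(3):
            brute = 0
            for i in range(n_probe):
                for j in range(n_site):
                    if np.linalg.norm(coords[f, i] - coords[f, n_probe + j]) <= 4.0:
                        brute += 1
                        break
            assert cc.count[f] == brute
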