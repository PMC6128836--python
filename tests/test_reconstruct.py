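"""Direct-Fourier reconstruction: insertion, Ewald correction, refinement."""

import numpy as np
import pytest

from ewaldrec import (
    CTFParams,
    OpticsModel,
    ReconstructionSettings,
    fsc,
    make_blob_phantom,
    symmetrize_volume,
)
from ewaldrec._fft import cfft2, cfftn
from ewaldrec.geometry import Orientation, random_orientations
from ewaldrec.reconstruct import (
    FourierAccumulator,
    _hermitian_mirror,
    finalize_map,
    flip_handedness,
    insert_image_central,
    insert_image_ewald,
    reconstruct,
    refine_defocus_per_particle,
    weight_particles,
)
from ewaldrec.simulate import (
    ParticleSet,
    project_central_slice,
    simulate_dataset,
)
from ewaldrec.experiment import crossing_shell

IDENTITY = Orientation(0.0, 0.0, 0.0)
OPTICS = OpticsModel(pixel_size=1.25, wavelength=0.15, cs_mm=0.5)


class TestCentralInsertion:
    def test_single_slice_identity(self, small_phantom):
        img = project_central_slice(small_phantom, IDENTITY)
        acc = FourierAccumulator(small_phantom.box, small_phantom.pixel_size)
        insert_image_central(acc, img, IDENTITY, None, OPTICS)
        vol = finalize_map(acc, ReconstructionSettings(wiener_constant=1e-9))
        c = small_phantom.box // 2
        central = cfftn(vol.grid)[c]
        expected = cfft2(img)
        # compare where the plane was actually filled (inside the sphere)
        k = np.arange(small_phantom.box) - c
        ky, kx = np.meshgrid(k, k, indexing="ij")
        mask = np.hypot(kx, ky) <= c - 2
        np.testing.assert_allclose(
            central[mask], expected[mask], atol=2e-6 * np.abs(expected).max()
        )

    def test_zero_weight_leaves_accumulator(self, small_phantom):
        img = project_central_slice(small_phantom, IDENTITY)
        acc = FourierAccumulator(small_phantom.box, small_phantom.pixel_size)
        insert_image_central(acc, img, IDENTITY, None, OPTICS, weight=0.0)
        assert not acc.numerator.any() and not acc.denominator.any()

    def test_box_mismatch(self, small_phantom):
        acc = FourierAccumulator(32, 1.25)
        with pytest.raises(ValueError):
            insert_image_central(
                acc, np.zeros((48, 48)), IDENTITY, None, OPTICS
            )

    def test_ctf_free_self_consistency(self, small_phantom, rng):
        # noise-free, CTF-free projections from many directions recover the
        # phantom to high FSC below ~0.8 Nyquist
        acc = FourierAccumulator(small_phantom.box, small_phantom.pixel_size)
        for o in random_orientations(300, np.random.default_rng(15)):
            insert_image_central(acc, project_central_slice(small_phantom, o), o, None, OPTICS)
        vol = finalize_map(acc, ReconstructionSettings(wiener_constant=1e-3))
        curve = fsc(vol, small_phantom)
        n80 = int(0.8 * len(curve))
        assert curve.correlations[:n80].min() > 0.9


class TestEwaldInsertion:
    ctf = CTFParams(9000.0, 9000.0)

    def _accumulate(self, phantom, mode, optics, n=40):
        rng = np.random.default_rng(7)
        acc = FourierAccumulator(phantom.box, phantom.pixel_size)
        for o in random_orientations(n, rng):
            img = project_central_slice(phantom, o)
            if mode == "central":
                insert_image_central(acc, img, o, self.ctf, optics)
            else:
                insert_image_ewald(acc, img, o, self.ctf, optics, hand=+1)
        return acc

    def test_vanishing_curvature_matches_central(self, small_phantom):
        optics0 = OpticsModel(pixel_size=1.25, wavelength=1e-8, cs_mm=0.5)
        acc_c = self._accumulate(small_phantom, "central", optics0)
        acc_e = self._accumulate(small_phantom, "ewald", optics0)
        num_c = 0.5 * (acc_c.numerator + np.conj(_hermitian_mirror(acc_c.numerator)))
        num_e = 0.5 * (acc_e.numerator + np.conj(_hermitian_mirror(acc_e.numerator)))
        # denominators agree exactly (|CTF|^2 weighting in both schemes)
        np.testing.assert_allclose(
            acc_e.denominator, acc_c.denominator, atol=1e-5 * acc_c.denominator.max()
        )
        # numerator phases agree where power is significant; amplitudes agree
        # up to the positive per-coefficient |CTF| demodulation factor
        strong = np.abs(num_c) > 1e-3 * np.abs(num_c).max()
        phase = np.angle(num_e[strong] * np.conj(num_c[strong]))
        assert np.abs(phase).max() < 1e-4
        m_c = finalize_map(acc_c, ReconstructionSettings(wiener_constant=1e-3))
        m_e = finalize_map(acc_e, ReconstructionSettings(wiener_constant=1e-3))
        corr = np.corrcoef(m_c.grid.ravel(), m_e.grid.ravel())[0, 1]
        assert corr > 0.995

    def test_hermitian_accumulation(self, small_phantom):
        acc = self._accumulate(small_phantom, "ewald", OPTICS, n=10)
        vol = finalize_map(acc)  # raises if the symmetrised map is not real
        assert np.isrealobj(vol.grid)

    def test_invalid_hand(self, small_phantom):
        acc = FourierAccumulator(small_phantom.box, small_phantom.pixel_size)
        img = project_central_slice(small_phantom, IDENTITY)
        with pytest.raises(ValueError):
            insert_image_ewald(acc, img, IDENTITY, self.ctf, OPTICS, hand=2)


class TestFinalize:
    def test_empty_accumulator(self):
        with pytest.raises(ValueError):
            finalize_map(FourierAccumulator(16, 1.0))

    def test_wiener_damping_monotone(self, small_phantom):
        img = project_central_slice(small_phantom, IDENTITY)
        acc = FourierAccumulator(small_phantom.box, small_phantom.pixel_size)
        insert_image_central(acc, img, IDENTITY, CTFParams(8000, 8000), OPTICS)
        p = []
        for w in (0.01, 0.02):
            vol = finalize_map(acc, ReconstructionSettings(wiener_constant=w))
            f = np.abs(cfftn(vol.grid)) ** 2
            p.append(f)
        assert np.all(p[1] <= p[0] + 1e-12)


class TestFlipHandedness:
    def test_methods_formula(self):
        o = flip_handedness(Orientation(10.0, 20.0, 30.0))
        assert (o.phi, o.theta, o.psi) == pytest.approx((-10.0, 160.0, 30.0))

    def test_involution(self):
        o = Orientation(-47.0, 112.0, 163.0)
        back = flip_handedness(flip_handedness(o))
        assert (back.phi, back.theta, back.psi) == pytest.approx((o.phi, o.theta, o.psi))

    def test_equator_fixed_point(self):
        o = flip_handedness(Orientation(0.0, 90.0, 0.0))
        assert (o.phi, o.theta, o.psi) == pytest.approx((0.0, 90.0, 0.0))


class TestReconstruct:
    def test_identical_half_sets_give_unit_fsc(self, small_phantom):
        ps0 = simulate_dataset(small_phantom, 1, OPTICS, snr=np.inf, seed=3, n_slabs=1)
        ps = ParticleSet(
            images=np.repeat(ps0.images, 2, axis=0),
            orientations=ps0.orientations * 2,
            ctf_params=ps0.ctf_params * 2,
            pixel_size=ps0.pixel_size,
        )
        h1, h2, _ = reconstruct(ps, ReconstructionSettings(), OPTICS)
        curve = fsc(h1, h2)
        np.testing.assert_allclose(curve.correlations, 1.0, atol=1e-9)

    def test_empty_set_rejected(self, small_phantom):
        ps = simulate_dataset(small_phantom, 1, OPTICS, snr=np.inf, seed=3, n_slabs=1)
        from ewaldrec.experiment import subset

        with pytest.raises(ValueError):
            reconstruct(subset(ps, np.array([], dtype=int)), ReconstructionSettings(), OPTICS)

    def test_symmetry_expansion_beats_c1(self):
        # on an icosahedrally symmetric phantom, imposing I reaches at least
        # the C1 resolution with the same (small, noisy) particle set
        base = make_blob_phantom(40, 1.25, 36.0, n_blobs=40, seed=4, sigma_range=(1.2, 2.0))
        phantom = symmetrize_volume(base, "I")
        optics = OpticsModel(pixel_size=1.25, wavelength=0.05, cs_mm=0.5)
        ps = simulate_dataset(phantom, 24, optics, snr=0.5, seed=5, n_slabs=1)
        shells = {}
        for sym in ("C1", "I"):
            h1, h2, _ = reconstruct(
                ps, ReconstructionSettings(symmetry=sym), optics
            )
            shells[sym] = crossing_shell(fsc(h1, h2), 0.143)
        assert shells["I"] >= shells["C1"]


class TestDefocusRefinement:
    optics = OPTICS

    def _dataset(self, phantom, offsets, seed=11):
        return simulate_dataset(
            phantom, len(offsets), self.optics, snr=np.inf, seed=seed,
            n_slabs=1, defocus_offsets=np.array(offsets),
        )

    def test_zero_offets_recovered_within_step(self, small_phantom):
        ps = self._dataset(small_phantom, [0.0] * 6)
        out = refine_defocus_per_particle(ps, small_phantom, self.optics, 400.0, 100.0)
        rec = np.array([c.defocus_u for c in out.ctf_params]) - np.array(
            [c.defocus_u for c in ps.ctf_params]
        )
        assert np.abs(rec).max() <= 100.0

    def test_systematic_offset_recovered(self, small_phantom):
        ps = self._dataset(small_phantom, [300.0] * 8)
        out = refine_defocus_per_particle(ps, small_phantom, self.optics, 500.0, 50.0)
        rec = np.array([c.defocus_u for c in out.ctf_params]) - np.array(
            [c.defocus_u for c in ps.ctf_params]
        )
        assert abs(rec.mean() - 300.0) <= 50.0
        assert np.all(out.scores > 0.9)  # exact reference, noise-free


class TestWeighting:
    def _ps(self, small_phantom):
        ps = simulate_dataset(small_phantom, 4, OPTICS, snr=np.inf, seed=2, n_slabs=1)
        ps.scores = np.array([2.0, 8.0, 5.0, -1.0])
        return ps

    def test_equal(self, small_phantom):
        out = weight_particles(self._ps(small_phantom), "equal")
        np.testing.assert_array_equal(out.weights, 1.0)

    def test_threshold(self, small_phantom):
        out = weight_particles(self._ps(small_phantom), "score_threshold", tau=4.0)
        np.testing.assert_array_equal(out.weights, [0.0, 1.0, 1.0, 0.0])
        below_min = weight_particles(self._ps(small_phantom), "score_threshold", tau=-5.0)
        np.testing.assert_array_equal(below_min.weights, 1.0)

    def test_proportional_mean_one(self, small_phantom):
        out = weight_particles(self._ps(small_phantom), "score_proportional")
        assert out.weights.mean() == pytest.approx(1.0)
        assert np.all(out.weights >= 0)

    def test_missing_scores(self, small_phantom):
        ps = self._ps(small_phantom)
        ps.scores = None
        with pytest.raises(ValueError):
            weight_particles(ps, "score_threshold", tau=1.0)
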