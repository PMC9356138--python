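"""Phasor transform math, phasor-plane clustering and probe unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import srscell as sc
from srscell.errors import ConditioningError, InsufficientDataError
from srscell.phasor import spectrum_phasor
from srscell.synthetic import make_component_spectrum


def _stack_from_pixels(pixels):
    """(n_pix, n_ch) spectra -> 1 x n_pix stack with a linear axis."""
    pixels = np.asarray(pixels, dtype=float)
    data = pixels.T[:, None, :]
    wn = np.linspace(2800, 3050, pixels.shape[1])
    return sc.HyperspectralStack(data=data, wavenumbers=wn)


class TestPhasorTransform:
    def test_constant_spectrum_maps_to_origin(self):
        stack = _stack_from_pixels(np.full((1, 50), 3.0))
        f = sc.phasor_transform(stack, dc_floor=0.0)
        assert f.g[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_delta_spectrum_on_unit_circle(self):
        spec = np.zeros(50)
        spec[10] = 7.0
        stack = _stack_from_pixels([spec])
        f = sc.phasor_transform(stack, dc_floor=0.0)
        ang = 2 * np.pi * 10 / 50
        assert f.g[0, 0] == pytest.approx(np.cos(ang), abs=1e-12)
        assert f.s[0, 0] == pytest.approx(np.sin(ang), abs=1e-12)
        assert f.g[0, 0] ** 2 + f.s[0, 0] ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_opposed_delta_mixture_cancels(self):
        spec = np.zeros(50)
        spec[0] = 1.0
        spec[25] = 1.0  # phasors (1,0) and (-1,0), equal DC
        stack = _stack_from_pixels([spec])
        f = sc.phasor_transform(stack, dc_floor=0.0)
        assert f.g[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_low_dc_pixels_flagged_invalid(self):
        stack = _stack_from_pixels([np.full(50, 1.0), np.full(50, 1e-9)])
        f = sc.phasor_transform(stack, dc_floor=1e-3)
        assert f.valid[0, 0] and not f.valid[0, 1]

    def test_domain_errors(self):
        stack = _stack_from_pixels([[1.0]])
        with pytest.raises(ValueError, match="channels"):
            sc.phasor_transform(stack)
        stack2 = _stack_from_pixels([np.ones(10)])
        with pytest.raises(ValueError, match="harmonic"):
            sc.phasor_transform(stack2, harmonic=0)

    @given(
        arrays(
            np.float64,
            st.integers(min_value=2, max_value=64),
            elements=st.floats(0.0, 1e6),
        ).filter(lambda a: a.sum() > 1e-9)
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_unit_disc_containment(self, spectrum):
        """Any non-negative spectrum lands inside the unit disc."""
        g, s = spectrum_phasor(spectrum)
        assert g * g + s * s <= 1.0 + 1e-9

    @given(st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_mixture_linearity(self, alpha, seed):
        """Phasor of a pixel mixture lies on the segment between components,
        at the DC-weighted position."""
        rng = np.random.default_rng(seed)
        a = rng.random(40) + 1e-3
        b = rng.random(40) + 1e-3
        mix = alpha * a + (1 - alpha) * b
        pa = np.array(spectrum_phasor(a))
        pb = np.array(spectrum_phasor(b))
        pm = np.array(spectrum_phasor(mix))
        wa, wb = alpha * a.sum(), (1 - alpha) * b.sum()
        expected = (wa * pa + wb * pb) / (wa + wb)
        np.testing.assert_allclose(pm, expected, atol=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        spec = rng.random(50)
        assert spectrum_phasor(spec) == pytest.approx(spectrum_phasor(100.0 * spec))


class TestClusterPhasor:
    def test_noise_free_phantom_compartments_recovered_exactly(self, ch_phantom_clean):
        """Three spectrally distinct compartments -> k=3 clustering reproduces
        the ground-truth masks pixel-for-pixel on valid pixels."""
        _, stack, truth = ch_phantom_clean
        f = sc.phasor_transform(stack)
        cl = sc.cluster_phasor(f, method="kmeans", k=3, seed=0)
        nuc = truth.nuclei_labels > 0
        drop = truth.droplet_labels > 0
        cyto = (truth.cell_labels > 0) & ~nuc & ~drop
        for mask in (nuc, drop, cyto):
            m = mask & f.valid
            ids = np.unique(cl.assignments[m])
            assert len(ids) == 1 and ids[0] != 0
            # no other compartment shares this cluster
            assert np.all((cl.assignments == ids[0])[f.valid] == m[f.valid])

    def test_reference_anchored_component_naming(self, ch_phantom_clean):
        spec, stack, _ = ch_phantom_clean
        f = sc.phasor_transform(stack)
        refs = {
            "nuclei": spectrum_phasor(
                make_component_spectrum(spec.components[0], spec.wavenumbers)
            ),
            "lipid": spectrum_phasor(
                make_component_spectrum(spec.components[1], spec.wavenumbers)
            ),
        }
        cl = sc.cluster_phasor(f, method="kmeans", k=3, references=refs, seed=0)
        names = list(cl.component_map.values())
        assert "nuclei" in names and "lipid" in names
        assert len(names) == len(set(names))  # unique naming

    def test_single_gate_covering_everything(self, ch_phantom_clean):
        _, stack, _ = ch_phantom_clean
        f = sc.phasor_transform(stack)
        gate = np.array([[-2, -2], [2, -2], [2, 2], [-2, 2]], dtype=float)
        cl = sc.cluster_phasor(f, method="polygon", gates=[gate])
        assert np.all(cl.assignments[f.valid] == 1)

    def test_empty_gate_assigns_nothing(self, ch_phantom_clean):
        _, stack, _ = ch_phantom_clean
        f = sc.phasor_transform(stack)
        gate = np.array([[10, 10], [11, 10], [11, 11], [10, 11]], dtype=float)
        cl = sc.cluster_phasor(f, method="polygon", gates=[gate])
        assert cl.assignments.max() == 0

    def test_too_many_clusters_raises(self):
        stack = _stack_from_pixels([np.ones(10), 2 * np.ones(10)])
        f = sc.phasor_transform(stack, dc_floor=0.0)
        with pytest.raises(InsufficientDataError):
            sc.cluster_phasor(f, method="kmeans", k=5)

    def test_component_images_partition_dc(self, ch_phantom_clean):
        _, stack, _ = ch_phantom_clean
        f = sc.phasor_transform(stack)
        cl = sc.cluster_phasor(f, method="kmeans", k=3, seed=0)
        imgs = sc.map_clusters_to_images(cl, f)
        total = sum(imgs.values())
        np.testing.assert_allclose(total[f.valid], f.dc[f.valid])
        supports = [img > 0 for img in imgs.values()]
        for i in range(len(supports)):
            for j in range(i + 1, len(supports)):
                assert not np.any(supports[i] & supports[j])

    def test_unknown_component_name_raises(self, ch_phantom_clean):
        _, stack, _ = ch_phantom_clean
        f = sc.phasor_transform(stack)
        cl = sc.cluster_phasor(f, method="kmeans", k=2, seed=0)
        with pytest.raises(KeyError):
            sc.map_clusters_to_images(cl, f, names=["no-such-component"])


class TestUnmixDualProbe:
    @pytest.fixture()
    def refs(self):
        wn = np.linspace(2050, 2350, 40)
        cc = np.exp(-((wn - 2100.0) ** 2) / (2 * 15.0**2))
        cd = np.exp(-((wn - 2150.0) ** 2) / (2 * 45.0**2))
        return wn, cc, cd

    def _stack(self, wn, pixels):
        return sc.HyperspectralStack(
            data=np.asarray(pixels, dtype=float).T[:, None, :], wavenumbers=wn
        )

    def test_pure_reference_pixel(self, refs):
        wn, cc, cd = refs
        res = sc.unmix_dual_probe(self._stack(wn, [cc]), {"CC": cc, "CD": cd})
        assert res.abundances["CC"][0, 0] == pytest.approx(1.0, abs=1e-9)
        assert res.abundances["CD"][0, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.residual[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_known_mixture_recovered(self, refs):
        wn, cc, cd = refs
        res = sc.unmix_dual_probe(
            self._stack(wn, [0.3 * cc + 0.7 * cd]), {"CC": cc, "CD": cd}
        )
        assert res.abundances["CC"][0, 0] == pytest.approx(0.3, abs=1e-9)
        assert res.abundances["CD"][0, 0] == pytest.approx(0.7, abs=1e-9)

    def test_orthogonal_spectrum_gets_zero_abundance(self, refs):
        wn, cc, cd = refs
        # Gram-Schmidt: a vector orthogonal to both references
        rng = np.random.default_rng(0)
        y = rng.random(len(wn))
        A = np.column_stack([cc, cd])
        y = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        res = sc.unmix_dual_probe(self._stack(wn, [y]), {"CC": cc, "CD": cd})
        assert res.abundances["CC"][0, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.abundances["CD"][0, 0] == pytest.approx(0.0, abs=1e-9)
        assert res.residual[0, 0] == pytest.approx(np.linalg.norm(y), rel=1e-9)

    def test_collinear_references_rejected(self, refs):
        wn, cc, _ = refs
        with pytest.raises(ConditioningError):
            sc.unmix_dual_probe(self._stack(wn, [cc]), {"CC": cc, "CD": 2.0 * cc})

    def test_negative_free_solution_clips_to_single_component(self, refs):
        wn, cc, cd = refs
        # pure CC minus a bit of CD structure drives unconstrained CD negative
        y = np.clip(1.0 * cc - 0.05 * cd, 0, None)
        res = sc.unmix_dual_probe(self._stack(wn, [y]), {"CC": cc, "CD": cd})
        assert res.abundances["CD"][0, 0] >= 0.0
        assert res.abundances["CC"][0, 0] > 0.5

    def test_phasor_and_least_squares_agree_on_pure_pixels(self, refs):
        """Dual-route check: phasor clustering and NNLS argmax give the same
        component call wherever a pixel is pure."""
        wn, cc, cd = refs
        rng = np.random.default_rng(1)
        n = 200
        pure_cc = np.outer(rng.uniform(0.5, 2.0, n // 2), cc)
        pure_cd = np.outer(rng.uniform(0.5, 2.0, n // 2), cd)
        pixels = np.vstack([pure_cc, pure_cd])
        stack = self._stack(wn, pixels)
        f = sc.phasor_transform(stack, dc_floor=0.0)
        refs_ph = {"CC": spectrum_phasor(cc), "CD": spectrum_phasor(cd)}
        cl = sc.cluster_phasor(f, method="kmeans", k=2, references=refs_ph, seed=0)
        phasor_call = np.vectorize(cl.component_map.get)(cl.assignments[0])
        um = sc.unmix_dual_probe(stack, {"CC": cc, "CD": cd})
        ls_call = np.where(
            um.abundances["CC"][0] >= um.abundances["CD"][0], "CC", "CD"
        )
        assert np.all(phasor_call == ls_call)
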