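"""Images and density maps: FT semantics, filters, density, correlation, MRC."""

import struct

import numpy as np
import pytest

from molkit import (
    DensityParams, ImageError, ImageHandle, apply_mask, create_view,
    entity_to_density, fft, gaussian_blur, high_pass, low_pass, read_mrc,
    real_space_correlation, score_fragments, write_mrc,
)
from molkit import fixtures as fx


@pytest.fixture
def rand_img(rng):
    return ImageHandle(rng.normal(size=(8, 8, 8)), sampling=1.0)


class TestFFT:
    def test_domain_toggles_and_symmetry_flag(self, rand_img):
        f = fft(rand_img)
        assert f.domain == "frequency"
        assert f.conjugate_symmetric
        back = fft(f)
        assert back.domain == "spatial"
        assert back.is_real

    def test_conjugate_symmetry_holds(self, rand_img):
        f = fft(rand_img).data
        n = f.shape[0]
        for idx in [(1, 2, 3), (4, 0, 5), (7, 7, 1)]:
            neg = tuple((-i) % n for i in idx)
            assert np.isclose(f[idx], np.conj(f[neg]), rtol=1e-6)

    def test_complex_frequency_input_gives_complex_spatial(self, rng):
        spec = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        img = ImageHandle(spec, domain="frequency", conjugate_symmetric=False)
        out = fft(img)
        assert out.domain == "spatial"
        assert not out.is_real

    def test_delta_has_flat_unit_spectrum(self):
        data = np.zeros((8, 8, 8))
        data[0, 0, 0] = 1.0
        f = fft(ImageHandle(data))
        assert np.allclose(np.abs(f.data), 1.0)

    def test_round_trip_identity(self, rand_img):
        back = fft(fft(rand_img))
        assert np.allclose(back.data, rand_img.data, atol=1e-9)

    def test_matches_naive_dft(self, rng):
        # direct O(N^2) DFT on an 8^3 crop of a 16^3 image
        data = rng.normal(size=(16, 16, 16))[:8, :8, :8].copy()
        got = fft(ImageHandle(data)).data
        n = 8
        idx = np.arange(n)
        expected = np.zeros((n, n, n), dtype=complex)
        for kx in range(n):
            for ky in range(n):
                for kz in range(n):
                    phase = np.exp(-2j * np.pi * (
                        kx * idx[:, None, None] + ky * idx[None, :, None]
                        + kz * idx[None, None, :]) / n)
                    expected[kx, ky, kz] = np.sum(data * phase)
        assert np.allclose(got, expected, atol=1e-8)

    def test_parseval(self, rng):
        data = rng.normal(size=(12, 10))
        spec = fft(ImageHandle(data)).data
        lhs = np.sum(np.abs(data) ** 2)
        rhs = np.sum(np.abs(spec) ** 2) / data.size
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestFilters:
    def test_blur_preserves_constant_image(self):
        img = ImageHandle(np.full((8, 8), 3.5))
        out = gaussian_blur(img, 2.0)
        assert np.allclose(out.data, 3.5, atol=1e-12)

    def test_blur_preserves_mean(self, rand_img):
        out = gaussian_blur(rand_img, 1.5)
        assert out.data.mean() == pytest.approx(rand_img.data.mean(),
                                                abs=1e-12)

    def test_blur_of_delta_matches_closed_form(self):
        n, d, sigma = 256, 0.5, 2.0
        data = np.zeros(n)
        data[0] = 1.0
        out = gaussian_blur(ImageHandle(data, sampling=d), sigma).data
        x = np.fft.fftfreq(n, d=1.0 / (n * d))   # signed distances from 0
        expected = d / (np.sqrt(2 * np.pi) * sigma) * np.exp(
            -x ** 2 / (2 * sigma ** 2))
        assert np.allclose(out, expected, atol=1e-6)

    def test_low_then_high_pass_is_zero(self, rand_img):
        cut = 2.5
        out = high_pass(low_pass(rand_img, cut), cut)
        # only the shell |k| == 1/cutoff may survive
        k = np.sqrt(sum(g ** 2 for g in np.meshgrid(
            *[np.fft.fftfreq(n, d=1.0) for n in rand_img.size],
            indexing="ij")))
        shell = np.isclose(k, 1.0 / cut)
        spec = np.fft.fftn(out.data)
        spec[shell] = 0.0
        assert np.allclose(np.fft.ifftn(spec).real, 0.0, atol=1e-10)

    def test_low_pass_keeps_dc(self, rand_img):
        out = low_pass(rand_img, 2.0)
        assert out.data.mean() == pytest.approx(rand_img.data.mean(),
                                                abs=1e-12)

    def test_nonpositive_cutoff_rejected(self, rand_img):
        with pytest.raises(ImageError):
            low_pass(rand_img, 0.0)

    def test_mask_is_voxelwise_product(self, rand_img, rng):
        mask = (rng.random(rand_img.size) > 0.5).astype(float)
        out = apply_mask(rand_img, mask)
        assert np.array_equal(out.data, rand_img.data * mask)

    def test_mask_shape_mismatch(self, rand_img):
        with pytest.raises(ImageError, match="shape"):
            apply_mask(rand_img, np.ones((4, 4, 4)))


def single_atom_entity(pos=(0.0, 0.0, 0.0)):
    from molkit.mol import build_entity
    return build_entity([{"name": "A", "residues": [
        {"name": "UNK", "number": 1,
         "atoms": [{"name": "C1", "element": "C", "pos": pos}]}]}])


class TestEntityToDensity:
    def test_single_atom_closed_form(self):
        ent = single_atom_entity((2.0, 2.0, 2.0))
        params = DensityParams(sigma=1.0, sampling=0.5, padding=2.0)
        img = entity_to_density(create_view(ent, ent.atoms), params)
        centers = img.voxel_centers()
        ix = [int(np.argmin(np.abs(c - 2.0))) for c in centers]
        assert img.data[tuple(ix)] == pytest.approx(1.0, abs=1e-12)
        off = (ix[0] + 2, ix[1], ix[2])    # 1 A off-centre at 0.5 A sampling
        assert img.data[off] == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_two_distant_atoms_superpose_linearly(self):
        from molkit.mol import build_entity
        ent = build_entity([{"name": "A", "residues": [
            {"name": "UNK", "number": 1, "atoms": [
                {"name": "C1", "element": "C", "pos": (0.0, 0.0, 0.0)},
                {"name": "C2", "element": "C", "pos": (12.0, 0.0, 0.0)}]}]}])
        # padding >= 4 sigma so each single-atom grid holds its full support
        params = DensityParams(sigma=1.0, sampling=1.0, padding=4.0)
        both = entity_to_density(create_view(ent, ent.atoms), params)
        total = np.zeros(both.size)
        for atom in ent.atoms:
            single = single_atom_entity(tuple(atom.pos))
            m = entity_to_density(create_view(single, single.atoms), params)
            # place the single-atom map into the big grid by voxel offset
            shift = np.rint((m.origin - both.origin) / 1.0).astype(int)
            sl = tuple(slice(s, s + n) for s, n in zip(shift, m.size))
            total[sl] += m.data
        assert np.allclose(both.data, total, atol=1e-12)

    def test_matches_exhaustive_double_loop(self):
        ent = fx.make_point_cloud(10, seed=3, box=6.0)
        params = DensityParams(sigma=1.2, sampling=1.0, padding=3.0)
        img = entity_to_density(create_view(ent, ent.atoms), params)
        pos = ent.positions
        centers = img.voxel_centers()
        expected = np.zeros(img.size)
        for i, x in enumerate(centers[0]):
            for j, y in enumerate(centers[1]):
                for k, z in enumerate(centers[2]):
                    d2 = np.sum((pos - [x, y, z]) ** 2, axis=1)
                    expected[i, j, k] = np.sum(np.exp(-d2 / (2 * 1.2 ** 2)))
        # the 4-sigma truncation is the only allowed deviation: each atom
        # contributes at most exp(-8) outside its cutoff
        bound = len(pos) * np.exp(-8.0)
        assert np.allclose(img.data, expected, rtol=1e-4, atol=bound)
        # voxels with every atom inside the cutoff are exact
        cut2 = (4 * 1.2) ** 2
        for i, x in enumerate(centers[0]):
            for j, y in enumerate(centers[1]):
                for k, z in enumerate(centers[2]):
                    d2 = np.sum((pos - [x, y, z]) ** 2, axis=1)
                    if (d2 <= cut2).all():
                        assert img.data[i, j, k] == pytest.approx(
                            expected[i, j, k], abs=1e-12)

    def test_translation_equivariance(self):
        ent = fx.make_point_cloud(5, seed=9, box=5.0)
        params = DensityParams(sigma=1.5, sampling=1.0, padding=2.0)
        a = entity_to_density(create_view(ent, ent.atoms), params)
        delta = np.array([4.0, -2.0, 1.0])
        for atom in ent.atoms:
            atom.pos = atom.pos + delta
        b = entity_to_density(create_view(ent, ent.atoms), params)
        assert np.allclose(a.data, b.data, atol=1e-12)
        assert np.allclose(b.origin - a.origin, delta)

    def test_empty_view_rejected(self, helix10):
        with pytest.raises(ImageError, match="empty"):
            entity_to_density(create_view(helix10, []))


class TestCorrelation:
    def test_self_correlation_is_one(self, helix10):
        img = entity_to_density(create_view(helix10, helix10.atoms))
        assert real_space_correlation(img, img) == pytest.approx(1.0)

    def test_negation_is_minus_one(self, helix10):
        img = entity_to_density(create_view(helix10, helix10.atoms))
        neg = ImageHandle(-img.data, img.sampling, img.origin)
        assert real_space_correlation(img, neg) == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self, helix10, rng):
        img = entity_to_density(create_view(helix10, helix10.atoms))
        noisy = ImageHandle(img.data + rng.normal(scale=0.1, size=img.size),
                            img.sampling, img.origin)
        base = real_space_correlation(img, noisy)
        scaled = ImageHandle(2.5 * noisy.data + 7.0, img.sampling, img.origin)
        assert real_space_correlation(img, scaled) == pytest.approx(
            base, abs=1e-12)

    def test_matches_direct_formula(self, helix10, rng):
        img = entity_to_density(create_view(helix10, helix10.atoms))
        other = gaussian_blur(img, 1.0)
        other.data = other.data + rng.normal(scale=0.05, size=img.size)
        got = real_space_correlation(img, other)
        a, b = img.data.ravel(), other.data.ravel()
        ac, bc = a - a.mean(), b - b.mean()
        expected = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        flat = ImageHandle(np.ones((4, 4, 4)))
        with pytest.raises(ImageError, match="variance"):
            real_space_correlation(flat, flat)

    def test_incongruent_grids_resampled(self, helix10):
        params_a = DensityParams(sampling=1.0)
        params_b = DensityParams(sampling=0.5)
        va = create_view(helix10, helix10.atoms)
        a = entity_to_density(va, params_a)
        b = entity_to_density(va, params_b)
        corr = real_space_correlation(a, b)
        assert corr > 0.99


class TestScoreFragments:
    def make_fragments(self):
        true = fx.make_polyala_helix(6)
        decoys = []
        for k, shift in enumerate([(3.5, 0, 0), (0, 4, 0), (0, 0, 5),
                                   (-4, 2, 0)]):
            d = fx.make_polyala_helix(6)
            for atom in d.atoms:
                atom.pos = atom.pos + np.array(shift, dtype=float)
            decoys.append(create_view(d, d.atoms))
        return create_view(true, true.atoms), decoys

    def test_true_fragment_on_clean_map_scores_one(self):
        true, decoys = self.make_fragments()
        params = DensityParams()
        exp_map = entity_to_density(true, params)
        scored = score_fragments([true] + decoys, exp_map, params)
        assert scored[0][0] is true
        assert scored[0][1] == pytest.approx(1.0, abs=1e-9)

    def test_displaced_decoys_rank_below_truth_with_noise(self, rng):
        true, decoys = self.make_fragments()
        params = DensityParams()
        exp_map = entity_to_density(true, params)
        signal = exp_map.data.std()
        exp_map.data = exp_map.data + rng.normal(
            scale=signal / 2.0, size=exp_map.size)      # SNR = 2
        scored = score_fragments([true] + decoys, exp_map, params)
        assert scored[0][0] is true
        for frag, corr in scored[1:]:
            assert corr < scored[0][1]

    def test_composition_equals_manual_calls(self):
        true, decoys = self.make_fragments()
        params = DensityParams()
        exp_map = entity_to_density(true, params)
        scored = dict((id(f), c) for f, c in
                      score_fragments([true, decoys[0]], exp_map, params))
        from molkit.img import entity_to_density as e2d
        for frag in (true, decoys[0]):
            frag_map, footprint = e2d(frag, params, _with_footprint=True)
            manual = real_space_correlation(frag_map, exp_map,
                                            region=footprint)
            assert scored[id(frag)] == pytest.approx(manual, abs=1e-12)


class TestMRC:
    def test_round_trip_exact(self, tmp_path, rng):
        img = ImageHandle(rng.normal(size=(8, 8, 8)).astype(np.float32)
                          .astype(float), sampling=1.0,
                          origin=(1.0, -2.0, 3.0))
        p = tmp_path / "m.mrc"
        write_mrc(img, p)
        back = read_mrc(p)
        assert back.size == img.size
        assert np.array_equal(back.data.astype(np.float32),
                              img.data.astype(np.float32))
        assert back.sampling == img.sampling
        assert np.allclose(back.origin, img.origin, atol=1e-6)

    def test_non_unit_sampling_preserved(self, tmp_path):
        img = ImageHandle(np.zeros((4, 6, 8)), sampling=1.5)
        p = tmp_path / "s.mrc"
        write_mrc(img, p)
        assert read_mrc(p).sampling == (1.5, 1.5, 1.5)

    def test_gemmi_reads_our_maps(self, tmp_path, rng):
        gemmi = pytest.importorskip("gemmi")
        img = ImageHandle(rng.normal(size=(6, 5, 4)), sampling=2.0)
        p = tmp_path / "g.mrc"
        write_mrc(img, p)
        g = gemmi.read_ccp4_map(str(p))
        arr = np.array(g.grid, copy=False)
        assert np.allclose(arr, img.data.astype(np.float32))

    def test_axis_permuted_header(self, tmp_path, rng):
        # write a file with MAPC/MAPR/MAPS = (2,1,3): columns run along y
        data = rng.normal(size=(5, 6, 7)).astype("<f4")    # canonical x,y,z
        p = tmp_path / "perm.mrc"
        hdr = bytearray(1024)
        # file stores [s=z, r=x, c=y]
        struct.pack_into("<3i", hdr, 0, 6, 5, 7)           # NC NR NS
        struct.pack_into("<i", hdr, 12, 2)
        struct.pack_into("<3i", hdr, 28, 5, 6, 7)          # MX MY MZ (x,y,z)
        struct.pack_into("<3f", hdr, 40, 5.0, 6.0, 7.0)
        struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)
        struct.pack_into("<3i", hdr, 64, 2, 1, 3)          # MAPC MAPR MAPS
        hdr[208:212] = b"MAP "
        hdr[212:216] = bytes([0x44, 0x44, 0, 0])
        with open(p, "wb") as fh:
            fh.write(hdr)
            fh.write(np.ascontiguousarray(
                data.transpose(2, 0, 1)).tobytes())        # [z, x, y]
        back = read_mrc(p)
        assert back.size == (5, 6, 7)
        assert np.array_equal(back.data.astype(np.float32), data)

    def test_unsupported_mode_rejected(self, tmp_path):
        hdr = bytearray(1024)
        struct.pack_into("<3i", hdr, 0, 2, 2, 2)
        struct.pack_into("<i", hdr, 12, 1)                 # int16 mode
        struct.pack_into("<3i", hdr, 28, 2, 2, 2)
        struct.pack_into("<3f", hdr, 40, 2.0, 2.0, 2.0)
        struct.pack_into("<3i", hdr, 64, 1, 2, 3)
        hdr[208:212] = b"MAP "
        hdr[212:216] = bytes([0x44, 0x44, 0, 0])
        p = tmp_path / "mode1.mrc"
        p.write_bytes(bytes(hdr) + b"\x00" * 16)
        with pytest.raises(ImageError, match="mode"):
            read_mrc(p)

    def test_missing_stamp_rejected(self, tmp_path):
        p = tmp_path / "junk.mrc"
        p.write_bytes(b"\x00" * 2048)
        with pytest.raises(ImageError, match="MAP stamp"):
            read_mrc(p)
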