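"""Domain-aware images and density maps: FT, filters, structure→density,
real-space correlation, MRC/CCP4 I/O.

An :class:`ImageHandle` wraps a 1-, 2- or 3-D scalar buffer together with
its sampling (Å per pixel, per dimension), its origin (Å position of pixel
(0, …, 0); pixel centres sit at ``origin + index * sampling``) and the
currently active domain.  Applying :func:`fft` toggles the domain: a real
spatial image yields a frequency image flagged conjugate-symmetric
(F(−k) = conj(F(k))); transforming a conjugate-symmetric frequency image
back gives a real spatial image, while a frequency image without that
symmetry transforms to a complex spatial image.

The FT normalisation is the unitary pair convention: forward unscaled,
inverse carries 1/N, so ``Σ|x|² = Σ|X|²/N`` (Parseval).

Molecular structures are converted to density by placing a Gaussian sphere
of width σ (default 1.5 Å) at every atom position, evaluated within 4σ;
maps are compared by Pearson cross-correlation over a voxel region.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageHandle",
    "DensityParams",
    "ImageError",
    "fft",
    "gaussian_blur",
    "low_pass",
    "high_pass",
    "apply_mask",
    "entity_to_density",
    "real_space_correlation",
    "score_fragments",
    "read_mrc",
    "write_mrc",
]


class ImageError(Exception):
    pass


# approximate atomic numbers for element-weighted amplitudes
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "FE": 26}


class ImageHandle:
    """1/2/3-D pixel buffer with sampling metadata and an active domain."""

    def __init__(self, data: np.ndarray, sampling=1.0, origin=None,
                 domain: str = "spatial", conjugate_symmetric: bool = False):
        data = np.asarray(data)
        if data.ndim not in (1, 2, 3):
            raise ImageError("images must be 1-, 2- or 3-dimensional")
        if domain not in ("spatial", "frequency"):
            raise ImageError(f"unknown domain {domain!r}")
        self.data = data
        if np.isscalar(sampling):
            sampling = (float(sampling),) * data.ndim
        self.sampling = tuple(float(s) for s in sampling)
        if len(self.sampling) != data.ndim:
            raise ImageError("sampling must give one spacing per dimension")
        if any(s <= 0 for s in self.sampling):
            raise ImageError("sampling must be positive")
        self.origin = (np.zeros(data.ndim) if origin is None
                       else np.asarray(origin, dtype=float))
        if self.origin.shape != (data.ndim,):
            raise ImageError("origin must have one coordinate per dimension")
        self.domain = domain
        self.conjugate_symmetric = conjugate_symmetric

    # -- basics -----------------------------------------------------------

    @property
    def size(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def is_real(self) -> bool:
        return not np.iscomplexobj(self.data)

    def copy(self) -> "ImageHandle":
        return ImageHandle(self.data.copy(), self.sampling, self.origin.copy(),
                           self.domain, self.conjugate_symmetric)

    def congruent_with(self, other: "ImageHandle", tol: float = 1e-6) -> bool:
        return (self.size == other.size
                and np.allclose(self.sampling, other.sampling, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def voxel_centers(self) -> list[np.ndarray]:
        """Per-axis physical coordinates of pixel centres (Å)."""
        return [self.origin[d] + np.arange(self.size[d]) * self.sampling[d]
                for d in range(self.ndim)]

    def __repr__(self):
        return (f"<ImageHandle {self.size} {self.domain}"
                f"{' conj-sym' if self.conjugate_symmetric else ''}>")


def fft(img: ImageHandle) -> ImageHandle:
    """Fourier transform toggling the active domain.

    spatial→frequency: forward unscaled FT; the result is flagged
    conjugate-symmetric iff the input was real.  frequency→spatial: inverse
    FT with 1/N; a conjugate-symmetric input produces a real image, any
    other input a complex one.
    """
    if img.domain == "spatial":
        out = np.fft.fftn(img.data)
        return ImageHandle(out, img.sampling, img.origin, "frequency",
                           conjugate_symmetric=img.is_real)
    out = np.fft.ifftn(img.data)
    if img.conjugate_symmetric:
        out = out.real
    return ImageHandle(out, img.sampling, img.origin, "spatial", False)


def _freq_sq(shape, sampling) -> np.ndarray:
    """|k|² on the FFT grid, cycles²/Å²."""
    axes = [np.fft.fftfreq(n, d=s) for n, s in zip(shape, sampling)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return sum(g ** 2 for g in grids)


def _require_spatial(img: ImageHandle, op: str):
    if img.domain != "spatial":
        raise ImageError(f"{op} expects a spatial-domain image")


def gaussian_blur(img: ImageHandle, sigma: float) -> ImageHandle:
    """Convolve with a unit-integral Gaussian of width ``sigma`` Å
    (multiplication by exp(−2π²σ²|k|²) in frequency space; DC untouched,
    so the mean intensity is preserved)."""
    _require_spatial(img, "gaussian_blur")
    if sigma <= 0:
        raise ImageError("sigma must be positive")
    k2 = _freq_sq(img.size, img.sampling)
    spec = np.fft.fftn(img.data) * np.exp(-2.0 * np.pi ** 2 * sigma ** 2 * k2)
    out = np.fft.ifftn(spec)
    if img.is_real:
        out = out.real
    return ImageHandle(out, img.sampling, img.origin, "spatial")


def _pass_filter(img: ImageHandle, cutoff: float, keep_low: bool) -> ImageHandle:
    _require_spatial(img, "low_pass/high_pass")
    if cutoff <= 0:
        raise ImageError("cutoff must be positive")
    k = np.sqrt(_freq_sq(img.size, img.sampling))
    keep = k <= 1.0 / cutoff if keep_low else k >= 1.0 / cutoff
    spec = np.fft.fftn(img.data) * keep
    out = np.fft.ifftn(spec)
    if img.is_real:
        out = out.real
    return ImageHandle(out, img.sampling, img.origin, "spatial")


def low_pass(img: ImageHandle, cutoff: float) -> ImageHandle:
    """Zero all spatial frequencies beyond 1/cutoff (cutoff in Å)."""
    return _pass_filter(img, cutoff, keep_low=True)


def high_pass(img: ImageHandle, cutoff: float) -> ImageHandle:
    """Zero all spatial frequencies below 1/cutoff (cutoff in Å)."""
    return _pass_filter(img, cutoff, keep_low=False)


def apply_mask(img: ImageHandle, mask) -> ImageHandle:
    """Voxelwise product with a mask (ImageHandle or array of equal shape)."""
    mdata = mask.data if isinstance(mask, ImageHandle) else np.asarray(mask)
    if mdata.shape != img.data.shape:
        raise ImageError("mask shape does not match image shape")
    return ImageHandle(img.data * mdata, img.sampling, img.origin, img.domain,
                       img.conjugate_symmetric)


# ---------------------------------------------------------------------------
# Structure → density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityParams:
    """Parameters of the Gaussian-sphere density generator."""
    sigma: float = 1.5            # Å, Gaussian width per atom
    amplitude_mode: str = "uniform"   # uniform | element_weighted
    sampling: float = 1.0         # Å per voxel
    padding: float = 3.0          # Å added around the bounding box

    def __post_init__(self):
        if self.sigma <= 0:
            raise ImageError("sigma must be positive")
        if self.sampling <= 0:
            raise ImageError("sampling must be positive")
        if self.amplitude_mode not in ("uniform", "element_weighted"):
            raise ImageError(f"unknown amplitude mode {self.amplitude_mode!r}")


def _atom_amplitude(atom, mode: str) -> float:
    if mode == "uniform":
        return 1.0
    return float(_Z.get(atom.element.upper(), 6))


def entity_to_density(view, params: DensityParams = DensityParams(),
                      _with_footprint: bool = False):
    """Gaussian-sphere density of a structure on a regular 3-D grid.

    value(v) = Σ_atoms A · exp(−|v − pos|² / 2σ²), each atom evaluated
    within 4σ.  The grid covers the bounding box plus ``padding``; the
    origin is recorded so the voxel↔Å mapping is exact.
    """
    atoms = list(view.atoms)
    if not atoms:
        raise ImageError("cannot compute density of an empty view")
    pos = np.array([a.pos for a in atoms], dtype=float)
    s, sigma = params.sampling, params.sigma
    lo = pos.min(axis=0) - params.padding
    hi = pos.max(axis=0) + params.padding
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / s)) + 1 for d in range(3))
    data = np.zeros(shape)
    footprint = np.zeros(shape, dtype=bool) if _with_footprint else None
    cut = 4.0 * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for atom, p in zip(atoms, pos):
        amp = _atom_amplitude(atom, params.amplitude_mode)
        imin = [max(0, int(np.floor((p[d] - cut - lo[d]) / s))) for d in range(3)]
        imax = [min(shape[d] - 1, int(np.ceil((p[d] + cut - lo[d]) / s)))
                for d in range(3)]
        if any(imin[d] > imax[d] for d in range(3)):
            continue
        ax = [lo[d] + np.arange(imin[d], imax[d] + 1) * s - p[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        inside = d2 <= cut * cut
        block = (slice(imin[0], imax[0] + 1), slice(imin[1], imax[1] + 1),
                 slice(imin[2], imax[2] + 1))
        data[block] += np.where(inside, amp * np.exp(-d2 * inv2s2), 0.0)
        if footprint is not None:
            footprint[block] |= inside
    img = ImageHandle(data, s, lo, "spatial")
    return (img, footprint) if _with_footprint else img


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _resample_onto(target: ImageHandle, source: ImageHandle) -> np.ndarray:
    """Trilinear interpolation of ``source`` onto ``target``'s grid;
    NaN outside the source footprint."""
    idx = [(target.origin[d] + np.arange(target.size[d]) * target.sampling[d]
            - source.origin[d]) / source.sampling[d]
           for d in range(target.ndim)]
    grids = np.meshgrid(*idx, indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    vals = ndimage.map_coordinates(source.data.astype(float), coords,
                                   order=1, mode="constant", cval=np.nan)
    return vals.reshape(target.size)


def real_space_correlation(map_a: ImageHandle, map_b: ImageHandle,
                           region: Optional[np.ndarray] = None) -> float:
    """Pearson correlation of two maps over a voxel region.

    On congruent grids the correlation runs voxel-by-voxel (over ``region``
    if given, else the whole grid); otherwise ``map_b`` is resampled onto
    ``map_a``'s grid by trilinear interpolation and the correlation runs
    over the overlap.  Zero-variance input or an empty overlap is an error.
    """
    a = map_a.data.astype(float)
    if map_a.congruent_with(map_b):
        b = map_b.data.astype(float)
    else:
        b = _resample_onto(map_a, map_b)
    valid = ~np.isnan(b)
    if region is not None:
        if region.shape != a.shape:
            raise ImageError("region mask shape does not match map shape")
        valid &= region.astype(bool)
    if not valid.any():
        raise ImageError("empty overlap between maps")
    av, bv = a[valid], b[valid]
    ac, bc = av - av.mean(), bv - bv.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0:
        raise ImageError("zero-variance input in correlation")
    return float((ac @ bc) / denom)


def score_fragments(fragments: Sequence, exp_map: ImageHandle,
                    params: DensityParams = DensityParams()) -> list:
    """Correlate candidate fragments against an experimental map.

    Each fragment is converted to density with ``params`` and correlated
    against ``exp_map`` over the fragment's footprint (voxels within 4σ of
    any fragment atom).  Returns ``[(fragment, correlation), ...]`` sorted
    by descending correlation.
    """
    if not fragments:
        raise ImageError("no fragments to score")
    scored = []
    for frag in fragments:
        frag_map, footprint = entity_to_density(frag, params,
                                                _with_footprint=True)
        corr = real_space_correlation(frag_map, exp_map, region=footprint)
        scored.append((frag, corr))
    scored.sort(key=lambda t: t[1], reverse=True)
    return scored


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (mode 2, float32)
# ---------------------------------------------------------------------------

_MRC_HEADER = 1024


def write_mrc(img: ImageHandle, path) -> None:
    """Write a 3-D spatial image as an MRC/CCP4 mode-2 map.

    Data are stored x-fastest (MAPC,MAPR,MAPS = 1,2,3); the origin goes to
    the ORIGIN header words.  Round trip preserves size, sampling, origin
    and voxel values exactly.
    """
    if img.ndim != 3:
        raise ImageError("MRC export requires a 3-D image")
    if not img.is_real:
        raise ImageError("MRC export requires real-valued data")
    data = img.data.astype("<f4")
    nx, ny, nz = img.size
    cell = [img.size[d] * img.sampling[d] for d in range(3)]
    dmin, dmax = float(data.min()), float(data.max())
    dmean, rms = float(data.mean()), float(data.std())
    hdr = bytearray(_MRC_HEADER)
    struct.pack_into("<3i", hdr, 0, nx, ny, nz)
    struct.pack_into("<i", hdr, 12, 2)                      # MODE 2
    struct.pack_into("<3i", hdr, 16, 0, 0, 0)               # N*START
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)            # MX MY MZ
    struct.pack_into("<3f", hdr, 40, *cell)                 # CELLA
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)      # CELLB
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)               # MAPC MAPR MAPS
    struct.pack_into("<3f", hdr, 76, dmin, dmax, dmean)
    struct.pack_into("<i", hdr, 88, 1)                      # ISPG
    struct.pack_into("<3f", hdr, 196, *img.origin)          # ORIGIN
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0, 0])                # MACHST LE
    struct.pack_into("<f", hdr, 216, rms)
    with open(path, "wb") as fh:
        fh.write(hdr)
        # file order: sections (z) slowest, columns (x) fastest
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def read_mrc(path) -> ImageHandle:
    """Read a mode-2 MRC/CCP4 map into a canonical x,y,z-ordered image.

    Axis-permuted files (MAPC/MAPR/MAPS) are reordered to x,y,z.  The
    origin comes from the ORIGIN words when set, else from N*START times
    the sampling.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER:
        raise ImageError("truncated MRC header")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ImageError("missing MAP stamp: not an MRC/CCP4 file")
    machst = raw[212:216]
    endian = ">" if machst[:2] == bytes([0x11, 0x11]) else "<"

    def ints(off, n):
        return struct.unpack_from(endian + f"{n}i", raw, off)

    def floats(off, n):
        return struct.unpack_from(endian + f"{n}f", raw, off)

    ncrs = ints(0, 3)
    (mode,) = ints(12, 1)
    if mode != 2:
        raise ImageError(f"unsupported MRC mode {mode} (only mode 2)")
    nstart = ints(16, 3)
    mxyz = ints(28, 3)
    cella = floats(40, 3)
    mapc, mapr, maps = ints(64, 3)
    (nsymbt,) = ints(92, 1)
    origin_words = floats(196, 3)
    perm = (mapc - 1, mapr - 1, maps - 1)
    if sorted(perm) != [0, 1, 2]:
        raise ImageError(f"invalid axis order MAPC/MAPR/MAPS = "
                         f"{(mapc, mapr, maps)}")
    n_expected = ncrs[0] * ncrs[1] * ncrs[2]
    data_off = _MRC_HEADER + nsymbt
    buf = np.frombuffer(raw, dtype=endian + "f4", count=n_expected,
                        offset=data_off)
    if buf.size < n_expected:
        raise ImageError("data block shorter than header promises")
    # file layout [s, r, c] -> [c, r, s] -> canonical x,y,z
    data_crs = buf.reshape(ncrs[2], ncrs[1], ncrs[0]).transpose(2, 1, 0)
    inv = np.argsort(perm)
    data = np.ascontiguousarray(data_crs.transpose(inv)).astype(np.float64)
    size = data.shape
    sampling = []
    for d in range(3):
        if mxyz[d] <= 0 or cella[d] <= 0:
            raise ImageError("header/grid inconsistency: bad cell or sampling")
        sampling.append(cella[d] / mxyz[d])
    if any(origin_words):
        origin = np.array(origin_words, dtype=float)
    else:
        start_xyz = [0, 0, 0]
        for k in range(3):
            start_xyz[perm[k]] = nstart[k]
        origin = np.array([start_xyz[d] * sampling[d] for d in range(3)])
    return ImageHandle(data, tuple(sampling), origin, "spatial")
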