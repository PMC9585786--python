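"""Density-adapted 3D radial (DA-3DPR) sampling, PSF simulation, and gridding.

The sodium acquisition is a center-out 3D radial readout whose gradient is
shaped so that beyond a transition radius ``k0`` the sampled k-space density
falls off as k^-2, i.e. every spherical shell receives the same number of
samples per unit volume. Spokes start with a constant-gradient (linear in
time) segment up to ``k0`` and then follow the cube-root law

    k(t) = (k0^3 + 3 k0^2 g (t - t0))^(1/3),   g = k0 / t0,

which keeps k^3 affine in time and the gradient continuous at the transition.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
from numpy.fft import fftshift, ifftshift, fftn, ifftn

logger = logging.getLogger("natriq")

#: 23Na gyromagnetic ratio, MHz/T
GAMMA_NA_MHZ_PER_T = 11.262

#: Kaiser-Bessel gridding kernel width (grid cells on the oversampled grid)
KERNEL_WIDTH = 4
#: Image-domain oversampling factor for gridding
OVERSAMPLE = 2

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0


@dataclasses.dataclass
class RadialTrajectory:
    """A DA-3DPR k-space sample set.

    ``k_radii``, ``density_weights`` and ``sample_times`` are per-sample along
    one spoke (all spokes share the radial profile); ``directions`` holds one
    unit vector per spoke.
    """

    n_spokes: int
    n_samples_per_spoke: int
    directions: np.ndarray      # (n_spokes, 3) unit vectors
    k_radii: np.ndarray         # (n_samples,) 1/mm, non-decreasing
    density_weights: np.ndarray  # (n_samples,) > 0
    sample_times: np.ndarray    # (n_samples,) ms from readout start
    k0: float                   # transition radius, 1/mm
    kmax: float                 # 1/(2 * resolution), 1/mm
    gamma: float = GAMMA_NA_MHZ_PER_T

    @property
    def n_samples(self) -> int:
        return self.n_spokes * self.n_samples_per_spoke

    def kvectors(self) -> np.ndarray:
        """All sample positions as an (n_spokes * n_samples, 3) array in 1/mm."""
        return (self.directions[:, None, :] * self.k_radii[None, :, None]).reshape(-1, 3)

    def flat_weights(self) -> np.ndarray:
        return np.broadcast_to(
            self.density_weights, (self.n_spokes, self.n_samples_per_spoke)
        ).reshape(-1)

    def flat_times(self) -> np.ndarray:
        return np.broadcast_to(
            self.sample_times, (self.n_spokes, self.n_samples_per_spoke)
        ).reshape(-1)

    def subsample(self, step: int) -> "RadialTrajectory":
        """Keep every ``step``-th spoke (weights are unchanged; PSFs are
        re-normalized downstream, see :func:`simulate_psf`)."""
        return dataclasses.replace(
            self,
            n_spokes=int(np.ceil(self.n_spokes / step)),
            directions=self.directions[::step],
        )

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            directions=self.directions,
            k_radii=self.k_radii,
            density_weights=self.density_weights,
            sample_times=self.sample_times,
            scalars=np.array([self.n_spokes, self.n_samples_per_spoke,
                              self.k0, self.kmax, self.gamma]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RadialTrajectory":
        with np.load(path) as f:
            s = f["scalars"]
            return cls(
                n_spokes=int(s[0]), n_samples_per_spoke=int(s[1]),
                directions=f["directions"], k_radii=f["k_radii"],
                density_weights=f["density_weights"], sample_times=f["sample_times"],
                k0=float(s[2]), kmax=float(s[3]), gamma=float(s[4]),
            )


@dataclasses.dataclass
class PointSpreadFunction:
    """Image-domain PSF of a trajectory, normalized to unit sum."""

    grid: np.ndarray        # complex 3D volume, sum == 1
    voxel_size: float       # mm
    peak_index: tuple[int, int, int]
    fwhm: float             # mm


def _sphere_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors from the golden-means spherical spiral."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / GOLDEN_RATIO**2
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_da3dpr_trajectory(
    n_spokes: int,
    matrix: int,
    resolution: float,
    t0_fraction: float = 0.25,
    n_samples_per_spoke: int | None = None,
    readout_duration: float = 10.0,
) -> RadialTrajectory:
    """Construct the density-adapted radial trajectory.

    Parameters
    ----------
    n_spokes
        Number of radial projections (10,000 for the sodium protocol).
    matrix
        Nominal image matrix size (isotropic).
    resolution
        Nominal voxel size in mm; kmax = 1/(2*resolution).
    t0_fraction
        k0/kmax: fraction of k-space covered by the initial constant-gradient
        segment before density adaptation begins. 1.0 disables adaptation.
    n_samples_per_spoke
        Radial samples per spoke; defaults to ``matrix`` (2x radial Nyquist).
    readout_duration
        Readout window in ms, used to attach a time stamp to every sample
        (off-resonance and T2* phase evolve over these times).
    """
    if n_spokes < 1:
        raise ValueError(f"n_spokes must be >= 1, got {n_spokes}")
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution} mm")
    if not 0.0 < t0_fraction <= 1.0:
        raise ValueError(f"t0_fraction must lie in (0, 1], got {t0_fraction}")
    if n_samples_per_spoke is None:
        # radial Nyquist at the maximum gradient: the largest radial step is
        # (k0/t0)/n, which must stay below the grid spacing 2*kmax/matrix;
        # with t0 = 3 f^3/(1+2 f^3) this gives n >= matrix (1+2 f^3)/(6 f^2).
        f = float(t0_fraction)
        n_samples_per_spoke = int(np.ceil(1.05 * matrix * (1.0 + 2.0 * f**3)
                                          / (6.0 * f**2)))
    if n_samples_per_spoke < 2:
        raise ValueError("need at least 2 samples per spoke")

    kmax = 1.0 / (2.0 * resolution)
    f = float(t0_fraction)
    k0 = f * kmax
    # time of the linear->adapted transition, on a unit readout: from
    # kmax^3 = k0^3 (1 + 3 (1 - t0)/t0)  =>  t0 = 3 f^3 / (1 + 2 f^3)
    t0 = 3.0 * f**3 / (1.0 + 2.0 * f**3)

    t = (np.arange(n_samples_per_spoke) + 0.5) / n_samples_per_spoke
    k = np.where(
        t <= t0,
        k0 * t / t0,
        np.cbrt(k0**3 * (1.0 + 3.0 * np.maximum(t - t0, 0.0) / t0)),
    )
    if f == 1.0:  # pure constant-gradient spokes
        k = kmax * t

    # density compensation: exact k-space shell volume per sample,
    # (k_out^3 - k_in^3)/3 with midpoint shell edges; strictly positive.
    edges = np.empty(n_samples_per_spoke + 1)
    edges[1:-1] = 0.5 * (k[1:] + k[:-1])
    edges[0] = 0.0
    edges[-1] = k[-1] + 0.5 * (k[-1] - k[-2])
    weights = (edges[1:] ** 3 - edges[:-1] ** 3) / 3.0

    return RadialTrajectory(
        n_spokes=int(n_spokes),
        n_samples_per_spoke=int(n_samples_per_spoke),
        directions=_sphere_directions(int(n_spokes)),
        k_radii=k,
        density_weights=weights,
        sample_times=t * readout_duration,
        k0=k0,
        kmax=kmax,
    )


# ---------------------------------------------------------------------------
# Kaiser-Bessel gridding
# ---------------------------------------------------------------------------

def _kb_beta(width: int = KERNEL_WIDTH, os: float = OVERSAMPLE) -> float:
    # Beatty et al. optimal shape parameter
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def _kb_kernel(x: np.ndarray, width: int = KERNEL_WIDTH) -> np.ndarray:
    beta = _kb_beta(width)
    m = np.abs(x) <= width / 2.0
    out = np.zeros_like(x, dtype=float)
    arg = 1.0 - (2.0 * x[m] / width) ** 2
    out[m] = np.i0(beta * np.sqrt(np.maximum(arg, 0.0))) / width
    return out


def _kb_apodization(n: int, grid_os: int, width: int = KERNEL_WIDTH) -> np.ndarray:
    """Image-domain transform of the KB kernel along one axis (length n,
    centered), evaluated on the oversampled-grid frequency scale."""
    beta = _kb_beta(width)
    x = (np.arange(n) - n // 2) / float(grid_os)
    arg = (np.pi * width * x) ** 2 - beta**2
    out = np.empty(n)
    neg = arg < 0
    sq = np.sqrt(np.abs(arg))
    out[neg] = np.sinh(sq[neg]) / sq[neg]
    out[~neg] = np.sinc(sq[~neg] / np.pi)
    return out


def _grid_positions(traj: RadialTrajectory, grid_size: int) -> np.ndarray:
    """Sample positions in (oversampled) grid index units, centered at G/2."""
    G = OVERSAMPLE * grid_size
    kv = traj.kvectors()  # 1/mm
    # kmax maps to the edge of the nominal grid: index offset N/2 * OVERSAMPLE
    return kv / traj.kmax * (grid_size / 2.0) * OVERSAMPLE + G / 2.0


def _neighbor_offsets() -> np.ndarray:
    w = KERNEL_WIDTH
    r = np.arange(w) - w // 2 + 1
    return np.stack(np.meshgrid(r, r, r, indexing="ij"), axis=-1).reshape(-1, 3)


def radial_filter(traj: RadialTrajectory, kind: str | None, onset: float = 0.5) -> np.ndarray:
    """Per-sample radial k-space window. ``hann`` rolls off as cos^2 from
    ``onset * kmax`` to ``kmax``; undersampled center-out radial acquisitions
    conventionally use such a window to suppress streak energy at high k."""
    if kind is None:
        return np.ones(traj.n_samples_per_spoke)
    if kind != "hann":
        raise ValueError(f"unknown k-space filter {kind!r}")
    k = traj.k_radii / traj.kmax
    w = np.ones_like(k)
    m = k > onset
    w[m] = np.cos(0.5 * np.pi * (k[m] - onset) / (1.0 - onset)) ** 2
    return w


def grid_reconstruct(
    kspace_data: np.ndarray,
    traj: RadialTrajectory,
    grid_size: int,
    kspace_filter: str | None = None,
    crop: bool = True,
) -> np.ndarray:
    """Density-compensated Kaiser-Bessel gridding reconstruction.

    Returns a complex ``grid_size**3`` volume scaled to match the conjugate
    phase sum  x(r) = sum_s w_s d_s exp(+2pi i k_s . r). With ``crop=False``
    the full oversampled field of view (``2*grid_size`` per axis, same voxel
    scale) is returned; undersampling halos extend well beyond the nominal
    FOV and are only fully captured there.
    """
    kspace_data = np.asarray(kspace_data).reshape(-1)
    if kspace_data.size != traj.n_samples:
        raise ValueError(
            f"kspace_data has {kspace_data.size} samples but the trajectory "
            f"has {traj.n_samples}"
        )
    G = OVERSAMPLE * grid_size
    pos = _grid_positions(traj, grid_size)
    filt = np.broadcast_to(
        radial_filter(traj, kspace_filter),
        (traj.n_spokes, traj.n_samples_per_spoke),
    ).reshape(-1)
    vals = kspace_data * traj.flat_weights() * filt

    grid = np.zeros(G**3, dtype=complex)
    base = np.floor(pos).astype(np.int64)
    for off in _neighbor_offsets():
        idx = base + off
        w = (
            _kb_kernel(idx[:, 0] - pos[:, 0])
            * _kb_kernel(idx[:, 1] - pos[:, 1])
            * _kb_kernel(idx[:, 2] - pos[:, 2])
        )
        idx %= G
        flat = (idx[:, 0] * G + idx[:, 1]) * G + idx[:, 2]
        grid += np.bincount(flat, weights=(vals * w).real, minlength=G**3)
        grid += 1j * np.bincount(flat, weights=(vals * w).imag, minlength=G**3)

    img = fftshift(ifftn(ifftshift(grid.reshape(G, G, G)))) * G**3
    if crop:
        lo, hi = (G - grid_size) // 2, (G + grid_size) // 2
        img = img[lo:hi, lo:hi, lo:hi]
        ap = _kb_apodization(grid_size, G)
    else:
        ap = _kb_apodization(G, G)
    img /= ap[:, None, None] * ap[None, :, None] * ap[None, None, :]
    return img


def forward_sample(volume: np.ndarray, traj: RadialTrajectory) -> np.ndarray:
    """Sample a Cartesian volume on the trajectory (adjoint-consistent NUFFT).

    Returns per-sample complex k-space values d_s ≈ sum_r x(r) exp(-2pi i k_s.r).
    """
    volume = np.asarray(volume, dtype=complex)
    n = volume.shape[0]
    if volume.shape != (n, n, n):
        raise ValueError("volume must be a cube")
    G = OVERSAMPLE * n
    ap = _kb_apodization(n, G)
    v = volume / (ap[:, None, None] * ap[None, :, None] * ap[None, None, :])
    pad = np.zeros((G, G, G), dtype=complex)
    lo, hi = (G - n) // 2, (G + n) // 2
    pad[lo:hi, lo:hi, lo:hi] = v
    kgrid = fftshift(fftn(ifftshift(pad)))

    pos = _grid_positions(traj, n)
    base = np.floor(pos).astype(np.int64)
    out = np.zeros(pos.shape[0], dtype=complex)
    kflat = kgrid.reshape(-1)
    for off in _neighbor_offsets():
        idx = base + off
        w = (
            _kb_kernel(idx[:, 0] - pos[:, 0])
            * _kb_kernel(idx[:, 1] - pos[:, 1])
            * _kb_kernel(idx[:, 2] - pos[:, 2])
        )
        idx %= G
        out += kflat[(idx[:, 0] * G + idx[:, 1]) * G + idx[:, 2]] * w
    return out


# ---------------------------------------------------------------------------
# PSF simulation
# ---------------------------------------------------------------------------

def _profile_fwhm(profile: np.ndarray, peak: int) -> float:
    """FWHM of a 1D profile (grid units) by linear interpolation of the
    half-maximum crossings either side of ``peak``."""
    half = profile[peak] / 2.0
    left = right = None
    for i in range(peak, 0, -1):
        if profile[i - 1] < half <= profile[i]:
            left = (i - 1) + (half - profile[i - 1]) / (profile[i] - profile[i - 1])
            break
    for i in range(peak, len(profile) - 1):
        if profile[i + 1] < half <= profile[i]:
            right = i + (profile[i] - half) / (profile[i] - profile[i + 1])
            break
    if left is None or right is None:
        raise ValueError("PSF main lobe does not fit in the grid; increase grid_size")
    return right - left


def simulate_psf(
    traj: RadialTrajectory,
    grid_size: int,
    off_resonance: float = 0.0,
    readout_times: np.ndarray | None = None,
    voxel_size: float = 1.0,
    t2s: float | None = None,
    t2l: float | None = None,
    fs: float = 60.0,
    kspace_filter: str | None = "hann",
    full_extent: bool = False,
) -> PointSpreadFunction:
    """Simulate the image-domain PSF of ``traj`` on a ``grid_size``^3 grid.

    Unit k-space data are phase-modulated by ``off_resonance`` (Hz) over the
    per-sample readout times (ms) and optionally damped by a bi-exponential
    T2* envelope (the decay the tissue undergoes while the spoke is read
    out), then gridded and inverse transformed. The result is normalized to
    unit sum so that convolution with it preserves total signal.
    """
    if grid_size < 16:
        raise ValueError(f"grid_size must be >= 16, got {grid_size}")
    times = traj.flat_times() if readout_times is None else np.broadcast_to(
        np.asarray(readout_times, dtype=float),
        (traj.n_spokes, traj.n_samples_per_spoke),
    ).reshape(-1)
    data = np.exp(2j * np.pi * off_resonance * times * 1e-3)
    if t2s is not None and t2l is not None:
        frac = fs / 100.0
        data = data * (frac * np.exp(-times / t2s) + (1 - frac) * np.exp(-times / t2l))
    img = grid_reconstruct(data, traj, grid_size, kspace_filter=kspace_filter,
                           crop=not full_extent)
    img = img / img.sum()
    mag = np.abs(img)
    peak = np.unravel_index(int(np.argmax(mag)), mag.shape)
    fwhm = voxel_size * np.mean([
        _profile_fwhm(mag[:, peak[1], peak[2]], peak[0]),
        _profile_fwhm(mag[peak[0], :, peak[2]], peak[1]),
        _profile_fwhm(mag[peak[0], peak[1], :], peak[2]),
    ])
    return PointSpreadFunction(grid=img, voxel_size=voxel_size,
                               peak_index=tuple(int(p) for p in peak), fwhm=float(fwhm))


def apply_psf(volume: np.ndarray, psf: PointSpreadFunction | np.ndarray) -> np.ndarray:
    """Blur a volume by linear convolution with a PSF kernel, aligned so a
    delta kernel is the identity (kernels with the peak at index M//2 of an
    even-sized axis are trimmed by one plane to center the peak)."""
    from scipy.signal import fftconvolve

    kern = psf.grid if isinstance(psf, PointSpreadFunction) else psf
    if kern.shape[0] % 2 == 0:
        kern = kern[1:, 1:, 1:]
    return fftconvolve(volume, kern, mode="same")


def save_psf_nifti(psf: PointSpreadFunction, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag([psf.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.abs(psf.grid).astype(np.float32), affine), str(path))


def conjugate_phase_reconstruct(
    kspace_data: np.ndarray,
    traj: RadialTrajectory,
    grid_size: int,
    voxel_size: float | None = None,
) -> np.ndarray:
    """Brute-force direct-DFT (conjugate phase) reconstruction.

    O(samples * voxels); intended as an independent oracle on small grids,
    not for production use.
    """
    kv = traj.kvectors() * (1.0 / (2.0 * traj.kmax))  # cycles per voxel pitch
    w = traj.flat_weights() * np.asarray(kspace_data).reshape(-1)
    ax = np.arange(grid_size) - grid_size // 2
    out = np.zeros((grid_size, grid_size, grid_size), dtype=complex)
    for i, x in enumerate(ax):
        phase = np.exp(2j * np.pi * (
            kv[:, 0, None, None] * x
            + kv[:, 1, None, None] * ax[None, :, None]
            + kv[:, 2, None, None] * ax[None, None, :]
        ))
        out[i] = (w[:, None, None] * phase).sum(0)
    return out
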