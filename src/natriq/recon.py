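"""Coil combination, SNR mapping, B0/B1+ field estimation, and intensity
and off-resonance corrections.

Field maps are derived on the homogeneous cylinder phantom (scanned with the
same geometry as the subject) and transferred: the dual-echo phase difference
gives B0 in Hz, a phase-sensitive composite-pulse acquisition (nominal
180deg about x followed by 90deg about y) gives the actual flip angle, and
the cylinder's observed intensity profile yields a multiplicative shading
correction applied to in-vivo-like data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .phantom import AcquisitionSeries
from .trajectory import RadialTrajectory, grid_reconstruct

logger = logging.getLogger("natriq")

#: actual-flip inversion domain of the phase-sensitive B1 method, degrees.
#: The composite-pulse phase degenerates toward 0/180, so voxels outside
#: this range are flagged invalid.
B1_FLIP_DOMAIN = (10.0, 170.0)


@dataclasses.dataclass
class FieldMaps:
    """B0 (Hz) and B1+ (actual/nominal flip) maps with a validity mask."""

    b0: np.ndarray | None = None
    b1: np.ndarray | None = None
    support_mask: np.ndarray | None = None


@dataclasses.dataclass
class CorrectionFactors:
    """Per-voxel multiplicative intensity gain (1 where uninformed)."""

    intensity_gain: np.ndarray
    provenance: str = ""


@dataclasses.dataclass
class SNRMap:
    snr: np.ndarray
    n_replicas: int


# ---------------------------------------------------------------------------
# Adaptive (Walsh-style) coil combination
# ---------------------------------------------------------------------------

def adaptive_combine(
    coil_volumes: np.ndarray,
    block_overlap: int = 8,
    interp_factor: int = 2,
) -> np.ndarray:
    """Combine per-coil complex volumes by block-wise dominant-eigenvector
    sensitivity estimation (3D adaptive combine).

    Local coil covariance matrices are formed over overlapping blocks of
    ``block_overlap`` voxels placed every ``block_overlap // interp_factor``
    voxels; the dominant eigenvector per block is the sensitivity estimate,
    phase-referenced to the first coil, and trilinearly interpolated back to
    the full grid before the matched-filter combination.
    """
    coil_volumes = np.asarray(coil_volumes, dtype=complex)
    if coil_volumes.ndim != 4:
        raise ValueError("coil_volumes must be (n_coils, nx, ny, nz)")
    nc = coil_volumes.shape[0]
    shape = coil_volumes.shape[1:]
    if any(block_overlap > s for s in shape):
        raise ValueError("block larger than volume")
    if nc == 1:
        return coil_volumes[0].copy()

    stride = max(1, block_overlap // interp_factor)
    centers = [np.arange(0, s, stride) for s in shape]
    wshape = tuple(len(c) for c in centers)
    weights = np.empty((nc,) + wshape, dtype=complex)
    half = block_overlap // 2
    for ix, cx in enumerate(centers[0]):
        sx = slice(max(0, cx - half), min(shape[0], cx + half + 1))
        for iy, cy in enumerate(centers[1]):
            sy = slice(max(0, cy - half), min(shape[1], cy + half + 1))
            for iz, cz in enumerate(centers[2]):
                sz = slice(max(0, cz - half), min(shape[2], cz + half + 1))
                block = coil_volumes[:, sx, sy, sz].reshape(nc, -1)
                cov = block @ block.conj().T
                evals, evecs = np.linalg.eigh(cov)
                v = evecs[:, -1]
                v = v * np.exp(-1j * np.angle(v[0]))  # first-coil phase reference
                weights[:, ix, iy, iz] = v
    factors = [s / w for s, w in zip(shape, wshape)]
    full = np.empty((nc,) + shape, dtype=complex)
    for c in range(nc):
        full[c] = (zoom(weights[c].real, factors, order=1, grid_mode=True, mode="nearest")
                   + 1j * zoom(weights[c].imag, factors, order=1, grid_mode=True, mode="nearest"))
    norm = np.sqrt((np.abs(full) ** 2).sum(axis=0))
    norm[norm == 0] = 1.0
    return (full.conj() * coil_volumes).sum(axis=0) / norm


# ---------------------------------------------------------------------------
# Multiple-replica SNR
# ---------------------------------------------------------------------------

def multiple_replica_snr(
    acq: AcquisitionSeries,
    n_replicas: int = 100,
    seed: int = 0,
    contrast: int = 0,
    recon=None,
) -> SNRMap:
    """Per-voxel SNR from repeated reconstructions of noise-perturbed copies.

    Fresh complex Gaussian noise matching the noise-only scans' statistics is
    added to the (already measured) volume ``n_replicas`` times; each copy is
    passed through ``recon`` (default: coil-combined magnitude) and SNR is
    mean/sd across replicas.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if acq.noise_only.size == 0:
        raise ValueError("acquisition has no noise-only volumes; SNR needs them")
    sigma = float(np.std(np.concatenate([
        acq.noise_only.real.ravel(), acq.noise_only.imag.ravel()
    ])))
    if recon is None:
        def recon(vols):  # vols: (n_coils, *grid)
            return np.abs(adaptive_combine(vols)) if vols.shape[0] > 1 else np.abs(vols[0])
    rng = np.random.default_rng(seed)
    base = acq.volumes[contrast]
    acc = None
    acc2 = None
    for _ in range(n_replicas):
        noisy = base + sigma * (rng.standard_normal(base.shape)
                                + 1j * rng.standard_normal(base.shape))
        img = recon(noisy)
        acc = img if acc is None else acc + img
        acc2 = img**2 if acc2 is None else acc2 + img**2
    mean = acc / n_replicas
    var = np.maximum(acc2 / n_replicas - mean**2, 0.0)
    sd = np.sqrt(var * n_replicas / (n_replicas - 1))
    snr = np.where(sd > 0, mean / np.maximum(sd, 1e-30), 0.0)
    return SNRMap(snr=snr, n_replicas=n_replicas)


# ---------------------------------------------------------------------------
# B0 mapping (dual echo)
# ---------------------------------------------------------------------------

def b0_map_dual_echo(
    echo1: np.ndarray,
    echo2: np.ndarray,
    te1: float,
    te2: float,
    mag_threshold: float = 0.1,
) -> FieldMaps:
    """Off-resonance in Hz from the phase difference of two echoes.

    b0 = angle(echo2 * conj(echo1)) / (2 pi (te2 - te1)), TEs in ms. The
    measurable range is +-1/(2 dTE); larger offsets wrap (alias) back into
    it. Support is where the first-echo magnitude exceeds ``mag_threshold``
    of its maximum.
    """
    if te2 <= te1:
        raise ValueError("te2 must exceed te1")
    dte_s = (te2 - te1) * 1e-3
    b0 = np.angle(np.asarray(echo2) * np.conj(np.asarray(echo1))) / (2.0 * np.pi * dte_s)
    support = np.abs(echo1) > mag_threshold * np.abs(echo1).max()
    return FieldMaps(b0=b0, support_mask=support)


# ---------------------------------------------------------------------------
# Phase-sensitive B1 mapping
# ---------------------------------------------------------------------------

def _rot_x(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.array([[o, z, z], [z, c, -s], [z, s, c]])


def _rot_y(a: np.ndarray) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.array([[c, z, s], [z, o, z], [-s, z, c]])


def composite_pulse_phase(flip_y_deg) -> np.ndarray:
    """Transverse-magnetization phase after the composite pulse
    (2*alpha about x, then alpha about y) applied to equilibrium Mz,
    where alpha = ``flip_y_deg``, by explicit rotation composition."""
    a = np.deg2rad(np.atleast_1d(np.asarray(flip_y_deg, dtype=float)))
    flat = a.ravel()
    rx = np.moveaxis(_rot_x(2 * flat), -1, 0)   # (n, 3, 3)
    ry = np.moveaxis(_rot_y(flat), -1, 0)
    m0 = np.array([0.0, 0.0, 1.0])
    m = np.einsum("nij,nj->ni", ry, np.einsum("nij,j->ni", rx, m0))
    return np.angle(m[:, 0] + 1j * m[:, 1]).reshape(a.shape)


def _b1_lookup(n: int = 4001) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = B1_FLIP_DOMAIN
    alphas = np.linspace(lo, hi, n)
    phases = np.unwrap(composite_pulse_phase(alphas))
    return alphas, phases


def b1_map_phase_sensitive(
    prepared: np.ndarray,
    reference: np.ndarray,
    flip_nominal: float = 90.0,
) -> FieldMaps:
    """Actual flip angle per voxel from the composite-pulse signal phase.

    The phase of ``prepared * conj(reference)`` is matched against the
    tabulated (strictly monotone) phase-versus-flip relation of the
    composite rotation; ``b1 = alpha_actual / flip_nominal``. Voxels whose
    phase falls outside the invertible branch are flagged invalid (NaN).
    """
    if prepared.shape != reference.shape:
        raise ValueError("prepared and reference must share a grid")
    alphas, phases = _b1_lookup()
    lo_p, hi_p = phases.min(), phases.max()
    measured = np.angle(np.asarray(prepared) * np.conj(np.asarray(reference)))
    # the tabulated branch spans < 2 pi, so exactly one 2 pi shift of the
    # measured angle lands inside it
    shifted = measured + 2.0 * np.pi * np.ceil((lo_p - measured) / (2.0 * np.pi))
    valid = (shifted >= lo_p) & (shifted <= hi_p)
    order = np.argsort(phases)
    alpha = np.interp(shifted, phases[order], alphas[order])
    alpha = np.where(valid, alpha, np.nan)
    return FieldMaps(b1=alpha / flip_nominal, support_mask=valid)


# ---------------------------------------------------------------------------
# Off-resonance (conjugate-phase / multi-frequency) correction
# ---------------------------------------------------------------------------

def correct_off_resonance(
    kspace_data: np.ndarray,
    b0: np.ndarray,
    traj: RadialTrajectory,
    grid_size: int,
    n_freq_bins: int = 20,
    kspace_filter: str | None = "hann",
) -> np.ndarray:
    """Multi-frequency reconstruction: the data are reconstructed at
    demodulation frequencies spanning the B0 range and the final image takes,
    per voxel, the reconstruction demodulated at that voxel's off-resonance
    (nearest bin)."""
    b0 = np.asarray(b0, dtype=float)
    times_ms = traj.flat_times()
    lo, hi = float(np.nanmin(b0)), float(np.nanmax(b0))
    if not np.isfinite(lo) or hi - lo < 1e-9:
        freqs = np.array([0.5 * (lo + hi) if np.isfinite(lo) else 0.0])
    else:
        freqs = np.linspace(lo, hi, max(1, int(n_freq_bins)))
    out = np.zeros((grid_size,) * 3, dtype=complex)
    if len(freqs) == 1:
        sel = np.zeros(b0.shape, dtype=int)
    else:
        sel = np.argmin(np.abs(b0[..., None] - freqs[None, None, None, :]), axis=-1)
    for i, f in enumerate(freqs):
        mask = sel == i
        if not mask.any():
            continue
        demod = np.asarray(kspace_data).reshape(-1) * np.exp(-2j * np.pi * f * times_ms * 1e-3)
        img = grid_reconstruct(demod, traj, grid_size, kspace_filter=kspace_filter)
        out[mask] = img[mask]
    return out


# ---------------------------------------------------------------------------
# Phantom-derived intensity correction
# ---------------------------------------------------------------------------

def derive_correction_factors(
    cylinder_image: np.ndarray,
    reference_shape: np.ndarray | None = None,
    nominal_level: float | None = None,
    smooth_sigma: float = 2.0,
    support_threshold: float = 0.2,
    provenance: str = "cylinder",
) -> CorrectionFactors:
    """Multiplicative shading correction from the homogeneous cylinder.

    The observed cylinder image is smoothed (Gaussian, sd ``smooth_sigma``
    voxels) and the gain is (expected)/(observed) inside the cylinder
    support; outside support, and where the observed intensity is near zero,
    the gain is 1. ``reference_shape`` is the cylinder's PVE-expected
    profile (its known geometry blurred by the acquisition PSF, flat deep
    inside, rolling off at the rim); normalizing by it keeps the cylinder's
    own partial-volume rolloff out of the shading estimate. Without it a
    flat nominal level is used. Because the cylinder is scanned with the
    subject's geometry, the shading carries the combined transmit/receive
    (B1) and residual reconstruction non-uniformity that also affects the
    in-vivo image.
    """
    obs = np.abs(np.asarray(cylinder_image, dtype=float))
    # normalized (mask-aware) smoothing: dividing by the smoothed support
    # keeps object edges from biasing the local level estimate
    rough_support = obs > 0.05 * obs.max()
    num = gaussian_filter(obs * rough_support, smooth_sigma)
    den = gaussian_filter(rough_support.astype(float), smooth_sigma)
    smoothed = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)
    if reference_shape is not None:
        ref = np.abs(np.asarray(reference_shape, dtype=float))
        ref_support = ref > 0.05 * ref.max()
        rnum = gaussian_filter(ref * ref_support, smooth_sigma)
        rden = gaussian_filter(ref_support.astype(float), smooth_sigma)
        ref = np.where(rden > 1e-6, rnum / np.maximum(rden, 1e-6), 0.0)
        support = ref > support_threshold * ref.max()
        level = nominal_level if nominal_level is not None else float(
            smoothed[support].sum() / ref[support].sum()
        )
        expected = level * ref
    else:
        support = smoothed > support_threshold * smoothed.max()
        level = nominal_level if nominal_level is not None else float(
            smoothed[support].mean()
        )
        expected = np.full_like(smoothed, level)
    gain = np.ones_like(smoothed)
    ok = support & (smoothed > 1e-12 * smoothed.max())
    gain[ok] = expected[ok] / smoothed[ok]
    n_bad = int(support.sum() - ok.sum())
    if n_bad:
        logger.warning("correction factors: %d near-zero voxels left at gain 1", n_bad)
    return CorrectionFactors(intensity_gain=gain, provenance=provenance)


def apply_correction(invivo: np.ndarray, factors: CorrectionFactors) -> np.ndarray:
    return np.asarray(invivo) * factors.intensity_gain


def derive_and_apply_correction(
    invivo: np.ndarray,
    cylinder_image: np.ndarray,
    reference_shape: np.ndarray | None = None,
    nominal_level: float | None = None,
    smooth_sigma: float = 2.0,
) -> tuple[np.ndarray, CorrectionFactors]:
    """Convenience wrapper: derive factors from the cylinder and apply them."""
    factors = derive_correction_factors(cylinder_image, reference_shape,
                                        nominal_level, smooth_sigma)
    return apply_correction(invivo, factors), factors
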