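"""Partial-volume correction by the geometric transfer matrix (GTM) method.

Finite resolution mixes signal between neighbouring compartments: the
observed mean of ROI j is a weighted combination of the true compartment
means. Convolving each compartment mask with the acquisition's simulated PSF
yields its region-spread function (RSF); the matrix of ROI means of the
RSFs,

    omega[j, i] = mean over ROI j of (mask_i (*) PSF),

links true means c to observed means b through omega @ c = b, which is
solved by least squares. For noiseless piecewise-constant images and a
full-rank omega this inversion is exact for any PSF.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .trajectory import PointSpreadFunction, apply_psf

logger = logging.getLogger("natriq")

CONDITION_LIMIT = 1e6


@dataclasses.dataclass
class GTMSystem:
    """Assembled and solved GTM linear system."""

    names: list
    weights: np.ndarray      # (n, n) omega
    observed: np.ndarray     # (n,) b
    solved: np.ndarray       # (n,) c
    condition_number: float

    def as_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.weights, index=self.names, columns=self.names)
        df["observed"] = self.observed
        df["solved"] = self.solved
        return df


def _kernel(psf) -> np.ndarray:
    kern = psf.grid if isinstance(psf, PointSpreadFunction) else np.asarray(psf)
    total = kern.sum()
    if not np.isclose(abs(total), 1.0, rtol=1e-6):
        logger.info("PSF not normalized (sum=%s); normalizing for RSF computation", total)
        kern = kern / total
    return kern


def compute_rsf(mask: np.ndarray, psf) -> np.ndarray:
    """Region-spread function: compartment mask convolved with the
    (unit-sum) PSF. Linear convolution (implicit zero padding), so no
    wrap-around leakage; total RSF mass equals the mask voxel count minus
    whatever the kernel support carries outside the array."""
    mask = np.asarray(mask, dtype=float)
    kern = _kernel(psf)
    rsf = apply_psf(mask, kern)
    return rsf.real if np.iscomplexobj(rsf) else rsf


def gtm_correct(
    masks: dict,
    psf,
    image: np.ndarray,
    slices: slice | None = None,
    condition_limit: float = CONDITION_LIMIT,
) -> GTMSystem:
    """Assemble and solve the GTM system for ``image``.

    ``masks`` maps compartment names to disjoint binary volumes; every
    structure carrying signal should be included (unsegmented anatomy is
    absorbed into an explicit "other" compartment so the rows account for
    essentially all spread-in). ``slices`` optionally restricts the ROI
    means to a sub-volume along z (segmentation on a few slices), while the
    RSFs are still computed in 3D.
    """
    if len(masks) < 2:
        raise ValueError("GTM needs at least 2 compartments")
    image = np.asarray(image)
    names = list(masks.keys())
    bool_masks = []
    for name in names:
        m = np.asarray(masks[name], dtype=bool)
        if m.shape != image.shape:
            raise ValueError(f"mask {name!r} shape {m.shape} != image {image.shape}")
        if not m.any():
            raise ValueError(f"mask {name!r} is empty")
        bool_masks.append(m)
    for i in range(len(bool_masks)):
        for j in range(i + 1, len(bool_masks)):
            if (bool_masks[i] & bool_masks[j]).any():
                raise ValueError(f"masks {names[i]!r} and {names[j]!r} overlap")

    sub = (slice(None), slice(None), slices) if slices is not None else None
    n = len(names)
    omega = np.empty((n, n))
    rsfs = [compute_rsf(m, psf) for m in bool_masks]
    for j, mj in enumerate(bool_masks):
        sel = mj if sub is None else mj[sub]
        for i, rsf in enumerate(rsfs):
            r = rsf if sub is None else rsf[sub]
            omega[j, i] = r[sel].mean()

    b = np.array([
        (image if sub is None else image[sub])[(mj if sub is None else mj[sub])].mean()
        for mj in bool_masks
    ])
    cond = float(np.linalg.cond(omega))
    if cond > condition_limit:
        raise ValueError(
            f"GTM matrix is ill-conditioned (cond={cond:.3g}); merge or drop "
            "compartments that the PSF cannot separate"
        )
    c, *_ = np.linalg.lstsq(omega, b, rcond=None)
    return GTMSystem(names=names, weights=omega, observed=b, solved=c,
                     condition_number=cond)
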