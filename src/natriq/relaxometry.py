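"""ROI-based sodium relaxometry: T1 from inversion recovery and
bi-exponential T2* from multi-echo magnitude data.

Fitting is performed ROI-by-ROI on mean signal curves. The T1 model is the
magnitude inversion-recovery curve

    SI(TI) = | M_m (1 - 2 exp(-TI/T1)) | + offset,

and the T2* model is the five-parameter bi-exponential decay

    SI(TE) = C0s exp(-TE/T2s*) + C0l exp(-TE/T2l*) + offset,

with short/long component fractions Fs = 100 C0s/(C0s + C0l) and
Fl = 100 - Fs. The offset is a free non-negative parameter absorbing the
Rician noise floor of magnitude images. Spin-3/2 sodium in tissue decays
bi-exponentially (60/40 short/long in muscle); agarose phantoms differ.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("natriq")

#: default initial guesses (ms) for the two T2* components in muscle
T2S_INIT, T2L_INIT = 3.0, 13.0
T2_BOUNDS = (0.1, 100.0)
N_STARTS = 8
MAX_ITER = 500
FTOL = 1e-10
#: short/long time constants closer than this ratio flag a degenerate bi fit
DEGENERACY_RATIO = 0.9


@dataclasses.dataclass
class ROISeries:
    """Mean ROI signal versus TE or TI for one compartment."""

    roi_label: int | str
    contrast_values: np.ndarray   # ms
    mean_signal: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.contrast_values = np.asarray(self.contrast_values, dtype=float)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        if self.contrast_values.shape != self.mean_signal.shape:
            raise ValueError("contrast_values and mean_signal lengths differ")
        if self.n_voxels <= 0:
            raise ValueError("ROI is empty")


@dataclasses.dataclass
class T1Fit:
    mm: float
    t1: float
    offset: float
    residual_rms: float
    converged: bool


@dataclasses.dataclass
class T2StarFit:
    c0s: float
    c0l: float
    t2s: float
    t2l: float
    offset: float
    model: str                 # "mono" | "bi"
    residual_rms: float
    converged: bool
    degenerate: bool = False

    @property
    def fs(self) -> float:
        tot = self.c0s + self.c0l
        return 100.0 * self.c0s / tot if tot > 0 else 0.0

    @property
    def fl(self) -> float:
        return 100.0 - self.fs


def extract_roi_series(
    volumes: np.ndarray,
    contrast_values: np.ndarray,
    masks: dict,
    reference_contrast: int = 0,
) -> dict:
    """Mean ROI signal per compartment across a contrast series.

    ``volumes`` is (n_contrast, nx, ny, nz) (magnitude). The ROI geometry is
    taken from ``masks`` as evaluated on the reference contrast (the lowest
    TE in the multi-echo protocol) and reused unchanged for every contrast.
    """
    volumes = np.asarray(volumes)
    out = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"ROI {name!r} is empty")
        means = volumes[:, mask].mean(axis=1)
        out[name] = ROISeries(roi_label=name, contrast_values=contrast_values,
                              mean_signal=means, n_voxels=n)
    return out


def _multi_start_fit(residual, x0, bounds, jitters, rng):
    best = None
    for j in range(jitters):
        start = np.array(x0, dtype=float)
        if j > 0:
            start = start * rng.uniform(0.5, 1.8, size=len(start))
        start = np.clip(start, bounds[0], bounds[1])
        try:
            res = least_squares(residual, start, bounds=bounds, ftol=FTOL,
                                xtol=1e-12, max_nfev=MAX_ITER)
        except Exception:  # singular start; try next
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_t1_ir(series: ROISeries, seed: int = 0) -> T1Fit:
    """Fit the magnitude inversion-recovery model by multi-start
    Levenberg-Marquardt least squares.

    T1 is initialized from the zero-crossing estimate TI_null / ln 2 (the
    signed IR signal crosses zero at TI = T1 ln 2, so the TI of the signal
    minimum approximates TI_null).
    """
    ti = series.contrast_values
    y = series.mean_signal
    if len(np.unique(ti)) < 4:
        raise ValueError("T1 fit needs at least 4 distinct inversion times")

    ti_null = ti[int(np.argmin(y))]
    t1_init = max(ti_null / np.log(2.0), 1.0)
    x0 = [max(y.max() - y.min(), 1e-12), t1_init, max(y.min(), 0.0)]
    lb = [0.0, 0.1, 0.0]
    ub = [np.inf, 1e4, np.inf]

    def residual(p):
        mm, t1, off = p
        return np.abs(mm * (1.0 - 2.0 * np.exp(-ti / t1))) + off - y

    rng = np.random.default_rng(seed)
    best = _multi_start_fit(residual, x0, (lb, ub), N_STARTS, rng)
    if best is None:
        return T1Fit(np.nan, np.nan, np.nan, np.nan, converged=False)
    mm, t1, off = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    # degenerate data: no TI dependence the model can attribute to recovery
    signal_range = y.max() - y.min()
    converged = bool(best.success) and mm > 1e-9 * max(off, 1.0) and (
        signal_range > 1e-12 + 1e-6 * max(y.max(), 1.0)
    )
    return T1Fit(mm=float(mm), t1=float(t1), offset=float(off),
                 residual_rms=rms, converged=converged)


def fit_t2star(series: ROISeries, model: str = "bi", seed: int = 0) -> T2StarFit:
    """Fit mono- or bi-exponential T2* decay with non-negative amplitudes.

    Components are ordered so t2s <= t2l after the fit; a bi fit whose two
    time constants nearly coincide is flagged degenerate (the data do not
    resolve two components).
    """
    te = series.contrast_values
    y = series.mean_signal
    n_req = 7 if model == "bi" else 5
    if len(np.unique(te)) < n_req:
        raise ValueError(f"{model} T2* fit needs >= {n_req} distinct echo times")
    rng = np.random.default_rng(seed)
    amp0 = max(y.max() - y.min(), 1e-12)

    if model == "mono":
        def residual(p):
            c0, t2, off = p
            return c0 * np.exp(-te / t2) + off - y

        best = _multi_start_fit(residual, [amp0, T2L_INIT, max(y.min(), 0.0)],
                                ([0.0, T2_BOUNDS[0], 0.0],
                                 [np.inf, T2_BOUNDS[1], np.inf]),
                                N_STARTS, rng)
        if best is None:
            return T2StarFit(*[np.nan] * 5, model="mono", residual_rms=np.nan,
                             converged=False)
        c0, t2, off = best.x
        return T2StarFit(c0s=0.0, c0l=float(c0), t2s=float(t2), t2l=float(t2),
                         offset=float(off), model="mono",
                         residual_rms=float(np.sqrt(np.mean(best.fun**2))),
                         converged=bool(best.success))

    if model != "bi":
        raise ValueError(f"unknown model {model!r}")

    def residual(p):
        c0s, c0l, t2s, t2l, off = p
        return c0s * np.exp(-te / t2s) + c0l * np.exp(-te / t2l) + off - y

    x0 = [0.6 * amp0, 0.4 * amp0, T2S_INIT, T2L_INIT, max(y.min(), 0.0)]
    lb = [0.0, 0.0, T2_BOUNDS[0], T2_BOUNDS[0], 0.0]
    ub = [np.inf, np.inf, T2_BOUNDS[1], T2_BOUNDS[1], np.inf]
    best = _multi_start_fit(residual, x0, (lb, ub), N_STARTS, rng)
    if best is None:
        return T2StarFit(*[np.nan] * 5, model="bi", residual_rms=np.nan,
                         converged=False)
    c0s, c0l, t2s, t2l, off = best.x
    if t2s > t2l:  # enforce short/long ordering
        c0s, c0l, t2s, t2l = c0l, c0s, t2l, t2s
    # two components merge, or one carries (essentially) no amplitude: the
    # data do not support two distinct decays
    tot = c0s + c0l
    degenerate = (t2l > 0 and (t2s / t2l) > DEGENERACY_RATIO) or (
        tot > 0 and min(c0s, c0l) / tot < 0.02
    )
    return T2StarFit(c0s=float(c0s), c0l=float(c0l), t2s=float(t2s),
                     t2l=float(t2l), offset=float(off), model="bi",
                     residual_rms=float(np.sqrt(np.mean(best.fun**2))),
                     converged=bool(best.success), degenerate=degenerate)


def fit_voxelwise(
    volumes: np.ndarray,
    contrast_values: np.ndarray,
    mask: np.ndarray,
    kind: str = "t2star",
    model: str = "bi",
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Voxelwise parameter maps (extra to the primary ROI-level path).

    Fits every voxel inside ``mask`` independently; returns maps (NaN
    outside the mask). Slow by construction — intended for small volumes or
    single slices.
    """
    volumes = np.asarray(volumes)
    mask = np.asarray(mask, dtype=bool)
    shape = volumes.shape[1:]
    if kind == "t1":
        out = {k: np.full(shape, np.nan) for k in ("t1", "mm", "offset")}
    else:
        out = {k: np.full(shape, np.nan) for k in ("t2s", "t2l", "fs", "offset")}
    for idx in zip(*np.nonzero(mask)):
        series = ROISeries("voxel", contrast_values, volumes[(slice(None),) + idx], 1)
        if kind == "t1":
            f = fit_t1_ir(series, seed=seed)
            if f.converged:
                out["t1"][idx], out["mm"][idx], out["offset"][idx] = f.t1, f.mm, f.offset
        else:
            f = fit_t2star(series, model=model, seed=seed)
            if f.converged:
                out["t2s"][idx], out["t2l"][idx] = f.t2s, f.t2l
                out["fs"][idx], out["offset"][idx] = f.fs, f.offset
    return out


def fits_to_frame(fits: dict):
    """Tabulate fits (dict of label -> T1Fit/T2StarFit) as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for name, f in fits.items():
        row = {"roi": name, **dataclasses.asdict(f)}
        if isinstance(f, T2StarFit):
            row["fs"] = f.fs
            row["fl"] = f.fl
        rows.append(row)
    return pd.DataFrame(rows)
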