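"""Tissue sodium concentration from calibrated, corrected intensities.

Four agarose calibration tubes (15.4, 30.8, 46.2, 61.6 mmol/L) define a
linear intensity-versus-concentration calibration. TSC follows

    [Na_invivo] = (I_invivo_corr / I_phan_corr) * [Na_ref],

with [Na_ref] = 25 mmol/L and I_phan_corr the calibration-curve-predicted
corrected intensity at the reference concentration. Both intensities are
first divided by their steady-state relaxation factor

    f = (1 - exp(-TR/T1)) * [(Fs/100) exp(-TE/T2s*) + (1-Fs/100) exp(-TE/T2l*)]

so that tissue/phantom relaxation differences cancel out of the ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

DEFAULT_NA_REF = 25.0  # mmol/L
DEFAULT_CONCENTRATIONS = (15.4, 30.8, 46.2, 61.6)  # mmol/L


@dataclasses.dataclass
class CalibrationCurve:
    concentrations: np.ndarray
    corrected_intensities: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    na_ref: float
    through_origin: bool = False

    @property
    def i_phan_corr(self) -> float:
        """Curve-predicted corrected intensity at the reference concentration."""
        return self.slope * self.na_ref + self.intercept

    def predict(self, concentration) -> np.ndarray:
        return self.slope * np.asarray(concentration) + self.intercept


@dataclasses.dataclass
class TSCResult:
    compartments: list
    i_invivo_corr: np.ndarray
    relaxation_factor_tissue: np.ndarray
    relaxation_factor_phantom: float
    tsc: np.ndarray                    # mmol/L
    provenance: dict = dataclasses.field(default_factory=dict)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "muscle": self.compartments,
            "i_invivo_corr": self.i_invivo_corr,
            "relaxation_factor_tissue": self.relaxation_factor_tissue,
            "relaxation_factor_phantom": self.relaxation_factor_phantom,
            "tsc_mmol_per_L": self.tsc,
            **{k: v for k, v in self.provenance.items()},
        })


def fit_calibration_curve(
    tube_means,
    concentrations=DEFAULT_CONCENTRATIONS,
    na_ref: float = DEFAULT_NA_REF,
    through_origin: bool = False,
) -> CalibrationCurve:
    """Ordinary least-squares calibration line of corrected tube intensity
    versus prepared concentration. The intercept is free by default (it
    absorbs any residual noise floor); ``through_origin`` forces it to 0."""
    y = np.asarray(tube_means, dtype=float)
    x = np.asarray(concentrations, dtype=float)
    if len(np.unique(x)) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 tubes with distinct concentrations")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    else:
        fit = sps.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    if slope <= 0:
        raise ValueError("calibration slope is non-positive; tube intensities corrupt")
    return CalibrationCurve(concentrations=x, corrected_intensities=y,
                            slope=slope, intercept=intercept, r_squared=r2,
                            na_ref=na_ref, through_origin=through_origin)


def relaxation_factor(t1, t2s, t2l, fs, tr, te):
    """Steady-state relaxation attenuation (dimensionless, in (0, 1])."""
    t1, t2s, t2l = map(np.asarray, (t1, t2s, t2l))
    if np.any(t1 <= 0) or np.any(t2s <= 0) or np.any(t2l <= 0):
        raise ValueError("relaxation times must be positive")
    frac = np.asarray(fs) / 100.0
    return (1.0 - np.exp(-tr / t1)) * (
        frac * np.exp(-te / t2s) + (1.0 - frac) * np.exp(-te / t2l)
    )


def compute_tsc(
    compartment_means: dict,
    cal: CalibrationCurve,
    tissue_relax: dict,
    phantom_relax: dict,
    tr: float,
    te: float,
    provenance: dict | None = None,
) -> TSCResult:
    """Apply the calibration ratio to solved compartment means.

    ``compartment_means`` maps muscle name to its (PVE/B0/B1-corrected)
    intensity; ``tissue_relax`` maps muscle name to a dict with keys
    t1/t2s/t2l/fs (cohort means by default upstream); ``phantom_relax`` is
    one such dict for the agarose calibration phantoms.
    """
    names = list(compartment_means.keys())
    missing = [n for n in names if n not in tissue_relax]
    if missing:
        raise ValueError(f"missing tissue relaxation parameters for {missing}")
    fp = float(relaxation_factor(phantom_relax["t1"], phantom_relax["t2s"],
                                 phantom_relax["t2l"], phantom_relax["fs"], tr, te))
    ft = np.array([
        relaxation_factor(tissue_relax[n]["t1"], tissue_relax[n]["t2s"],
                          tissue_relax[n]["t2l"], tissue_relax[n]["fs"], tr, te)
        for n in names
    ])
    raw = np.array([compartment_means[n] for n in names], dtype=float)
    neg = raw < 0
    if neg.any():
        import logging

        logging.getLogger("natriq").warning(
            "negative solved means clipped to 0 for %s",
            [n for n, bad in zip(names, neg) if bad],
        )
        raw = np.where(neg, 0.0, raw)
    tsc = (raw / ft) / (cal.i_phan_corr / fp) * cal.na_ref
    return TSCResult(compartments=names, i_invivo_corr=raw,
                     relaxation_factor_tissue=ft, relaxation_factor_phantom=fp,
                     tsc=tsc, provenance=provenance or {})
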