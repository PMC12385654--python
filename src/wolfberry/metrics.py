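"""Maturity indices, titratable acidity and model-fit metrics.

Harvest maturity is expressed on a 0–100 % scale by linearly interpolating a
quality indicator between its initial and final values over the ripening
season.  Two printed calibrations tie maturity to soluble solids content
(SSC) and to vitamin C; both are kept exactly as printed, including their
unbounded outputs — no silent rescaling is applied.

Fit metrics follow the conventions used for the surrogate models: RMSE in
response units, an R² whose total sum of squares is written as
``sum(M²) - (sum M)²/n`` (algebraically the classical centred SST), a
relative-to-observed MAPE and a range-normalized NRMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaturityCalibration",
    "TitrationRecord",
    "FitMetrics",
    "maturity_index",
    "maturity_from_ssc",
    "maturity_from_vc",
    "titratable_acidity",
    "rmse",
    "r_squared",
    "mape",
    "nrmse",
    "fit_metrics",
]


@dataclass(frozen=True)
class MaturityCalibration:
    """Initial and final values of one ripening indicator."""

    y_initial: float
    y_final: float
    indicator_name: str = ""

    def __post_init__(self) -> None:
        if self.y_initial == self.y_final:
            raise ValueError(
                f"degenerate calibration for {self.indicator_name!r}: "
                "initial and final values coincide"
            )


def maturity_index(y: float, cal: MaturityCalibration) -> float:
    """Maturity percent: position of ``y`` between the calibration endpoints."""
    return (y - cal.y_initial) / (cal.y_final - cal.y_initial) * 100.0


def maturity_from_ssc(y_ssc: float) -> float:
    """SSC-based maturity calibration, ``M = 3.958 - 0.258 * y_SSC``."""
    return 3.958 - 0.258 * y_ssc


def maturity_from_vc(y_vc: float) -> float:
    """Vitamin-C-based maturity calibration, ``M = 0.237 * y_Vc - 0.434``."""
    return 0.237 * y_vc - 0.434


@dataclass(frozen=True)
class TitrationRecord:
    """NaOH titration of a fruit extract, expressed as percent malic acid.

    ``acid_factor`` is the conversion factor of the titrated acid
    (0.067 g/mmol for malic acid).
    """

    extract_volume_mL: float
    naoh_molarity: float
    titre_sample_mL: float
    titre_blank_mL: float
    aliquot_mL: float
    sample_mass_g: float
    acid_factor: float = 0.067

    def __post_init__(self) -> None:
        for name in ("extract_volume_mL", "titre_sample_mL", "titre_blank_mL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.aliquot_mL <= 0:
            raise ValueError("aliquot volume must be positive")


def titratable_acidity(rec: TitrationRecord) -> float:
    """TA percent: ``V c (V1 - V0) f / (Vs m) * 100``."""
    denom = rec.aliquot_mL * rec.sample_mass_g
    if denom == 0:
        raise ZeroDivisionError("aliquot volume times sample mass is zero")
    return (
        rec.extract_volume_mL
        * rec.naoh_molarity
        * (rec.titre_sample_mL - rec.titre_blank_mL)
        * rec.acid_factor
        / denom
        * 100.0
    )


# ---------------------------------------------------------------------------
# fit metrics


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(observed, dtype=float).ravel()
    P = np.asarray(predicted, dtype=float).ravel()
    if M.shape != P.shape:
        raise ValueError(f"observed {M.shape} and predicted {P.shape} differ in length")
    if M.size == 0:
        raise ValueError("empty vectors")
    return M, P


def rmse(observed, predicted) -> float:
    """Root mean square error in response units."""
    M, P = _paired(observed, predicted)
    return float(np.sqrt(np.mean((P - M) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 - SSE / (sum M² - (sum M)²/n)``."""
    M, P = _paired(observed, predicted)
    if M.size < 2:
        raise ValueError("R² needs at least two observations")
    denom = np.sum(M**2) - np.sum(M) ** 2 / M.size
    if denom <= 0:
        raise ValueError("degenerate data: observed values are all equal")
    return float(1.0 - np.sum((M - P) ** 2) / denom)


def mape(observed, predicted) -> float:
    """Mean absolute percentage error relative to the observed values."""
    M, P = _paired(observed, predicted)
    if np.any(M == 0):
        raise ValueError("MAPE undefined: observed values contain zero")
    return float(np.mean(np.abs(P - M) / np.abs(M)) * 100.0)


def nrmse(observed, predicted) -> float:
    """RMSE normalized by the observed range (dimensionless)."""
    M, P = _paired(observed, predicted)
    if M.size < 2:
        raise ValueError("NRMSE needs at least two observations")
    span = M.max() - M.min()
    if span == 0:
        raise ValueError("NRMSE undefined: observed values are all equal")
    return rmse(M, P) / span


@dataclass(frozen=True)
class FitMetrics:
    """R², RMSE (response units), MAPE (%) and range-normalized NRMSE."""

    r2: float
    rmse: float
    mape: float
    nrmse: float


def fit_metrics(observed, predicted) -> FitMetrics:
    """All four fit metrics for one response."""
    return FitMetrics(
        r2=r_squared(observed, predicted),
        rmse=rmse(observed, predicted),
        mape=mape(observed, predicted),
        nrmse=nrmse(observed, predicted),
    )
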