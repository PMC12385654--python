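"""The packaged 40-run storage dataset and synthetic data generators.

The experimental dataset pairs 40 normalized factor settings (storage
temperature, storage time, initial maturity) with four measured quality
responses: hardness, soluble solids content (SSC, %), titratable acidity
(TA, % malic acid) and vitamin C (Vc, mg/100 g).  It ships as an immutable,
checksummed CSV fixture.

Two generators produce data with the statistical structure the analysis
assumes:

* ``generate_from_rsm`` — responses from a known quadratic response surface
  plus independent homoscedastic Gaussian noise, the workhorse for
  parameter-recovery and surrogate-validation tests;
* ``kinetic_profile`` — one-factor sweeps reproducing the stage-wise kinetic
  shapes seen in storage trials (SSC and Vc parabolic in temperature and
  peaking at 8 °C; hardness and Vc peaking on day 4 while SSC and TA peak on
  day 8; monotone or V-shaped maturity trends), interpolated through the
  reported anchor values with shape-preserving (PCHIP) splines.

Hardness carries a unit duality: the 40-run table prints newton-scale
values, while the kinetic sweeps (and the reference response surface) are on
the gram scale used for the anchor figures.  Values are kept as printed and
the unit is recorded in the dataset provenance; no automatic conversion is
performed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Literal

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .design import DesignMatrix, wolfberry_space

__all__ = [
    "RESPONSES",
    "QualityDataset",
    "TruthModel",
    "NoiseSpec",
    "load_table2",
    "generate_from_rsm",
    "kinetic_profile",
    "generate_kinetic_profiles",
    "default_kinetic_truth",
]

RESPONSES = ("hardness", "ssc", "ta", "vc")

_TABLE2_SHA256 = "f489035ed7d414203e9732e4936bdc6b07eab8d883af844490d5012d353cda41"


@dataclass(frozen=True)
class QualityDataset:
    """Paired normalized factor settings and quality measurements."""

    X: np.ndarray
    Y: np.ndarray
    response_names: tuple[str, ...] = RESPONSES
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with matching row counts")
        if X.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        if np.any(~np.isfinite(X)) or np.any(~np.isfinite(Y)):
            raise ValueError("dataset contains non-finite values")
        if np.any(X < 0.0) or np.any(X > 1.0):
            raise ValueError("normalized factors must lie in [0, 1]")
        if Y.shape[1] != len(self.response_names):
            raise ValueError("Y column count must match response names")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": self.X[:, j] for j in range(self.X.shape[1])}
        cols.update({name: self.Y[:, j] for j, name in enumerate(self.response_names)})
        return pd.DataFrame(cols)


def load_table2() -> QualityDataset:
    """The packaged 40-run optimized-Latin-hypercube storage dataset.

    Factors are already normalized to [0, 1]; responses are as printed
    (hardness column in N).  The fixture is checksummed against accidental
    modification.
    """
    raw = resources.files("wolfberry").joinpath("data/table2.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise RuntimeError(
            f"packaged 40-run dataset is corrupted (sha256 {digest[:12]}...)"
        )
    frame = pd.read_csv(StringIO(raw.decode("utf-8")))
    X = frame[["x1", "x2", "x3"]].to_numpy()
    Y = frame[list(RESPONSES)].to_numpy()
    return QualityDataset(X, Y, provenance="40-run storage experiment, as printed (hardness in N)")


# ---------------------------------------------------------------------------
# synthetic generation from a quadratic response surface


@dataclass(frozen=True)
class NoiseSpec:
    """Independent homoscedastic Gaussian noise per response."""

    sd: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd):
            raise ValueError("noise standard deviations must be non-negative")


# default anchor parameters of the kinetic truth model; see module docstring
_TIME_ANCHORS = {
    # day 0 values reflect the fruit's initial state; hardness on gram scale
    "hardness": ((0.0, 4.0, 8.0, 28.0), (1500.0, 1636.54, 1400.0, 700.0)),
    "vc": ((0.0, 4.0, 8.0, 28.0), (28.5, 35.16, 28.0, 15.0)),
    "ssc": ((0.0, 8.0, 28.0), (15.3, 23.54, 10.0)),
    "ta": ((0.0, 8.0, 28.0), (1.2, 1.65, 0.5)),
}
_MATURITY_ANCHORS = {
    # hardness and TA fall monotonically from green to red fruit
    # (-27 % and -82 % respectively); SSC rises; Vc is V-shaped
    "hardness": ((20.0, 90.0), (1500.0, 1500.0 * (1 - 0.27))),
    "ta": ((20.0, 90.0), (2.2, 2.2 * (1 - 0.82))),
    "ssc": ((20.0, 90.0), (10.0, 23.56)),
    "vc": ((20.0, 55.0, 90.0), (26.89, 16.0, 22.0)),
}


@dataclass(frozen=True)
class TruthModel:
    """Known data-generating process for synthetic studies.

    ``rsm`` mode evaluates a quadratic response surface (10 coefficients per
    response).  ``kinetic`` mode produces one-factor storage-kinetics sweeps
    through fixed anchor points.
    """

    mode: Literal["rsm", "kinetic"]
    rsm: object | None = None  # QuadraticRSM when mode == "rsm"
    temp_peak: float = 8.0
    ssc_at_temp_peak: float = 24.95
    vc_at_temp_peak: float = 28.37
    ssc_temp_curvature: float = 0.05
    vc_temp_curvature: float = 0.04
    hardness_temp_endpoints: tuple[float, float] = (2135.96, 659.85)
    ta_temp_value: float = 1.65
    time_anchors: dict = field(default_factory=lambda: dict(_TIME_ANCHORS))
    maturity_anchors: dict = field(default_factory=lambda: dict(_MATURITY_ANCHORS))

    def __post_init__(self) -> None:
        if self.mode == "rsm":
            if self.rsm is None:
                raise ValueError("rsm mode requires a fitted/encoded QuadraticRSM")
            return
        space = wolfberry_space()
        t_lo, t_hi = space.factors[0].lower, space.factors[0].upper
        if not t_lo <= self.temp_peak <= t_hi:
            raise ValueError(f"temperature peak {self.temp_peak} outside [{t_lo}, {t_hi}]")
        d_lo, d_hi = space.factors[1].lower, space.factors[1].upper
        for name, (days, values) in self.time_anchors.items():
            days = np.asarray(days, dtype=float)
            if np.any(days < d_lo) or np.any(days > d_hi):
                raise ValueError(f"time anchors for {name!r} outside [{d_lo}, {d_hi}]")
            if len(days) != len(values):
                raise ValueError(f"anchor length mismatch for {name!r}")


def default_kinetic_truth() -> TruthModel:
    """Kinetic truth model with the reported anchor values."""
    return TruthModel(mode="kinetic")


def generate_from_rsm(
    design: DesignMatrix, truth: TruthModel, noise: NoiseSpec = NoiseSpec()
) -> QualityDataset:
    """Responses from a known quadratic surface plus Gaussian noise.

    With zero noise the output reproduces the surface exactly, which is the
    basis of the parameter-recovery guarantee tested elsewhere.
    """
    if truth.mode != "rsm":
        raise ValueError("generate_from_rsm requires a truth model in 'rsm' mode")
    from .surrogates import rsm_evaluate_batch

    Y = rsm_evaluate_batch(truth.rsm, design.points)
    rng = np.random.default_rng(noise.seed)
    sd = np.asarray(noise.sd, dtype=float)
    Y = Y + rng.standard_normal(Y.shape) * sd
    return QualityDataset(
        design.points,
        Y,
        response_names=tuple(truth.rsm.response_names),
        provenance="synthetic: quadratic response surface + Gaussian noise",
        seed=noise.seed,
    )


# ---------------------------------------------------------------------------
# kinetic one-factor sweeps

# reference conditions under which each single factor was swept
_SWEEP_CONTEXT = {
    "temperature": {"time": 8.0, "maturity": 70.0},
    "time": {"temperature": 4.0, "maturity": 70.0},
    "maturity": {"temperature": 4.0, "time": 8.0},
}


def _temperature_curves(truth: TruthModel, temp: np.ndarray) -> dict[str, np.ndarray]:
    h0, h1 = truth.hardness_temp_endpoints
    t_lo, t_hi = -4.0, 24.0
    slope = (h1 - h0) / (t_hi - t_lo)
    return {
        "hardness": h0 + slope * (temp - t_lo),
        "ssc": truth.ssc_at_temp_peak - truth.ssc_temp_curvature * (temp - truth.temp_peak) ** 2,
        "ta": np.full_like(temp, truth.ta_temp_value),
        "vc": truth.vc_at_temp_peak - truth.vc_temp_curvature * (temp - truth.temp_peak) ** 2,
    }


def _anchored_curves(anchors: dict, grid: np.ndarray) -> dict[str, np.ndarray]:
    out = {}
    for name, (knots, values) in anchors.items():
        spline = PchipInterpolator(np.asarray(knots, float), np.asarray(values, float))
        out[name] = spline(grid)
    return out


def kinetic_profile(truth: TruthModel, factor: str, raw_values: np.ndarray) -> QualityDataset:
    """One-factor storage-kinetics sweep at the reference conditions.

    ``factor`` is ``temperature``, ``time`` or ``maturity``; ``raw_values``
    are in physical units.  The other two factors stay at the conditions the
    sweeps were observed under.  Profiles pass exactly through the anchor
    values (peaks included); hardness is on the gram scale.
    """
    if truth.mode != "kinetic":
        raise ValueError("kinetic_profile requires a truth model in 'kinetic' mode")
    space = wolfberry_space()
    if factor not in _SWEEP_CONTEXT:
        raise ValueError(f"unknown factor {factor!r}")
    grid = np.asarray(raw_values, dtype=float)
    if factor == "temperature":
        curves = _temperature_curves(truth, grid)
    elif factor == "time":
        curves = _anchored_curves(truth.time_anchors, grid)
    else:
        curves = _anchored_curves(truth.maturity_anchors, grid)
    raw = np.empty((grid.size, 3))
    context = _SWEEP_CONTEXT[factor]
    for j, f in enumerate(space.factors):
        raw[:, j] = grid if f.name == factor else context[f.name]
    X = (raw - space.lower) / (space.upper - space.lower)
    Y = np.column_stack([curves[name] for name in RESPONSES])
    return QualityDataset(
        X,
        Y,
        provenance=f"synthetic: kinetic {factor} sweep (hardness in g)",
    )


def generate_kinetic_profiles(
    truth: TruthModel, n_per_factor: int = 29
) -> dict[str, QualityDataset]:
    """All three one-factor sweeps on evenly spaced grids."""
    space = wolfberry_space()
    out = {}
    for f in space.factors:
        grid = np.linspace(f.lower, f.upper, n_per_factor)
        out[f.name] = kinetic_profile(truth, f.name, grid)
    return out
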