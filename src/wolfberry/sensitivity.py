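"""Factor sensitivity: main-effect curves and term-wise contribution shares.

A main-effect curve shows, for one factor, the mean predicted response at
each level of that factor averaged over the settings of the remaining
factors.  Term contributions decompose a fitted quadratic response surface
into signed percentage shares, one per non-intercept basis term: the share
of term ``t`` is ``|coef_t| / sum |coef| * 100`` on the normalized factor
scale, signed by the coefficient.  This is a coefficient-share
approximation of the Pareto-chart decomposition produced by DOE software;
the dominant terms and their signs are meaningful, the exact percentages
depend on the (undisclosed) convention such software uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .surrogates import QUADRATIC_TERMS, QuadraticRSM

__all__ = [
    "MainEffectCurve",
    "ContributionTable",
    "main_effects",
    "term_contributions",
]


@dataclass(frozen=True)
class MainEffectCurve:
    """Mean response of one factor across its levels."""

    factor_name: str
    levels: np.ndarray
    mean_response: np.ndarray  # n_levels x m

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.mean_response):
            raise ValueError("levels and responses must have equal length")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be sorted ascending")


def _background(d: int, n: int, scheme: str, seed: int) -> np.ndarray:
    """Settings of the non-varying factors to average over."""
    if d == 0:
        return np.zeros((1, 0))
    if scheme == "grid":
        # centered lattice: per-dimension midpoints, full factorial
        g = max(2, int(round(n ** (1.0 / d))))
        axes = [(np.arange(g) + 0.5) / g] * d
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])
    if scheme == "sobol":
        sampler = qmc.Sobol(d, scramble=True, seed=seed)
        return sampler.random(n)
    raise ValueError(f"unknown background scheme {scheme!r}")


def main_effects(
    predictor,
    d: int = 3,
    n_levels: int = 10,
    n_background: int = 256,
    scheme: str = "grid",
    seed: int = 0,
    factor_names: tuple[str, ...] | None = None,
) -> list[MainEffectCurve]:
    """Main-effect curves of a batch predictor on the unit cube.

    ``predictor`` maps an ``(n, d)`` array of normalized points to an
    ``(n, m)`` response array.  For each factor the remaining factors are
    averaged over a deterministic centered lattice (default) or a seeded
    scrambled Sobol set.
    """
    if n_levels < 2:
        raise ValueError("need at least two levels")
    if n_background < 1:
        raise ValueError("need at least one background point")
    if factor_names is None:
        factor_names = tuple(f"x{j + 1}" for j in range(d))
    levels = np.linspace(0.0, 1.0, n_levels)
    others = _background(d - 1, n_background, scheme, seed)
    curves = []
    for j in range(d):
        rest = [k for k in range(d) if k != j]
        means = np.empty((n_levels, 0))
        rows = []
        for level in levels:
            pts = np.empty((others.shape[0], d))
            pts[:, j] = level
            pts[:, rest] = others
            rows.append(np.mean(np.atleast_2d(predictor(pts)), axis=0))
        means = np.vstack(rows)
        curves.append(MainEffectCurve(factor_names[j], levels, means))
    return curves


@dataclass(frozen=True)
class ContributionTable:
    """Signed percentage share of each quadratic term, per response."""

    # per response: list of (term, percent, sign)
    contributions: dict[str, list[tuple[str, float, int]]]

    def for_response(self, name: str) -> list[tuple[str, float, int]]:
        return self.contributions[name]


def term_contributions(rsm: QuadraticRSM) -> ContributionTable:
    """Coefficient-share contribution of each non-intercept term.

    Shares are non-negative, sum to 100 per response, and carry the sign of
    the underlying coefficient.  Undefined (an error) when every
    non-intercept coefficient of a response is zero.
    """
    terms = QUADRATIC_TERMS[1:]
    table: dict[str, list[tuple[str, float, int]]] = {}
    for i, name in enumerate(rsm.response_names):
        coefs = rsm.coefficients[i, 1:]
        total = np.sum(np.abs(coefs))
        if total == 0:
            raise ValueError(
                f"contributions undefined for {name!r}: all non-intercept "
                "coefficients are zero"
            )
        table[name] = [
            (term, float(abs(c) / total * 100.0), int(np.sign(c)) if c != 0 else 1)
            for term, c in zip(terms, coefs)
        ]
    return ContributionTable(table)
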