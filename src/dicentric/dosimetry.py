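"""Cytogenetic dose estimation from dicentric counts.

The dicentric yield per cell follows a linear-quadratic dose-effect curve
Y = C + alpha*D + beta*D**2.  Given X dicentrics observed in M scored
metaphases, the yield Y = X/M is inverted through the curve to an absorbed
dose D (Gy).  Uncertainty on the count is expressed through the classical
tabulated Poisson 95% confidence limits (X_L, X_U) on an observed count X;
the limits are divided by M and pushed through the same curve inversion to
give a dose confidence interval [D_L, D_U] (Merkle's simple construction,
ignoring calibration-curve error).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseCurve",
    "DoseEstimate",
    "DEFAULT_CURVE",
    "load_poisson_table",
    "poisson_limits",
    "yield_from_counts",
    "dose_from_yield",
    "confidence_interval",
    "pass_rate",
    "simulate_counts",
]

POISSON_TABLE_MAX_X = 159


@dataclass(frozen=True)
class DoseCurve:
    """Linear-quadratic dose-effect curve Y = C + alpha*D + beta*D^2.

    Units: C in dicentrics/cell, alpha in Gy^-1, beta in Gy^-2.
    """

    C: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.alpha < 0 or self.C < 0:
            raise ValueError("C and alpha must be non-negative")

    def __call__(self, dose_gy: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(dose_gy, dtype=float)
        y = self.C + self.alpha * d + self.beta * d**2
        return float(y) if np.isscalar(dose_gy) or y.ndim == 0 else y


#: Gamma-ray calibration curve for dicentric yield (dicentrics/cell vs Gy).
DEFAULT_CURVE = DoseCurve(C=0.000105, alpha=0.0186, beta=0.0217)


@dataclass(frozen=True)
class DoseEstimate:
    """A dose estimate with 95% confidence limits.

    ``below_background`` flags a yield under the curve intercept C, for
    which the dose is clamped to 0.
    """

    X: int
    M: int
    Y: float
    D: float
    Y_L: float
    Y_U: float
    D_L: float
    D_U: float
    below_background: bool = False

    def as_dict(self) -> dict:
        return {
            "X": self.X,
            "M": self.M,
            "Y": self.Y,
            "D": self.D,
            "Y_L": self.Y_L,
            "Y_U": self.Y_U,
            "D_L": self.D_L,
            "D_U": self.D_U,
            "below_background": self.below_background,
        }


_TABLE_CACHE: pd.DataFrame | None = None


def load_poisson_table() -> pd.DataFrame:
    """Return the bundled Poisson 95% confidence-limit table.

    Columns X (0..159), X_L, X_U. The values are the classical tabulated
    limits used in cytogenetic dosimetry, shipped verbatim as a data asset;
    they are treated as canonical rather than recomputed.
    """
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        with resources.files("dicentric.data").joinpath(
            "poisson_limits_table1.csv"
        ).open() as fh:
            _TABLE_CACHE = pd.read_csv(fh)
    return _TABLE_CACHE


def poisson_limits(X: int, allow_chi2_fallback: bool = False) -> tuple[float, float]:
    """Look up the tabulated Poisson 95% limits (X_L, X_U) for a count X.

    Parameters
    ----------
    X : observed dicentric count, 0 <= X <= 159 for table lookup.
    allow_chi2_fallback : if True, counts beyond the table are handled with
        exact chi-square Poisson limits instead of raising. These values are
        not from the bundled table.
    """
    if X < 0:
        raise ValueError("count must be non-negative")
    if X > POISSON_TABLE_MAX_X:
        if not allow_chi2_fallback:
            raise ValueError(
                f"X={X} exceeds the bundled table range 0..{POISSON_TABLE_MAX_X}; "
                "pass allow_chi2_fallback=True for exact chi-square limits"
            )
        from scipy.stats import chi2

        lo = 0.5 * chi2.ppf(0.025, 2 * X)
        hi = 0.5 * chi2.ppf(0.975, 2 * X + 2)
        return float(lo), float(hi)
    tab = load_poisson_table()
    row = tab.iloc[int(X)]
    return float(row.X_L), float(row.X_U)


def yield_from_counts(X: int, M: int) -> float:
    """Dicentric yield per cell, Y = X/M."""
    if M <= 0:
        raise ValueError("number of cells M must be positive")
    if X < 0:
        raise ValueError("count must be non-negative")
    return X / M


def dose_from_yield(Y: float, curve: DoseCurve = DEFAULT_CURVE) -> float:
    """Invert the linear-quadratic curve: the positive root of
    beta*D^2 + alpha*D + (C - Y) = 0.

    Yields below the intercept C map to dose 0 (below background); use
    :func:`confidence_interval` to carry the flag.
    """
    if Y < 0:
        raise ValueError("yield must be non-negative")
    if Y < curve.C:
        return 0.0
    disc = curve.alpha**2 + 4.0 * curve.beta * (Y - curve.C)
    return (-curve.alpha + math.sqrt(disc)) / (2.0 * curve.beta)


def confidence_interval(
    X: int,
    M: int,
    curve: DoseCurve = DEFAULT_CURVE,
    allow_chi2_fallback: bool = False,
) -> DoseEstimate:
    """Dose estimate with 95% confidence limits for X dicentrics in M cells.

    The count limits (X_L, X_U) are taken from the Poisson table, converted
    to yield limits Y_L = X_L/M and Y_U = X_U/M, and each is inverted through
    the calibration curve. Calibration-curve error is ignored.
    """
    Y = yield_from_counts(X, M)
    X_L, X_U = poisson_limits(X, allow_chi2_fallback=allow_chi2_fallback)
    Y_L, Y_U = X_L / M, X_U / M
    return DoseEstimate(
        X=int(X),
        M=int(M),
        Y=Y,
        D=dose_from_yield(Y, curve),
        Y_L=Y_L,
        Y_U=Y_U,
        D_L=dose_from_yield(Y_L, curve),
        D_U=dose_from_yield(Y_U, curve),
        below_background=Y < curve.C,
    )


def pass_rate(
    estimates: Sequence[tuple[float, float]], tol: float = 0.20
) -> float:
    """Fraction of (D_est, D_true) pairs with relative deviation <= tol.

    A dose estimate within 20% of the true delivered dose is the
    conventional "qualified" criterion.
    """
    if len(estimates) == 0:
        raise ValueError("empty estimate list")
    ok = 0
    for d_est, d_true in estimates:
        if d_true <= 0:
            raise ValueError("true dose must be positive")
        if abs(d_est - d_true) / d_true <= tol:
            ok += 1
    return ok / len(estimates)


def simulate_counts(
    D_true: float,
    curve: DoseCurve = DEFAULT_CURVE,
    M: int = 500,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Poisson replicates of the dicentric count at a true dose.

    X ~ Poisson(M * Y(D_true)) per replicate; reproducible by seed.
    """
    if D_true < 0:
        raise ValueError("dose must be non-negative")
    rng = np.random.default_rng(seed)
    lam = M * float(curve(D_true))
    return rng.poisson(lam, size=n_reps)
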