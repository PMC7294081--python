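"""T1 inversion-recovery and T2 CPMG-decay fitting.

Inversion recovery: ``I(t) = I_inf * (1 - 2 f exp(-t/T1))`` with the
inversion efficiency ``f`` a free parameter in [0.5, 1] (f = 1 is perfect
inversion, f = 0.5 the saturation-recovery limit).  CPMG decay:
``I(t) = I0 * exp(-t/T2)`` with a log-linear initialization refined by
least squares.  Weighted least squares is used whenever per-point
uncertainties are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RelaxationSeries",
    "RelaxationFit",
    "InversionRecoveryModel",
    "CpmgDecayModel",
    "fit_inversion_recovery",
    "fit_cpmg_decay",
    "pool_replicates",
    "ModelMismatchError",
]

#: delay grid of the inversion-recovery experiment (s)
T1_DELAYS = (0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

#: spin-echo evolution time range of the CPMG decay experiment (s), 8 points
T2_TIME_RANGE = (0.5e-3, 128e-3)
T2_N_POINTS = 8

#: fitted rates below this (relative to 1/t_max) are flagged as non-relaxing
_NONRELAXING_REL = 1e-3


class ModelMismatchError(ValueError):
    """The series shape contradicts the requested relaxation model."""


@dataclass
class RelaxationSeries:
    """An intensity-versus-time relaxation series.

    ``kind`` is ``"inversion_recovery"`` or ``"cpmg_decay"``; times are
    strictly increasing.  Duplicate acquisitions carry distinct
    ``replicate_id`` values but share a time grid.
    """

    kind: str
    times: np.ndarray
    intensities: np.ndarray
    sigma: np.ndarray | None = None
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("inversion_recovery", "cpmg_decay"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ValueError("sigma must match times in length")

    def to_frame(self) -> pd.DataFrame:
        sig = self.sigma if self.sigma is not None else np.full_like(self.times, np.nan)
        return pd.DataFrame(
            {
                "kind": self.kind,
                "replicate_id": self.replicate_id,
                "time_s": self.times,
                "intensity": self.intensities,
                "sigma": sig,
            }
        )


def write_series_csv(series: Sequence[RelaxationSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        Path(path), index=False
    )


def read_series_csv(path) -> list[RelaxationSeries]:
    df = pd.read_csv(Path(path))
    out = []
    for (kind, rep), grp in df.groupby(["kind", "replicate_id"], sort=True):
        grp = grp.sort_values("time_s")
        sig = grp["sigma"].to_numpy()
        out.append(
            RelaxationSeries(
                kind=kind,
                times=grp["time_s"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                sigma=None if np.all(np.isnan(sig)) else sig,
                replicate_id=int(rep),
            )
        )
    return out


def pool_replicates(series: Sequence[RelaxationSeries]) -> RelaxationSeries:
    """Average duplicate series point-wise; propagated sigma = sigma/sqrt(n).

    All series must share kind and time grid.  When no sigma is given, the
    pooled sigma defaults to the common per-point uncertainty that makes the
    pooled weighted fit equivalent to the pooled unweighted fit (i.e. all
    equal, scaled by 1/sqrt(n)).
    """
    if not series:
        raise ValueError("no series to pool")
    kind = series[0].kind
    t0 = series[0].times
    for s in series[1:]:
        if s.kind != kind or not np.array_equal(s.times, t0):
            raise ValueError("replicates must share kind and time grid")
    stack = np.vstack([s.intensities for s in series])
    mean = stack.mean(axis=0)
    n = len(series)
    if all(s.sigma is not None for s in series):
        sig = np.sqrt(np.mean(np.vstack([s.sigma**2 for s in series]), axis=0) / n)
    else:
        sig = np.full_like(t0, 1.0 / np.sqrt(n))
    return RelaxationSeries(kind=kind, times=t0, intensities=mean, sigma=sig)


@dataclass
class RelaxationFit:
    """Result of a mono-exponential relaxation fit."""

    kind: str
    rate: float  # 1/T1 or 1/T2, s^-1
    rate_stderr: float
    amplitude: float  # I_inf (IR) or I0 (CPMG decay)
    amplitude_stderr: float
    chi2: float
    dof: int
    inv_efficiency: float | None = None
    inv_efficiency_stderr: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def time_constant(self) -> float:
        """T1 or T2 in seconds."""
        return 1.0 / self.rate if self.rate > 0 else np.inf


def _stderr_from_jac(res, n_points: int, n_params: int, weighted: bool) -> np.ndarray:
    """Parameter standard errors from the least-squares Jacobian.

    With known per-point sigmas the residuals are already whitened and the
    covariance is (J^T J)^-1; otherwise it is scaled by the reduced chi^2.
    """
    dof = n_points - n_params
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    if not weighted and dof > 0:
        cov = cov * (2.0 * res.cost / dof)
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


class InversionRecoveryModel(BaseEstimator, RegressorMixin):
    """T1 inversion-recovery fit, ``I(t) = I_inf (1 - 2 f exp(-R1 t))``.

    ``fit(X, y, sample_weight=None)`` with ``X`` the delays (s) and ``y``
    the intensities; ``sample_weight`` is interpreted as 1/sigma^2 when it
    comes from per-point sigmas.  Fitted attributes carry a trailing
    underscore (``rate_``, ``t1_``, ``i_inf_``, ``inv_efficiency_``, ...).
    """

    def __init__(self, f_init: float = 0.98, f_bounds: tuple[float, float] = (0.5, 1.0)):
        self.f_init = f_init
        self.f_bounds = f_bounds

    def fit(self, X, y, sample_weight=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        inten = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 4:
            raise ValueError("inversion recovery needs at least 4 points")
        if np.all(np.diff(inten) <= 0) and inten[0] > inten[-1]:
            raise ModelMismatchError(
                "series decreases monotonically; not an inversion recovery"
            )
        w = np.ones_like(t) if sample_weight is None else np.sqrt(
            np.asarray(sample_weight, dtype=float).reshape(-1)
        )

        def resid(theta):
            i_inf, f, r1 = theta
            return w * (i_inf * (1.0 - 2.0 * f * np.exp(-r1 * t)) - inten)

        i_inf0 = inten[-1] if inten[-1] != 0 else float(np.max(np.abs(inten)))
        # crude T1 guess from the zero crossing (t_null ~ T1 ln 2 for f=1)
        sign_change = np.nonzero(np.diff(np.sign(inten)))[0]
        r1_0 = np.log(2.0) / t[sign_change[0] + 1] if sign_change.size else 1.0 / t[t.size // 2]
        theta0 = np.array([i_inf0, self.f_init, max(r1_0, 1e-3)])
        lo = np.array([-np.inf, self.f_bounds[0], 1e-9])
        hi = np.array([np.inf, self.f_bounds[1], np.inf])
        res = least_squares(
            resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        stderr = _stderr_from_jac(res, t.size, 3, weighted=sample_weight is not None)
        self.i_inf_, self.inv_efficiency_, self.rate_ = (float(v) for v in res.x)
        self.t1_ = 1.0 / self.rate_
        self.stderr_ = {"i_inf": stderr[0], "f": stderr[1], "rate": stderr[2]}
        self.chi2_ = float(2.0 * res.cost)
        self.dof_ = t.size - 3
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.i_inf_ * (1.0 - 2.0 * self.inv_efficiency_ * np.exp(-self.rate_ * t))

    @property
    def null_time_(self) -> float:
        """Zero-crossing time T1*ln(2f); 0 when f <= 0.5 (no inversion)."""
        arg = 2.0 * self.inv_efficiency_
        return self.t1_ * np.log(arg) if arg > 1.0 else 0.0


class CpmgDecayModel(BaseEstimator, RegressorMixin):
    """T2 exponential-decay fit, ``I(t) = I0 exp(-R2 t)``.

    Log-linear regression provides the starting point; nonlinear least
    squares refines it.  A fitted rate indistinguishable from zero is
    flagged ``non-relaxing``.
    """

    def __init__(self):
        pass

    def fit(self, X, y, sample_weight=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        inten = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 3:
            raise ValueError("CPMG decay needs at least 3 points")
        if np.any(inten <= 0):
            raise ValueError("CPMG decay intensities must be positive")
        w = np.ones_like(t) if sample_weight is None else np.sqrt(
            np.asarray(sample_weight, dtype=float).reshape(-1)
        )
        # log-linear initialization
        slope, intercept = np.polyfit(t, np.log(inten), 1)
        theta0 = np.array([np.exp(intercept), max(-slope, 0.0)])

        def resid(theta):
            i0, r2 = theta
            return w * (i0 * np.exp(-r2 * t) - inten)

        lo = np.array([1e-12, 0.0])
        hi = np.array([np.inf, np.inf])
        res = least_squares(
            resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        stderr = _stderr_from_jac(res, t.size, 2, weighted=sample_weight is not None)
        self.i0_, self.rate_ = (float(v) for v in res.x)
        self.t2_ = 1.0 / self.rate_ if self.rate_ > 0 else np.inf
        self.stderr_ = {"i0": stderr[0], "rate": stderr[1]}
        self.chi2_ = float(2.0 * res.cost)
        self.dof_ = t.size - 2
        self.flags_ = (
            ("non-relaxing",)
            if self.rate_ < _NONRELAXING_REL / t[-1]
            else ()
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.i0_ * np.exp(-self.rate_ * t)


def _weights(series: RelaxationSeries):
    if series.sigma is None:
        return None
    return 1.0 / series.sigma**2


def fit_inversion_recovery(series: RelaxationSeries) -> RelaxationFit:
    """Fit a T1 inversion-recovery series; see :class:`InversionRecoveryModel`."""
    if series.kind != "inversion_recovery":
        raise ValueError(f"expected an inversion_recovery series, got {series.kind!r}")
    m = InversionRecoveryModel().fit(
        series.times, series.intensities, sample_weight=_weights(series)
    )
    return RelaxationFit(
        kind=series.kind,
        rate=m.rate_,
        rate_stderr=m.stderr_["rate"],
        amplitude=m.i_inf_,
        amplitude_stderr=m.stderr_["i_inf"],
        chi2=m.chi2_,
        dof=m.dof_,
        inv_efficiency=m.inv_efficiency_,
        inv_efficiency_stderr=m.stderr_["f"],
    )


def fit_cpmg_decay(series: RelaxationSeries) -> RelaxationFit:
    """Fit a T2 CPMG decay series; see :class:`CpmgDecayModel`."""
    if series.kind != "cpmg_decay":
        raise ValueError(f"expected a cpmg_decay series, got {series.kind!r}")
    m = CpmgDecayModel().fit(
        series.times, series.intensities, sample_weight=_weights(series)
    )
    return RelaxationFit(
        kind=series.kind,
        rate=m.rate_,
        rate_stderr=m.stderr_["rate"],
        amplitude=m.i0_,
        amplitude_stderr=m.stderr_["i0"],
        chi2=m.chi2_,
        dof=m.dof_,
        flags=m.flags_,
    )
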