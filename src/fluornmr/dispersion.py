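"""Global multi-field CPMG relaxation-dispersion fitting (fast exchange).

All curves for one residue are fit jointly to the Luz–Meiboom model with a
single exchange rate ``kex`` shared across fields, one plateau rate ``R2_0``
per field, and one exchange amplitude ``Phi_ex`` quoted at a reference field
and tied to the other fields by the squared field ratio (``delta_omega`` is
linear in the static field).  Because ``Phi_ex = pA pB delta_omega^2`` is
the only identifiable combination in fast exchange, the individual
populations and shift difference are never reported.

The optimizer is multistart trust-region least squares over a log-spaced
``kex`` grid; chi-square ties are broken toward the smaller ``kex``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exchange import (
    DispersionCurve,
    FastExchangeFitParams,
    read_dispersion_csv,
    write_dispersion_csv,
)

__all__ = [
    "GlobalFitResult",
    "ProfileResult",
    "FastExchangeDispersionModel",
    "fit_dispersion_global",
    "profile_uncertainty",
    "DispersionCurve",
    "read_dispersion_csv",
    "write_dispersion_csv",
]

#: default multistart grid for kex (s^-1): log-spaced over this range
KEX_GRID = (1e2, 1e6)
KEX_N_STARTS = 9

#: chi-square ties within this are broken toward smaller kex
_TIE_TOL = 1e-6


@dataclass
class GlobalFitResult:
    """Outcome of a global dispersion fit."""

    params: FastExchangeFitParams
    stderr: dict[str, float]
    chi2: float
    chi2_reduced: float
    dof: int
    n_restarts: int
    converged: bool
    identifiability_flags: tuple[str, ...] = field(default_factory=tuple)
    label: str = ""

    def to_report(self) -> dict:
        """Flat JSON-serializable summary."""
        return {
            "label": self.label,
            "kex_s1": self.params.kex,
            "phi_ex_ref_s2": self.params.phi_ex_ref,
            "ref_field_mhz": self.params.ref_field_mhz,
            "r20_by_field_s1": {f"{f:.3f}": r for f, r in sorted(self.params.r20_by_field.items())},
            "stderr": dict(self.stderr),
            "chi2": self.chi2,
            "chi2_reduced": self.chi2_reduced,
            "dof": self.dof,
            "converged": self.converged,
            "identifiability_flags": list(self.identifiability_flags),
        }


@dataclass
class ProfileResult:
    """1-D chi-square profile of one fit parameter."""

    param: str
    values: np.ndarray
    chi2: np.ndarray
    optimum: float
    ci_low: float
    ci_high: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def _stack_curves(curves: Sequence[DispersionCurve]):
    fields, nus, r2s, sigs = [], [], [], []
    for c in curves:
        fields.append(np.full_like(c.nu_cpmg, c.field_mhz))
        nus.append(c.nu_cpmg)
        r2s.append(c.r2eff)
        sigs.append(
            c.sigma if c.sigma is not None else np.full_like(c.nu_cpmg, np.nan)
        )
    X = np.column_stack([np.concatenate(fields), np.concatenate(nus)])
    y = np.concatenate(r2s)
    sig = np.concatenate(sigs)
    return X, y, (None if np.any(np.isnan(sig)) else sig)


class FastExchangeDispersionModel(BaseEstimator, RegressorMixin):
    """Global fast-exchange (Luz–Meiboom) dispersion fit.

    sklearn-style estimator.  ``X`` has two columns ``(field_mhz,
    nu_cpmg_hz)`` and ``y`` is R2eff (s^-1); ``sample_weight`` is 1/sigma^2.
    The free parameters are ``kex`` (shared), ``Phi_ex`` at
    ``ref_field_mhz`` (default: the lowest field present) and one ``R2_0``
    per field.

    Fitted attributes: ``kex_``, ``phi_ex_ref_``, ``r20_by_field_``,
    ``ref_field_mhz_``, ``stderr_``, ``chi2_``, ``chi2_reduced_``, ``dof_``,
    ``converged_``, ``identifiability_flags_``, ``n_restarts_``, ``params_``.
    """

    def __init__(
        self,
        ref_field_mhz: float | None = None,
        kex_grid: tuple[float, float] = KEX_GRID,
        n_starts: int = KEX_N_STARTS,
    ):
        self.ref_field_mhz = ref_field_mhz
        self.kex_grid = kex_grid
        self.n_starts = n_starts

    # parameter vector: [kex, phi_ex_ref, r20_field1, r20_field2, ...]
    def _predict_theta(self, theta, fields_arr, nu_arr, field_list, ref):
        kex, phi_ref = theta[0], theta[1]
        out = np.empty_like(nu_arr)
        x = kex / (4.0 * nu_arr)
        disp = (phi_ref / kex) * (1.0 - np.tanh(x) / x)
        for j, f in enumerate(field_list):
            m = fields_arr == f
            out[m] = theta[2 + j] + disp[m] * (f / ref) ** 2
        return out

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: field_mhz, nu_cpmg_hz")
        if np.any(X[:, 0] <= 0) or np.any(X[:, 1] <= 0):
            raise ValueError("fields and CPMG frequencies must be positive")
        fields_arr, nu_arr = X[:, 0], X[:, 1]
        field_list = sorted(set(fields_arr.tolist()))
        n_params = 2 + len(field_list)
        if y.size <= n_params:
            raise ValueError(
                f"{y.size} points cannot constrain {n_params} parameters"
            )
        for f in field_list:
            if np.sum(fields_arr == f) < 4:
                raise ValueError("each curve needs at least 4 points")
        ref = self.ref_field_mhz if self.ref_field_mhz is not None else field_list[0]
        w = (
            np.ones_like(y)
            if sample_weight is None
            else np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
        )

        def resid(theta):
            return w * (self._predict_theta(theta, fields_arr, nu_arr, field_list, ref) - y)

        r20_0 = [max(float(np.min(y[fields_arr == f])), 1e-3) for f in field_list]
        # amplitude guess at the reference field
        m_ref = fields_arr == field_list[0]
        amp0 = max(float(np.max(y[m_ref]) - np.min(y[m_ref])), 1e-6)
        lo = np.array([1e-3, 0.0] + [0.0] * len(field_list))
        hi = np.full(n_params, np.inf)
        best = None
        best_kex = np.inf
        starts = np.geomspace(self.kex_grid[0], self.kex_grid[1], self.n_starts)
        for kex0 in starts:
            theta0 = np.array([kex0, amp0 * kex0 * (field_list[0] / ref) ** -2] + r20_0)
            res = least_squares(
                resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
            cost = 2.0 * res.cost
            if (
                best is None
                or cost < 2.0 * best.cost - _TIE_TOL
                or (abs(cost - 2.0 * best.cost) <= _TIE_TOL and res.x[0] < best_kex)
            ):
                best = res
                best_kex = res.x[0]
        theta = best.x
        self.ref_field_mhz_ = float(ref)
        self.kex_ = float(theta[0])
        self.phi_ex_ref_ = float(theta[1])
        self.r20_by_field_ = {f: float(theta[2 + j]) for j, f in enumerate(field_list)}
        self.chi2_ = float(2.0 * best.cost)
        self.dof_ = y.size - n_params
        self.chi2_reduced_ = self.chi2_ / self.dof_ if self.dof_ > 0 else np.nan
        self.converged_ = bool(best.status > 0)
        self.n_restarts_ = len(starts)

        weighted = sample_weight is not None
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj)
            singular = not np.all(np.isfinite(cov))
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj)
            singular = True
        if not weighted and self.dof_ > 0:
            cov = cov * self.chi2_reduced_
        err = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        self.stderr_ = {"kex": float(err[0]), "phi_ex_ref": float(err[1])}
        for j, f in enumerate(field_list):
            self.stderr_[f"r20_{f:.3f}"] = float(err[2 + j])

        flags: list[str] = []
        # dispersion amplitude at the reference field vs the noise scale
        amp_fit = self.phi_ex_ref_ / self.kex_ * (field_list[0] / ref) ** 2
        if weighted:
            med_sigma = float(np.median(1.0 / w**2) ** 0.5)
        else:
            med_sigma = float(np.sqrt(max(self.chi2_reduced_, 0.0))) if self.dof_ > 0 else 0.0
        floor = 1e-6 * float(np.median(list(self.r20_by_field_.values())))
        if amp_fit < max(2.0 * med_sigma, floor):
            flags.append("no dispersion")
            self.stderr_["kex"] = np.inf
        if singular:
            flags.append("singular covariance")
        self.identifiability_flags_ = tuple(flags)
        try:
            self.params_ = FastExchangeFitParams(
                kex=self.kex_,
                phi_ex_ref=max(self.phi_ex_ref_, 0.0),
                r20_by_field=self.r20_by_field_,
                ref_field_mhz=self.ref_field_mhz_,
            )
        except ValueError:  # degenerate optimum pinned at a bound
            self.params_ = None
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        fields_arr, nu_arr = X[:, 0], X[:, 1]
        field_list = sorted(self.r20_by_field_)
        theta = np.array(
            [self.kex_, self.phi_ex_ref_]
            + [self.r20_by_field_[f] for f in field_list]
        )
        return self._predict_theta(theta, fields_arr, nu_arr, field_list, self.ref_field_mhz_)


def fit_dispersion_global(
    curves: Sequence[DispersionCurve],
    ref_field_mhz: float | None = None,
) -> GlobalFitResult:
    """Fit all curves of one residue jointly to the fast-exchange model.

    Weighted by 1/sigma^2 whenever every curve carries uncertainties,
    unweighted otherwise.  All curves must share a label (one residue).
    """
    if not curves:
        raise ValueError("no curves to fit")
    labels = {c.label for c in curves}
    if len(labels) > 1:
        raise ValueError(f"curves carry different residue labels: {sorted(labels)}")
    X, y, sig = _stack_curves(curves)
    weight = None if sig is None else 1.0 / sig**2
    m = FastExchangeDispersionModel(ref_field_mhz=ref_field_mhz).fit(X, y, sample_weight=weight)
    if m.params_ is None:
        raise RuntimeError("fit collapsed onto a parameter bound; no valid parameter set")
    return GlobalFitResult(
        params=m.params_,
        stderr=m.stderr_,
        chi2=m.chi2_,
        chi2_reduced=m.chi2_reduced_,
        dof=m.dof_,
        n_restarts=m.n_restarts_,
        converged=m.converged_,
        identifiability_flags=m.identifiability_flags_,
        label=labels.pop(),
    )


_PROFILE_PARAMS = ("kex", "phi_ex_ref")


def profile_uncertainty(
    result: GlobalFitResult,
    curves: Sequence[DispersionCurve],
    param: str = "kex",
    n_grid: int = 21,
    span_stderr: float = 4.0,
) -> ProfileResult:
    """1-D chi-square profile of ``param`` with the others re-optimized.

    The 68.3% confidence interval is read off at ``delta chi^2 = 1`` by
    linear interpolation.  An interval endpoint outside the scanned grid is
    reported as +/- inf with an ``unbounded`` flag.
    """
    if not result.converged:
        raise ValueError("refusing to profile a non-converged fit")
    if param not in _PROFILE_PARAMS:
        raise ValueError(f"param must be one of {_PROFILE_PARAMS}")
    X, y, sig = _stack_curves(curves)
    w = np.ones_like(y) if sig is None else 1.0 / sig
    fields_arr, nu_arr = X[:, 0], X[:, 1]
    field_list = sorted(set(fields_arr.tolist()))
    ref = result.params.ref_field_mhz
    p = result.params
    opt = {"kex": p.kex, "phi_ex_ref": p.phi_ex_ref}[param]
    err = result.stderr.get(param, 0.0)
    if not np.isfinite(err) or err <= 0:
        err = 0.5 * abs(opt) if opt != 0 else 1.0
    span = span_stderr * err
    grid = np.linspace(max(opt - span, 1e-6 if param == "kex" else 0.0), opt + span, n_grid)

    r20_opt = [p.r20_by_field[f] for f in field_list]

    def chi2_at(value: float) -> float:
        def resid(theta_free):
            if param == "kex":
                kex, phi = value, theta_free[0]
                r20 = theta_free[1:]
            else:
                kex, phi = theta_free[0], value
                r20 = theta_free[1:]
            x = kex / (4.0 * nu_arr)
            disp = (phi / kex) * (1.0 - np.tanh(x) / x)
            out = np.empty_like(nu_arr)
            for j, f in enumerate(field_list):
                mask = fields_arr == f
                out[mask] = r20[j] + disp[mask] * (f / ref) ** 2
            return w * (out - y)

        free0 = np.array(
            ([p.phi_ex_ref] if param == "kex" else [p.kex]) + r20_opt
        )
        lo = np.zeros_like(free0)
        if param == "phi_ex_ref":
            lo[0] = 1e-3
        res = least_squares(resid, np.clip(free0, lo, np.inf), bounds=(lo, np.inf),
                            xtol=1e-13, ftol=1e-13, gtol=1e-13)
        return float(2.0 * res.cost)

    chi2 = np.array([chi2_at(v) for v in grid])
    chi2_min = min(float(np.min(chi2)), result.chi2)
    target = chi2_min + 1.0
    flags: list[str] = []

    def crossing(side: int) -> float:
        # side=-1: scan left of the optimum; side=+1: right
        order = np.argsort(grid) if side > 0 else np.argsort(grid)[::-1]
        g, c = grid[order], chi2[order]
        started = g[0]
        past_opt = (g >= opt) if side > 0 else (g <= opt)
        for k in range(1, len(g)):
            if past_opt[k] and c[k - 1] < target <= c[k]:
                return float(
                    g[k - 1] + (target - c[k - 1]) * (g[k] - g[k - 1]) / (c[k] - c[k - 1])
                )
        flags.append("unbounded")
        return -np.inf if side < 0 else np.inf

    ci_low = crossing(-1)
    ci_high = crossing(+1)
    return ProfileResult(
        param=param,
        values=grid,
        chi2=chi2,
        optimum=opt,
        ci_low=ci_low,
        ci_high=ci_high,
        flags=tuple(dict.fromkeys(flags)),
    )


def plot_dispersion_fit(result: GlobalFitResult, curves: Sequence[DispersionCurve], path) -> None:
    """Save a data-plus-fit figure, one panel per field (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .exchange import luz_meiboom_r2

    fig, axes = plt.subplots(1, len(curves), figsize=(4.5 * len(curves), 3.5), squeeze=False)
    for ax, c in zip(axes[0], sorted(curves, key=lambda c: c.field_mhz)):
        ax.errorbar(c.nu_cpmg, c.r2eff, yerr=c.sigma, fmt="o", ms=4, label="data")
        nu = np.geomspace(c.nu_cpmg[0], c.nu_cpmg[-1], 200)
        ax.plot(nu, luz_meiboom_r2(result.params, nu, c.field_mhz), "-", label="fit")
        ax.set_xscale("log")
        ax.set_xlabel(r"$\nu_{CPMG}$ (Hz)")
        ax.set_ylabel(r"$R_2^{eff}$ (s$^{-1}$)")
        ax.set_title(f"{result.label} @ {c.field_mhz:.3f} MHz")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
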