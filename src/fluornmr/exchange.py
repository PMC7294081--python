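"""Two-site chemical exchange under CPMG: closed form and numerical models.

A nucleus hopping between two conformations A and B (populations ``pA``,
``pB = 1 - pA``, exchange rate ``kex = kAB + kBA``, chemical-shift
difference ``delta_omega``) shows an effective transverse relaxation rate
``R2eff`` that depends on the CPMG pulsing frequency.  In the fast-exchange
limit (``kex >> delta_omega``) the dispersion collapses to the Luz–Meiboom
form

    R2eff(nu) = R2_0 + (Phi_ex / kex) * [1 - (4 nu / kex) * tanh(kex / (4 nu))]

where ``Phi_ex = pA * pB * delta_omega**2`` is the only combination of
populations and shift difference that remains identifiable, and scales with
the square of the static field.  The numerical route propagates the two
transverse coherences through explicit tau_cp - 180 - tau_cp blocks with the
Bloch–McConnell evolution matrix and serves as the independent oracle for
the closed form.

CPMG frequency convention
-------------------------
``nu_cpmg = 1 / (4 * tau_cp)`` where ``2 * tau_cp`` is the delay between
consecutive 180-degree pulses.  All CPMG frequencies in this package follow
this convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "ExchangeSystem",
    "FastExchangeFitParams",
    "CpmgSchedule",
    "DispersionCurve",
    "luz_meiboom_r2",
    "bloch_mcconnell_r2eff",
    "r2eff_from_intensities",
    "cpmg_intensity",
]

#: relative tolerance used when matching a field strength against a table key
_FIELD_RTOL = 1e-6

#: I/I0 below this is treated as numerical underflow and the point is flagged
_UNDERFLOW = 1e-12


@dataclass(frozen=True)
class ExchangeSystem:
    """Full two-site exchange parameter set (drives the numerical oracle).

    Parameters
    ----------
    pa : float
        Population fraction of state A, in [0, 1].
    kex : float
        Exchange rate ``kAB + kBA`` in s^-1.
    delta_omega_ppm : float
        Chemical-shift difference between the states, ppm.
    r2a0, r2b0 : float
        Intrinsic (exchange-free) transverse relaxation rates, s^-1.
    field_mhz : float
        19F Larmor frequency in MHz; converts ppm to rad/s.
    """

    pa: float
    kex: float
    delta_omega_ppm: float
    r2a0: float
    r2b0: float
    field_mhz: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError(f"pa must lie in [0, 1], got {self.pa}")
        if self.kex < 0:
            raise ValueError("kex must be non-negative")
        if self.r2a0 <= 0 or self.r2b0 <= 0:
            raise ValueError("intrinsic R2 rates must be positive")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")

    @property
    def pb(self) -> float:
        return 1.0 - self.pa

    @property
    def delta_omega_rad_s(self) -> float:
        """Shift difference in rad/s: 2*pi*field_mhz*delta_omega_ppm."""
        return 2.0 * np.pi * self.field_mhz * self.delta_omega_ppm

    @property
    def phi_ex(self) -> float:
        """pA*pB*delta_omega^2 in s^-2 at this field."""
        return self.pa * self.pb * self.delta_omega_rad_s**2


@dataclass(frozen=True)
class FastExchangeFitParams:
    """Identifiable parameters of the fast-exchange (Luz–Meiboom) model.

    ``phi_ex_ref`` is quoted at ``ref_field_mhz``; at any other field it is
    scaled by the squared field ratio, since ``delta_omega`` is linear in
    the static field.
    """

    kex: float
    phi_ex_ref: float
    r20_by_field: Mapping[float, float]
    ref_field_mhz: float = 564.686

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if self.phi_ex_ref < 0:
            raise ValueError("phi_ex_ref must be non-negative")
        if self.ref_field_mhz <= 0:
            raise ValueError("ref_field_mhz must be positive")
        for f, r in self.r20_by_field.items():
            if f <= 0 or r <= 0:
                raise ValueError("fields and R2_0 values must be positive")
        object.__setattr__(self, "r20_by_field", dict(self.r20_by_field))

    def phi_ex_at(self, field_mhz: float) -> float:
        """Phi_ex scaled to ``field_mhz`` by the squared field ratio."""
        return self.phi_ex_ref * (field_mhz / self.ref_field_mhz) ** 2

    def r20_at(self, field_mhz: float) -> float:
        for f, r in self.r20_by_field.items():
            if abs(f - field_mhz) <= _FIELD_RTOL * max(abs(f), abs(field_mhz)):
                return r
        raise KeyError(
            f"no R2_0 declared for field {field_mhz} MHz "
            f"(known: {sorted(self.r20_by_field)})"
        )

    @property
    def fields(self) -> list[float]:
        return sorted(self.r20_by_field)

    def with_reference(self, new_ref_mhz: float) -> "FastExchangeFitParams":
        """Re-express Phi_ex at a different reference field (same model)."""
        return replace(
            self,
            phi_ex_ref=self.phi_ex_at(new_ref_mhz),
            ref_field_mhz=new_ref_mhz,
        )


@dataclass(frozen=True)
class CpmgSchedule:
    """CPMG acquisition schedule for a constant-time dispersion experiment.

    ``nu_cpmg = 1/(4*tau_cp)``; the number of 180-degree pulses within the
    constant relaxation period ``t_relax`` is ``2*round(t_relax*nu)``
    (an even, positive integer).
    """

    nu_cpmg: Sequence[float]
    t_relax: float = 0.04

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_cpmg, dtype=float)
        if nu.ndim != 1 or nu.size == 0:
            raise ValueError("nu_cpmg must be a non-empty 1-D sequence")
        if np.any(nu <= 0):
            raise ValueError("CPMG frequencies must be positive")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("nu_cpmg must be strictly increasing")
        if self.t_relax <= 0:
            raise ValueError("t_relax must be positive")
        object.__setattr__(self, "nu_cpmg", tuple(float(x) for x in nu))

    def tau_cp(self, nu: float) -> float:
        return 1.0 / (4.0 * nu)

    def n_pulses(self, nu: float) -> int:
        return max(2, 2 * int(round(self.t_relax * nu)))


@dataclass
class DispersionCurve:
    """One relaxation-dispersion curve: R2eff versus nu_cpmg at one field."""

    field_mhz: float
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    #: indices of points flagged during generation (e.g. magnetization underflow)
    flagged: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.nu_cpmg.shape != self.r2eff.shape:
            raise ValueError("nu_cpmg and r2eff must have the same length")
        if np.any(np.diff(self.nu_cpmg) <= 0):
            raise ValueError("nu_cpmg must be strictly increasing")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.nu_cpmg.shape:
                raise ValueError("sigma must match nu_cpmg in length")

    def to_frame(self) -> pd.DataFrame:
        sig = self.sigma if self.sigma is not None else np.full_like(self.r2eff, np.nan)
        return pd.DataFrame(
            {
                "field_mhz": self.field_mhz,
                "nu_cpmg_hz": self.nu_cpmg,
                "r2eff_s1": self.r2eff,
                "sigma_s1": sig,
            }
        )


def write_dispersion_csv(curves: Sequence[DispersionCurve], path) -> None:
    """Write curves as CSV with columns field_mhz, nu_cpmg_hz, r2eff_s1, sigma_s1."""
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(path, index=False)


def read_dispersion_csv(path, label: str = "") -> list[DispersionCurve]:
    """Read dispersion curves (one per distinct field) from CSV."""
    df = pd.read_csv(path) if not isinstance(path, io.IOBase) else pd.read_csv(path)
    curves = []
    for f, grp in df.groupby("field_mhz", sort=True):
        grp = grp.sort_values("nu_cpmg_hz")
        sig = grp["sigma_s1"].to_numpy()
        curves.append(
            DispersionCurve(
                field_mhz=float(f),
                nu_cpmg=grp["nu_cpmg_hz"].to_numpy(),
                r2eff=grp["r2eff_s1"].to_numpy(),
                sigma=None if np.all(np.isnan(sig)) else sig,
                label=label,
            )
        )
    return curves


def luz_meiboom_r2(
    params: FastExchangeFitParams,
    nu: float | np.ndarray,
    field_mhz: float,
    r20: float | None = None,
) -> float | np.ndarray:
    """Fast-exchange closed-form R2eff at CPMG frequency ``nu`` (Hz).

    Evaluates ``R2_0 + (Phi_ex/kex) * [1 - (4 nu/kex) tanh(kex/(4 nu))]``
    with Phi_ex scaled to ``field_mhz`` by the squared field ratio.
    ``r20`` overrides the per-field lookup (needed when predicting at a
    field that has no declared plateau rate).
    """
    nu_arr = np.asarray(nu, dtype=float)
    if np.any(nu_arr <= 0):
        raise ValueError("CPMG frequency must be positive")
    if r20 is None:
        r20 = params.r20_at(field_mhz)
    phi = params.phi_ex_at(field_mhz)
    x = params.kex / (4.0 * nu_arr)
    out = r20 + (phi / params.kex) * (1.0 - np.tanh(x) / x)
    return float(out) if np.isscalar(nu) else out


def r2eff_from_intensities(i: float, i0: float, t_relax: float) -> float:
    """Constant-time conversion ``R2eff = -ln(i/i0)/t_relax``."""
    if i <= 0 or i0 <= 0:
        raise ValueError("intensities must be positive")
    if t_relax <= 0:
        raise ValueError("t_relax must be positive")
    return -float(np.log(i / i0)) / t_relax


def cpmg_intensity(sys: ExchangeSystem, nu: float, t_relax: float) -> tuple[float, float]:
    """Propagate transverse magnetization through the CPMG train.

    Returns ``(I/I0, t_evolved)``.  The evolution matrix acts on the
    transverse coherences (M+_A, M+_B) with shift offsets at +/- dw/2,
    intrinsic relaxation and exchange; each 180(y) pulse is complex
    conjugation.  The evolved time ``2*n*tau_cp`` can differ slightly from
    ``t_relax`` because the pulse count is rounded to an even integer.
    """
    kab = sys.kex * sys.pb
    kba = sys.kex * sys.pa
    dw = sys.delta_omega_rad_s
    L = np.array(
        [
            [-sys.r2a0 - kab - 1j * (-dw / 2.0), kba],
            [kab, -sys.r2b0 - kba - 1j * (+dw / 2.0)],
        ],
        dtype=complex,
    )
    tau = 1.0 / (4.0 * nu)
    n = max(2, 2 * int(round(t_relax * nu)))
    P = expm(L * tau)
    m = np.array([sys.pa, sys.pb], dtype=complex)
    i0 = abs(m.sum())
    for _ in range(n):
        m = P @ np.conj(P @ m)
    return abs(m.sum()) / i0, 2.0 * n * tau


def bloch_mcconnell_r2eff(sys: ExchangeSystem, sched: CpmgSchedule) -> DispersionCurve:
    """Numerical R2eff dispersion curve for a two-site system.

    For each CPMG frequency the two transverse coherences are propagated
    through explicit ``tau_cp - 180 - tau_cp`` blocks and
    ``R2eff = -ln(I/I0) / t`` is computed with the actually evolved time
    ``t = 2 n tau_cp``.  Points where the magnetization underflows are
    returned with NaN and recorded in ``flagged``.
    """
    r2 = np.empty(len(sched.nu_cpmg))
    flagged: list[int] = []
    for j, nu in enumerate(sched.nu_cpmg):
        ratio, t_evolved = cpmg_intensity(sys, nu, sched.t_relax)
        if ratio < _UNDERFLOW:
            r2[j] = np.nan
            flagged.append(j)
        else:
            r2[j] = -np.log(ratio) / t_evolved
    return DispersionCurve(
        field_mhz=sys.field_mhz,
        nu_cpmg=np.asarray(sched.nu_cpmg),
        r2eff=r2,
        flagged=tuple(flagged),
    )
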