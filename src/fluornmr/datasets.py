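"""Synthetic study fixtures: spectra panels, relaxation series, dispersion data.

Everything the analysis pipeline consumes can be generated here, emulating
the study conditions:

* 1D 19F spectra as sums of Lorentzians at the reported chemical shifts of
  the nine Trp residues of thrombin and prethrombin-2 (ppm relative to TFA),
  with 20-Hz exponential line broadening and additive Gaussian noise;
* wild-type plus single Trp-to-Phe mutant spectrum panels for
  difference-based assignment;
* inversion-recovery and CPMG-decay series on the acquisition grids
  (delays 0.0625–8 s; spin-echo times 0.5–128 ms);
* two-field (564.686 / 658.780 MHz) relaxation-dispersion curves generated
  from the three reported fast-exchange parameter sets.

Reproducibility: one root seed; per-file child seeds are derived
deterministically from (root seed, file index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exchange import DispersionCurve, FastExchangeFitParams, luz_meiboom_r2
from .relaxation import T1_DELAYS, T2_N_POINTS, T2_TIME_RANGE, RelaxationSeries
from .spectra import (
    DEFAULT_FWHM_PPM,
    DEFAULT_LB_HZ,
    AssignmentTable,
    Peak,
    Spectrum1D,
    simulate_spectrum,
)

__all__ = [
    "TABLE2_SHIFTS",
    "EXCHANGE_FIXTURES",
    "FIELDS_MHZ",
    "StudyFixture",
    "build_table2_fixture",
    "generate_panel",
    "generate_dispersion_dataset",
    "generate_relaxation_series",
]

#: the two 19F Larmor frequencies of the study (MHz)
FIELDS_MHZ = (564.686, 658.780)

#: reported 19F chemical shifts (ppm vs TFA) of the nine Trp residues;
#: None = not determined; two entries = two slowly exchanging conformations
TABLE2_SHIFTS: dict[str, dict[str, list[float] | None]] = {
    "29": {"thrombin": None, "prethrombin-2": None},
    "51": {"thrombin": [-46.7], "prethrombin-2": [-46.7]},
    "60d": {"thrombin": [-48.5, -48.7], "prethrombin-2": [-47.9]},
    "96": {"thrombin": [-47.9], "prethrombin-2": [-47.9]},
    "141": {"thrombin": [-43.5], "prethrombin-2": [-47.9]},
    "148": {"thrombin": [-48.5], "prethrombin-2": [-47.9]},
    "207": {"thrombin": None, "prethrombin-2": [-47.9]},
    "215": {"thrombin": [-47.5], "prethrombin-2": [-47.9, -49.8]},
    "237": {"thrombin": [-49.4], "prethrombin-2": [-48.6]},
}

#: reported two-state fast-exchange parameter sets, (protein, residue) ->
#: params.  Phi_ex is not identifiable from the published values; the
#: fixture convention is Phi_ex(564.686 MHz) = 3.0e5 s^-2 (dispersion
#: amplitudes of order 1e2 s^-1, commensurate with the reported plateaus);
#: kex / R2_0 recovery does not depend on this choice.
PHI_EX_FIXTURE = 3.0e5
EXCHANGE_FIXTURES: dict[tuple[str, str], FastExchangeFitParams] = {
    ("prethrombin-2", "Trp51"): FastExchangeFitParams(
        kex=2970.0, phi_ex_ref=PHI_EX_FIXTURE,
        r20_by_field={564.686: 204.0, 658.780: 260.0}, ref_field_mhz=564.686,
    ),
    ("thrombin", "Trp215"): FastExchangeFitParams(
        kex=7980.0, phi_ex_ref=PHI_EX_FIXTURE,
        r20_by_field={564.686: 160.0, 658.780: 258.0}, ref_field_mhz=564.686,
    ),
    ("thrombin", "Trp51"): FastExchangeFitParams(
        kex=19000.0, phi_ex_ref=PHI_EX_FIXTURE,
        r20_by_field={564.686: 100.0, 658.780: 140.0}, ref_field_mhz=564.686,
    ),
}

#: default nu_cpmg grid (Hz): 12 log-spaced points spanning a low-frequency
#: anchor (25 Hz) up to the nu_cpmg = 1/(4 tau_cp) = 5000 Hz implied by the
#: shortest acquired half-echo delay (tau_cp 50–500 us)
NU_CPMG_GRID = tuple(float(x) for x in np.geomspace(25.0, 5000.0, 12))


def _child_rng(seed: int | None, index: int) -> np.random.Generator:
    """Deterministic per-file generator derived from (root seed, file index)."""
    return np.random.default_rng([0 if seed is None else int(seed), int(index)])


@dataclass
class StudyFixture:
    """Bundle of study conditions driving all synthetic data.

    Defaults are the study conditions: two fields, the printed chemical
    shifts, the acquisition grids, unit amplitude per resonance (relative
    intensities were not published), 0.08-ppm pre-broadening linewidth,
    20-Hz exponential broadening, 1% noise.
    """

    seed: int = 0
    fields_mhz: tuple[float, float] = FIELDS_MHZ
    spectrum_field_mhz: float = 658.780
    fwhm_ppm: float = DEFAULT_FWHM_PPM
    lb_hz: float = DEFAULT_LB_HZ
    noise_sigma: float = 0.01
    noise_frac_dispersion: float = 0.01
    t1_delays: tuple[float, ...] = T1_DELAYS
    nu_cpmg: tuple[float, ...] = NU_CPMG_GRID
    t2_times: tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(T2_TIME_RANGE[0], T2_TIME_RANGE[1], T2_N_POINTS)
    )
    shifts: Mapping[str, Mapping[str, list[float] | None]] = field(
        default_factory=lambda: TABLE2_SHIFTS
    )
    exchange_sets: Mapping[tuple[str, str], FastExchangeFitParams] = field(
        default_factory=lambda: EXCHANGE_FIXTURES
    )

    def assignment(self, protein: str) -> AssignmentTable:
        return AssignmentTable(
            protein=protein,
            entries={res: cols[protein] for res, cols in self.shifts.items()},
        )

    def peaks(self, protein: str, omit: Sequence[str] = ()) -> list[Peak]:
        """Unit-amplitude peak list for ``protein``, minus residues in ``omit``."""
        out: list[Peak] = []
        for res, cols in self.shifts.items():
            if res in omit or cols[protein] is None:
                continue
            for shift in cols[protein]:
                out.append(
                    Peak(
                        center_ppm=shift,
                        fwhm_hz=self.fwhm_ppm * self.spectrum_field_mhz,
                        amplitude=1.0,
                        label=f"Trp{res}",
                    )
                )
        return out


def build_table2_fixture() -> dict[str, AssignmentTable]:
    """The published assignment table, one AssignmentTable per protein."""
    fx = StudyFixture()
    return {p: fx.assignment(p) for p in ("thrombin", "prethrombin-2")}


def _normalize_mutant(tag: str) -> str:
    """'W215F' / 'Trp215' / '215' -> residue key '215'."""
    t = tag.strip()
    if t.upper().startswith("W") and t.upper().endswith("F") and len(t) > 2:
        t = t[1:-1]
    t = t.replace("Trp", "").replace("trp", "")
    key = t.lower()
    if key not in TABLE2_SHIFTS:
        raise ValueError(f"unknown Trp position {tag!r}")
    return key


def generate_panel(
    fixture: StudyFixture,
    protein: str,
    mutants: Sequence[str] = (),
    seed: int | None = None,
) -> dict[str, Spectrum1D]:
    """Wild-type spectrum plus one spectrum per single Trp-to-Phe mutant.

    A mutant spectrum is the wild-type peak list with the mutated residue's
    peak(s) removed (no cross-perturbation of neighbors).  Deterministic per
    seed: file index 0 is the wild type, mutants follow in the given order.
    """
    if protein not in ("thrombin", "prethrombin-2"):
        raise ValueError(f"unknown protein {protein!r}")
    root = fixture.seed if seed is None else seed
    keys = [_normalize_mutant(mtag) for mtag in mutants]

    def _sim(omit: Sequence[str], index: int) -> Spectrum1D:
        rng = _child_rng(root, index)
        return simulate_spectrum(
            fixture.peaks(protein, omit=omit),
            field_mhz=fixture.spectrum_field_mhz,
            noise_sigma=fixture.noise_sigma,
            lb_hz=fixture.lb_hz,
            seed=rng.integers(0, 2**31 - 1),
        )

    panel = {"WT": _sim((), 0)}
    for i, (tag, key) in enumerate(zip(mutants, keys), start=1):
        panel[f"W{key.upper()}F" if not tag.upper().startswith("W") else tag] = _sim((key,), i)
    return panel


def generate_dispersion_dataset(
    fixture: StudyFixture,
    protein: str,
    residue: str,
    noise_frac: float | None = None,
    seed: int | None = None,
) -> list[DispersionCurve]:
    """Two-field dispersion curves from a stored fast-exchange parameter set.

    ``noise_frac = 0`` returns exact closed-form values with no sigma;
    otherwise Gaussian noise of ``noise_frac * R2eff`` is added and the same
    value is recorded as the per-point sigma.
    """
    key = (protein, residue if residue.startswith("Trp") else f"Trp{residue}")
    if key not in fixture.exchange_sets:
        raise ValueError(f"no exchange parameter set for {key}")
    params = fixture.exchange_sets[key]
    nf = fixture.noise_frac_dispersion if noise_frac is None else noise_frac
    root = fixture.seed if seed is None else seed
    nu = np.asarray(fixture.nu_cpmg)
    curves = []
    for i, f in enumerate(fixture.fields_mhz):
        r2 = np.asarray(luz_meiboom_r2(params, nu, f))
        if nf > 0:
            rng = _child_rng(root, i)
            sigma = nf * r2
            r2 = r2 + rng.normal(0.0, sigma)
            curves.append(DispersionCurve(f, nu, r2, sigma=sigma, label=key[1]))
        else:
            curves.append(DispersionCurve(f, nu, r2, label=key[1]))
    return curves


def generate_relaxation_series(
    fixture: StudyFixture,
    kind: str,
    rate: float,
    amplitude: float = 1.0,
    inv_efficiency: float = 1.0,
    noise_frac: float = 0.0,
    n_replicates: int = 2,
    seed: int | None = None,
) -> list[RelaxationSeries]:
    """Synthetic T1 or T2 series on the study's acquisition grids.

    Measurements are produced in duplicate by default.  Noise is Gaussian
    with standard deviation ``noise_frac * amplitude``.
    """
    root = fixture.seed if seed is None else seed
    if kind == "inversion_recovery":
        t = np.asarray(fixture.t1_delays)
        clean = amplitude * (1.0 - 2.0 * inv_efficiency * np.exp(-rate * t))
    elif kind == "cpmg_decay":
        t = np.asarray(fixture.t2_times)
        clean = amplitude * np.exp(-rate * t)
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    out = []
    for rep in range(n_replicates):
        y = clean.copy()
        sigma = None
        if noise_frac > 0:
            rng = _child_rng(root, rep)
            s = noise_frac * amplitude
            y = y + rng.normal(0.0, s, size=t.size)
            sigma = np.full_like(t, s)
        out.append(
            RelaxationSeries(kind=kind, times=t, intensities=y, sigma=sigma, replicate_id=rep)
        )
    return out
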