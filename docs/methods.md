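# Methods

`fluornmr` analyzes one-dimensional ¹⁹F NMR data from proteins carrying
5-fluoro-tryptophan reporters, with thrombin and its zymogen precursor
prethrombin-2 (nine Trp positions in chymotrypsin numbering: 29, 51, 60d,
96, 141, 148, 207, 215, 237) as the built-in study system. This note
documents the models, the synthetic-data conventions, the numerical choices,
and the limits of what the shipped tests demonstrate.

## Two-site exchange under CPMG

A nucleus exchanging between conformations A and B (populations pA, pB,
exchange rate kex = kAB + kBA, shift difference Δω rad/s) relaxes during a
CPMG pulse train at an effective rate R₂eff that depends on the pulsing
frequency. Throughout the package

    ν_cpmg = 1 / (4 τ_cp),

where 2 τ_cp is the delay between consecutive 180° pulses. This convention
is stated here prominently because other conventions (1/(2τ_cp)) are in
circulation; every CPMG frequency in the code follows the definition above.

**Closed form (user-facing model).** In the fast-exchange limit
(kex ≫ Δω) the dispersion collapses to the Luz–Meiboom expression

    R₂eff(ν) = R₂⁰ + (Φex / kex) · [1 − (4ν / kex) · tanh(kex / 4ν)],

with Φex = pA·pB·Δω². Only Φex is identifiable in this regime: pA, pB and
Δω cannot be separated, and the package deliberately never reports them
individually. Because Δω is linear in the static field, Φex scales with the
squared field ratio; the global fit ties the two fields together through
this constraint.

**Numerical oracle.** An independent Bloch–McConnell simulator propagates
the two transverse coherences (M⁺_A, M⁺_B) through explicit
τ_cp–180°–τ_cp blocks. The evolution operator is the matrix exponential of
the 2×2 complex matrix combining shift offsets at ±Δω/2, intrinsic
relaxation, and exchange; each 180°(y) pulse acts as complex conjugation.
The pulse count inside the constant relaxation period (default
t_relax = 0.04 s) is rounded to an even integer, and R₂eff is computed with
the actually evolved time 2·n·τ_cp rather than the nominal period, which
removes the rounding bias at low ν. Intensity ratios below 10⁻¹² are
treated as underflow and flagged rather than converted to rates. The oracle
is used in tests to *quantify* the closed-form approximation error (≤ 2%
for kex ≥ 10 Δω over the acquisition grid), never to correct it.
Carver–Richards all-timescale fitting is intentionally out of scope; the
study system is fit in the fast-exchange regime.

## Global dispersion fitting

`fit_dispersion_global` (estimator: `FastExchangeDispersionModel`) fits all
curves of one residue jointly: one shared kex, one R₂⁰ per field, and one
Φex quoted at a reference field (default: the lowest field present).
Weights are 1/σ² when per-point uncertainties are supplied, unweighted
otherwise; duplicate measurements enter as independent points. The
optimizer is bounded trust-region least squares multistarted from nine
log-spaced kex values between 10² and 10⁶ s⁻¹; χ² ties (Δχ² < 10⁻⁶) break
toward the smaller kex, preferring the slower-exchange explanation when the
data cannot tell. Standard errors come from the covariance at the optimum
— (JᵀJ)⁻¹ for weighted fits, scaled by the reduced χ² otherwise — and a
1-D profile-likelihood routine (`profile_uncertainty`, Δχ² = 1 interval
with nuisance parameters re-optimized) is available as the more honest
alternative near identifiability limits.

A fit is flagged `no dispersion` when the fitted amplitude Φex/kex falls
below twice the median noise level (with a small dynamic-range floor for
noiseless input); the kex standard error is then reported as infinite
rather than as a misleading finite number.

Reparameterization invariance (re-referencing Φex to the other field leaves
kex, R₂⁰ and χ² unchanged) and stderr growth under data removal are
asserted in the test suite.

## Relaxation fitting

Inversion recovery: I(t) = I∞·(1 − 2f·e^(−t/T1)), with the inversion
efficiency f a free parameter bounded to [0.5, 1] (initial value 0.98);
f = 1 is perfect inversion (null time T1·ln 2), f = 0.5 the
saturation-recovery limit (null time 0). A monotonically decreasing series
is rejected as a model mismatch rather than silently fit. CPMG decay:
I(t) = I₀·e^(−t/T2), initialized log-linearly and refined by least squares;
rates indistinguishable from zero are flagged `non-relaxing`. Both fits are
weighted when σ is available and are scale-equivariant. Pooling duplicates
into per-time means with σ/√2 weights is numerically equivalent to the
joint fit, and the suite asserts it. The 7-s inter-scan relaxation delay of
the acquisition scheme is metadata only. Multi-exponential decomposition is
out of scope.

## Spectrum synthesis and processing

Spectra are sums of peak-height-normalized Lorentzians on a ppm axis
referenced to TFA = 0, stored downfield→upfield over −40 to −54 ppm with
2¹⁴ points (≈ 0.85 milli-ppm steps). The default pre-broadening linewidth
is 0.08 ppm FWHM, chosen so the 0.2-ppm Trp60d doublet of the protease
column resolves; the 20-Hz exponential apodization of the processing
pipeline enters as an additive Lorentzian width (its exact frequency-domain
equivalent), giving ≈ 0.11 ppm total at 658.780 MHz. Synthesis is performed
directly in the frequency domain; time-domain synthesis followed by Fourier
transform would be equivalent for these ideal lineshapes and is not
implemented. Noise is additive Gaussian on the spectrum (σ default 0.01 of
the unit peak amplitude). Real processed spectra have noise correlated over
the apodization width; the white-noise convention is harsher on detection
algorithms, which is the conservative direction for testing them.

Relative peak intensities of the real spectra are unpublished, so every
resonance carries unit amplitude (equimolar reporters). This convention —
not a claim about the data — automatically makes the prethrombin-2 cluster
at −47.9 ppm large and broad by superposition of its five coincident
resonances.

**Peak picking.** The noise level is estimated from the most upfield 10% of
the axis via successive differences (insensitive to smooth Lorentzian tails
leaking into the window). When noise is non-negligible against the height
threshold (default 1% of the maximum), picking runs on a matched-filtered
copy: convolution with an area-normalized Lorentzian kernel whose FWHM
equals the applied line broadening. Candidate maxima must clear the height
threshold and a 5× smoothed-noise prominence; maxima closer than 0.05 ppm
merge keeping the taller. Centers are refined by parabolic interpolation
(clamped to one grid step), and since the convolution of two Lorentzians
adds their widths, the kernel width is subtracted from the measured
half-height width.

**Mutant-difference assignment.** A mutant spectrum is the wild-type peak
list minus the mutated residue's peak(s); cross-perturbation of neighbors
is off by default so that assignment recovery is exact by construction (the
real experiment showed non-selective perturbations; a realistic mode can
jitter neighbors by ±0.03 ppm). `assign_by_difference` uses two-threshold
hysteresis detection: perturbed regions are grown where |WT − mutant|
exceeds 3× the noise estimated from the difference's signal-free slice, and
reported only if they contain a 5× excursion. Supra-threshold runs closer
than 0.05 ppm merge, and regions with fewer than six supra-threshold
samples are discarded — any genuine Lorentzian at this sampling spans
dozens of points. For noiseless input a 1%-of-maximum dynamic-range floor
replaces σ, so region extent reflects the resolved lineshape rather than
arbitrarily faint tails. A perturbation weaker than the detection threshold
everywhere is reported as absent — a documented blind spot, acceptable for
unit-amplitude fixtures.

## Synthetic study fixtures

`StudyFixture` bundles the study conditions: fields 564.686 and
658.780 MHz; the nine-residue shift table with its dual entries (Trp60d
−48.5/−48.7 in the protease; Trp215 −47.9/−49.8 in the zymogen, the
slow-exchange pairs) and not-determined entries; inversion-recovery delays
0.0625–8 s; spin-echo times 0.5–128 ms (8 points); and the three
fast-exchange parameter sets (kex = 2,970 / 7,980 / 19,000 s⁻¹ with their
per-field plateau rates). Φex is not identifiable from the published
values, so fixtures adopt Φex(564.686 MHz) = 3.0×10⁵ s⁻² — dispersion
amplitudes of order 10² s⁻¹, commensurate with the reported plateaus;
recovery of kex and R₂⁰ does not depend on this choice, which the
round-trip tests confirm.

The default ν_cpmg grid is 12 log-spaced points over 25–5000 Hz: the upper
end is 1/(4·50 µs), fixed by the shortest half-echo delay of the
acquisition protocol, plus a low-frequency anchor. The upper end matters:
at 1% noise the kex ≈ 19,000 s⁻¹ parameter set is only weakly identified if
sampling stops near 2000 Hz, where ~40% of its dispersion remains
unquenched. Dispersion noise defaults to 1% of R₂eff, recorded as the
per-point σ. All generators derive per-file child seeds deterministically
from (root seed, file index), so every fixture regenerates bit-identically
and the CLI's end-to-end report is byte-stable for a fixed seed (floats are
rounded to 10 decimals before serialization to keep the report
platform-stable).

## Structural metrics

PDB parsing is backed by gemmi; the highest-occupancy altloc conformer is
kept, waters and non-Trp hetero groups (e.g. the active-site inhibitor and
bound Na⁺) are excluded from superposition, and any Trp-derived residue
name (FTR, 5FW, ...) at the nine positions is treated as Trp.
`kabsch_rmsd` pairs atoms on (residue number, insertion code, atom name) —
chain identity is ignored so differently lettered depositions pair — and
computes the SVD-based optimal proper rotation (reflection optima are
sign-corrected). The default selection is Cα over common residues; the
published superposition values do not state their selection, so
reproduction is approximate by nature and the result reports the selection
and pairing used. The active-site aperture is the Gly193–Gly216 Cα–Cα
distance; models are tagged E-like (open) at or above 10.05 Å — the
midpoint of the canonical 12 Å open and 8.1 Å closed values — and E*-like
below. Fluorine labeling is verified per Trp by requiring a fluorine within
a C–F bond length (1.8 Å) of the CZ3 ring carbon, the indole 5-position;
when CZ3 is absent the fluorine's presence alone counts, with a note.

## What the tests do and do not show

All NMR fixtures are synthetic: Lorentzian lineshapes, white Gaussian
noise, equimolar amplitudes, no baseline or phase errors, no scalar
coupling, no off-resonance or pulse-imperfection effects (the study data do
not constrain these). Passing tests therefore demonstrate correctness of
the estimators under the stated generative model — exact noiseless round
trips, calibrated uncertainties at 1% noise, closed-form/oracle agreement —
not robustness to raw-spectrometer artifacts. The structural comparison
against the deposited crystal structures requires the PDB files themselves,
which are not redistributable test fixtures; the corresponding check runs
only where those files are present, and all structural algorithms are
exercised on synthetic models regardless.
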