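# Methods

This note records the models behind each `ccmelt` module, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Sequence model (`seqcore`)

**Heptad register.** The coiled-coil register is a pure cyclic
arithmetic: one letter *a*–*g* per residue, fixed by a single anchor
(position, letter). The default anchor, Tpm1.1 92 = *a* (equivalently
Tpm3.12 93 = *a*), is the register under which the cardiomyopathy sites
I92/V95 fall in the core positions *a*/*d* and the congenital-myopathy
site R91 of Tpm3.12 falls in the outward-facing *f* position — the
placements the stability phenotypes require. The anchor is a config
parameter so alternative registers can be explored. Surface classes are
a fixed function of the letter: core (*a*, *d*), interface (*e*, *g*),
outer (*b*, *c*, *f*).

**Heptad counting** counts complete *a*→*g* windows inside the fragment's
tropomyosin portion: a 91-residue fragment starting on an *a* position
contains 13 such windows.

**Fragments and numbering.** A designed peptide is `fusion_tag +
isoform[start..end]`. All coordinates in the package are native isoform
positions; tag residues are numbered sequentially ending at `start − 1`
(Tpm1.1 tag = 57–63), so every published residue number can be used
directly. The designed peptides are 98 residues (7-residue tag +
91-residue tropomyosin portion); the package always reports the computed
length.

**Masses** use average (not monoisotopic) atomic masses via Biopython,
matching the convention of SDS-gel estimates and the usual web
calculators; the disulfide dimer is `2 × monomer − 2.016 Da` exactly (two
hydrogens leave when the S–S bond forms).

**Actin-binding periods** have no universally agreed numeric boundaries;
they enter only as an optional, user-supplied interval map. The default
places the 35-residue period 3 at Tpm1.1 85–119: this contains the
mutation cluster (91–95) while leaving the isoform differences at 79/84
in period 2 and those at 132/135 in period 4, consistent with how those
differences are conventionally attributed.

## CD melting analysis (`cdmelt`)

**Normalization.** `z_i = (x_i − min x)/(max x − min x)` is applied
as-is; `fraction_unfolded` then orients the curve so the folded state
(the most negative 222 nm MRE) maps to 0 regardless of sign conventions
or scan direction. No baseline correction is applied beyond this min-max
map; consequently, with sloping instrument baselines the normalized value
at T_m is near, but not exactly, 0.5 (it is exactly 0.5 for flat
baselines).

**T_m extraction.** The fraction-unfolded curve is smoothed by a local
least-squares quadratic (Savitzky–Golay, default window 7 points — a
mild smoothing appropriate for the 0.5 °C instrument grid), the first
derivative taken analytically from the same filter, and the global
derivative maximum refined by a quadratic fit of the derivative over
±5 °C around the discrete maximum. The refinement is what delivers
sub-grid precision (bias ≤ 0.2 °C on noiseless two-state curves, and
~98 of 100 seeded curves within ±0.5 °C of truth at 2% noise); the
window and the truncation threshold are CLI flags.

**Not determined (ND).** A T_m is refused, mirroring how instrument
software and practice treat curves without a folded baseline, when any
of:

* the smoothed normalized signal at the first grid point exceeds the
  truncation threshold (default 0.2);
* the initial derivative exceeds `thr(1 − thr)/0.25` of the peak
  derivative — the exact image of "fraction unfolded > thr at the first
  point" for a two-state signal, since dz/dT ∝ f_U(1 − f_U); this form
  survives the min-max renormalization that otherwise pins the first
  point of a truncated curve near z = 0;
* the derivative maximum falls in the outermost 5% of the grid.

**van't Hoff fit.** An independent estimator used as a cross-check:
least squares on `signal(T) = (1 − f_U)(bF + mF T) + f_U(bU + mU T)` with
`f_U = K/(1 + K)`, `K = exp[−(ΔH/R)(1/T − 1/T_m)]` (T in Kelvin inside
the exponent only, R = 8.314 J mol⁻¹ K⁻¹). Initial values come from
end-segment baseline fits and the coarse derivative maximum; ΔH is
bounded to (1, 5000] kJ/mol. On noiseless two-state data the two T_m
estimators agree within one grid step.

**ΔT_m reports.** `dtm_vs_reference = T_m(reference) − T_m(sample)` under
the same condition, so destabilization is positive;
`dtm_nonreduced_minus_reduced = T_m(no DTT) − T_m(DTT)` quantifies the
stabilization by the N-terminal disulfide cross-link. ND propagates
through every difference it touches.

**Helicity at 222 nm.** `f_H = ([θ]222 − [θ]coil)/([θ]helix − [θ]coil)`
with the chain-length-corrected helix limit `[θ]helix = −39,500(1 −
2.57/n)` and coil baseline `2,220 − 53 T(°C)` — one standard
single-wavelength convention, exposed in `HelicityConstants` because
percent-helix figures are convention-dependent: the same MRE shift (e.g.
−28,370 → −19,057) reads as a ~30% relative helicity drop under these
constants and ~33% as a zero-baseline relative change of the raw MRE.
Results are clipped to [0, 1].

**t-tests** delegate to scipy: paired (differences) and unpaired
Welch with Welch–Satterthwaite degrees of freedom. Zero-variance
situations (e.g. paired groups differing by an exact constant) return a
degenerate-flagged result rather than raising, so batch reports survive
pathological replicates.

**MRE conversion.** `MRE = θ(mdeg) · MRW / (10 · l(cm) · c(mg/mL))`; the
path length argument is taken in mm at the interface (instrument cuvettes
are specified in mm) and converted internally. A −33 mdeg reading at
0.1 mg/mL in a 1 mm cell with MRW 110 gives ≈ −36,300 deg cm² dmol⁻¹, the
right order for a fully helical coiled coil.

## Trajectory geometry (`trajgeom`)

**Helicity criterion.** A residue is helical when every backbone dihedral
it defines lies in φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; terminal residues
are judged on their single defined dihedral. A dihedral-window test was
chosen over hydrogen-bond (DSSP-style) assignment because the synthetic
models carry only N/CA/C backbones; windows and the minimum run length
(default 4 consecutive residues, filtering incidental hits inside frayed
termini) are parameters. The span runs from the first residue of the
first qualifying run to the last residue of the last one; "no helix" is
a `None` result, not an error.

**End-to-end distances** are per-frame Euclidean CA–CA distances between
a fixed residue pair. The pair is determined once on a designated
reference frame (default: the final frame, the natural choice when spans
are read off the end-of-run structure) and held fixed across frames, as
is standard when comparing chains over a run. Summaries report mean ± sd
per chain with population (n) sd by default — switchable to sample
(n − 1), since reported ± values rarely state which was used — plus the
fragment average: the per-frame mean across chains, then mean ± sd over
frames.

## Synthetic generators (`synthgen`)

**Melting curves.** The two-state signal with linear baselines plus
i.i.d. Gaussian noise from one explicit seed. Defaults: T_m 50 °C, ΔH
400 kJ/mol (mid-range for a ~100-residue coiled coil), folded baseline
−30,000 + 30 T, unfolded −3,000 − 10 T deg cm² dmol⁻¹ (typical 222 nm
levels and drifts), noise 270 ≈ 1% of the signal range, grid 0–90 °C in
0.5 °C steps (instrument-like: melts start near 0 °C). What this does
*not* emulate: aggregation, scan-rate hysteresis, baseline curvature,
or three-state intermediates — so passing recovery tests shows the
estimator handles noise and truncation, not every instrument pathology.

**Coiled coils.** Chain A's CA trace follows the Crick parameterization:
a superhelical axis of radius R0 = 4.9 Å and pitch 140 Å (left-handed),
rise 1.495 Å/residue along the axis, minor helix of radius R1 = 2.26 Å
advancing ω1 = +102.86°/residue (= 720°/7, so the heptad phase is exactly
periodic in the rotating frame and *a*/*d* positions keep facing the
partner; φ1 defaults to π, pointing residue 0 at the partner chain). N
and C atoms are attached in local frames built from the CA trace, with
offsets calibrated at run time against an ideal α-helix constructed from
internal coordinates (φ = −60°, ψ = −47°, standard bond geometry); the
calibration transfers cleanly because the supercoil bends the local
geometry only gently, leaving mid-chain dihedrals at φ ≈ −58°, ψ ≈ −46°.
The trace is extended by one virtual residue at each end so terminal
residues get proper frames. Chain B is the C2 rotation of chain A about
the superhelix axis — a parallel dimer with equivalent residues ~2 R0
apart on mid-chain average. Consecutive CA distances come out at
3.76–3.77 Å and the end-to-end distance within 0.5% of rise × (n − 1).

**Trajectory perturbation** is geometric, not physical. Each frame after
the unperturbed frame 0 applies (i) a global bend: the molecule is mapped
onto a circular arc in a random transverse plane, with arc angle
|N(0, 1)| × bend_amplitude, which shortens the end-to-end chord while
preserving axial fibre length (interior CA–CA distances change by < a
few %); and (ii) terminal fraying: rigid Gaussian displacement of the
outermost `fray_length` residues, ramping to `fray_amplitude` (1 sd) at
the ends. Defaults (500 frames at 0.4 ns spacing, bend 0.15 rad, fray 5
residues at 1.5 Å) give end-to-end fluctuations of the order seen for
~100-residue coiled-coil fragments in solution-scale simulations. Because
random draws are scaled by the amplitudes, the same seed yields
frame-by-frame comparable trajectories across amplitudes, making the
"mean distance decreases with bending" property testable without
Monte-Carlo slack. Not emulated: real dihedral dynamics, chain
separation, solvent, or force-field physics — distance statistics from
these trajectories validate the measurement code, not molecular
behaviour.

**Spectra.** Helix/coil basis shapes (Gaussian bands: helix minima at 208
and 222 nm, positive 193 nm band; coil negative band at 198 nm) pinned at
222 nm to the same constants as the helicity estimate, so
simulate → estimate round-trips to ±0.02.

## Degenerate inputs and tie-breaks

Flat melting curves (max = min) raise a dedicated error; curves shorter
than 10 points are rejected at fit time, not read time. The smoothing
window must be odd, ≥ 5 and ≤ n/2. If the derivative-peak quadratic fit
is non-concave or its vertex escapes the fit window, the estimator falls
back to a three-point parabola through the discrete maximum, then to the
grid point itself. Melting CSV groups are keyed by (sample, condition,
replicate); duplicated temperature rows within a group are format errors.
PDB round-trips are exact at the format's 3-decimal coordinate precision.

## Known limitations

* The helix-span criterion is a stand-in for visual/manual boundary
  identification and may place boundaries a residue or two differently.
* Absolute T_m values of real peptides and absolute MD distance
  statistics require the original measurements; the package reproduces
  the measured-table arithmetic exactly and validates its estimators on
  synthetic ground truth instead.
* The min-max normalization deliberately implements no baseline
  correction; strongly sloping folded baselines bias the normalized
  amplitude (not the derivative-maximum location, which is what T_m
  uses).
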