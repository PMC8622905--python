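"""CD melting-curve and spectrum processing.

The thermal-denaturation pipeline implemented here follows the standard
two-state treatment of coiled-coil unfolding monitored by the mean residue
ellipticity (MRE) at 222 nm:

* min-max normalization of the raw signal,
  ``z_i = (x_i - min(x)) / (max(x) - min(x))``;
* orientation of the normalized curve as *fraction unfolded* (the folded
  state has the most negative MRE at 222 nm, so it maps to 0);
* the melting temperature Tm as the maximum of the first derivative of the
  fraction-unfolded curve, with Savitzky-Golay smoothing and a quadratic
  refinement of the derivative peak;
* an explicit "not determined" (ND) outcome for curves that lack a folded
  baseline - i.e. the sample had already begun unfolding at the lowest
  measured temperature;
* an independent van't Hoff fit (two-state equilibrium with sloping linear
  baselines) used as a cross-check of the derivative-maximum estimate;
* delta-Tm reports of mutation and disulfide (reducing vs non-reducing)
  effects, single-wavelength helicity estimates, and replicate t-tests.

Temperatures are degrees Celsius everywhere at the interface and converted
to Kelvin only inside van't Hoff expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import savgol_filter

from .errors import (
    DegenerateCurveError,
    DomainError,
    FitError,
    GridError,
    ParameterError,
    ReportError,
    SampleSizeError,
    ValidationError,
)

GAS_CONSTANT = 8.314  # J / (mol K)
CELSIUS_OFFSET = 273.15

#: Minimum number of points for a curve to be fitted (enforced at fit
#: time, not at construction, so short records can still be inspected).
MIN_FIT_POINTS = 10


def celsius_to_kelvin(t_celsius):
    return np.asarray(t_celsius, dtype=float) + CELSIUS_OFFSET


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltingCurve:
    """An ellipticity-vs-temperature series for one sample and condition.

    ``signal`` is the mean residue ellipticity at 222 nm in
    deg cm^2 dmol^-1 (negative for folded helix); ``condition`` is
    ``"reduced"`` (with DTT) or ``"non_reduced"``.
    """

    temperatures: np.ndarray
    signal: np.ndarray
    sample_id: str = ""
    condition: str = "non_reduced"
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        x = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", x)
        if t.ndim != 1 or x.shape != t.shape:
            raise ValidationError("temperatures and signal must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise GridError(f"{self.sample_id}: temperatures must strictly increase")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"{self.sample_id}: signal contains non-finite values")
        if self.condition not in ("reduced", "non_reduced"):
            raise ValidationError(
                f"condition must be 'reduced' or 'non_reduced', got {self.condition!r}"
            )

    @property
    def n_points(self) -> int:
        return int(self.temperatures.size)


@dataclass(frozen=True)
class NormalizedCurve:
    """Min-max normalized melting data, z in [0, 1]."""

    temperatures: np.ndarray
    z: np.ndarray
    orientation: str  # fraction_unfolded | fraction_folded
    sample_id: str = ""
    condition: str = "non_reduced"


@dataclass(frozen=True)
class MeltingResult:
    """Outcome of Tm extraction for one curve.

    ``tm`` is ``None`` when the melting temperature could not be determined
    (ND) - either no folded baseline at the low end (``truncated_low``) or
    the derivative maximum sits at the edge of the grid.
    """

    sample_id: str
    condition: str
    tm: float | None
    derivative_peak_height: float = float("nan")
    smoothing_window: int = 0
    truncated_low: bool = False
    truncated_high: bool = False

    @property
    def determined(self) -> bool:
        return self.tm is not None

    def tm_label(self, decimals: int = 1) -> str:
        if self.tm is None:
            return "ND"
        return f"{self.tm:.{decimals}f}"


@dataclass(frozen=True)
class SpectrumRecord:
    """A far-UV CD spectrum: MRE vs wavelength at one temperature."""

    wavelengths: np.ndarray
    mre: np.ndarray
    temperature: float = 0.0
    condition: str = "non_reduced"
    sample_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.mre, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "mre", m)
        if w.ndim != 1 or m.shape != w.shape:
            raise ValidationError("wavelengths and mre must be equal-length 1-D")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise GridError("wavelengths must strictly increase")

    def mre_at(self, wavelength: float) -> float:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.mre[idx])


@dataclass(frozen=True)
class HelicityConstants:
    """Constants of the single-wavelength (222 nm) helicity convention.

    ``theta_inf`` is the 222 nm MRE of an infinite helix; the helix limit
    for a chain of n residues is ``theta_inf * (1 - chain_length_k / n)``.
    The random-coil baseline is linear in temperature:
    ``coil_intercept + coil_slope * T(degC)``.
    """

    theta_inf: float = -39500.0
    chain_length_k: float = 2.57
    coil_intercept: float = 2220.0
    coil_slope: float = -53.0

    def helix_limit(self, n_residues: int) -> float:
        return self.theta_inf * (1.0 - self.chain_length_k / n_residues)

    def coil_limit(self, temperature: float) -> float:
        return self.coil_intercept + self.coil_slope * temperature


@dataclass(frozen=True)
class VantHoffFit:
    """Fitted two-state parameters: Tm (degC), dH (kJ/mol), baselines."""

    tm: float
    dh_vh: float  # kJ/mol
    folded_baseline: tuple[float, float]  # intercept, slope per degC
    unfolded_baseline: tuple[float, float]
    residual_norm: float


@dataclass(frozen=True)
class TTestResult:
    """t statistic, degrees of freedom and two-sided p-value.

    ``degenerate`` marks the zero-variance guard case (e.g. paired groups
    differing by an exact constant), which is reported rather than raised.
    """

    t: float
    df: float
    p: float
    mode: str
    degenerate: bool = False
    note: str = ""


# ---------------------------------------------------------------------------
# Two-state (van't Hoff) model - shared by the fit and the simulator
# ---------------------------------------------------------------------------


def two_state_fraction_unfolded(t_celsius, tm_celsius: float, dh_kj: float):
    """Equilibrium fraction unfolded of a two-state transition.

    ``K(T) = exp(-(dH/R) (1/T - 1/Tm))`` with temperatures in Kelvin;
    ``f_U = K / (1 + K)``, exactly 0.5 at ``T = Tm``.
    """
    t_k = celsius_to_kelvin(t_celsius)
    tm_k = tm_celsius + CELSIUS_OFFSET
    log_k = -(dh_kj * 1000.0 / GAS_CONSTANT) * (1.0 / t_k - 1.0 / tm_k)
    # logistic form avoids overflow far from Tm
    return 1.0 / (1.0 + np.exp(-log_k))


def two_state_signal(
    t_celsius,
    tm_celsius: float,
    dh_kj: float,
    folded_baseline: tuple[float, float],
    unfolded_baseline: tuple[float, float],
):
    """Noise-free two-state CD signal with sloping linear baselines."""
    t = np.asarray(t_celsius, dtype=float)
    f_u = two_state_fraction_unfolded(t, tm_celsius, dh_kj)
    folded = folded_baseline[0] + folded_baseline[1] * t
    unfolded = unfolded_baseline[0] + unfolded_baseline[1] * t
    return (1.0 - f_u) * folded + f_u * unfolded


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def mre_from_raw(
    theta_mdeg: float,
    concentration_mg_ml: float,
    path_length_mm: float,
    mean_residue_weight: float,
) -> float:
    """Convert a raw ellipticity (millidegrees) to MRE (deg cm^2 dmol^-1).

    ``MRE = theta * MRW / (10 * path_cm * conc_mg_per_mL)``; linear in
    theta, so a zero reading maps to zero.
    """
    if concentration_mg_ml <= 0:
        raise DomainError("concentration must be > 0")
    if path_length_mm <= 0:
        raise DomainError("path length must be > 0")
    if mean_residue_weight <= 0:
        raise DomainError("mean residue weight must be > 0")
    path_cm = path_length_mm / 10.0
    return theta_mdeg * mean_residue_weight / (10.0 * path_cm * concentration_mg_ml)


def normalize(curve: MeltingCurve) -> NormalizedCurve:
    """Min-max normalize the signal: ``z = (x - min) / (max - min)``.

    The raw equation is sign-agnostic; the orientation label records
    whether low z corresponds to the folded state (which, for MRE at
    222 nm, holds when the folded end is the signal minimum).
    """
    x = curve.signal
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateCurveError(
            f"{curve.sample_id}: flat curve (max == min), cannot normalize"
        )
    z = (x - lo) / (hi - lo)
    # If the signal at the lowest temperatures sits nearer the minimum,
    # z already reads as fraction unfolded.
    orientation = (
        "fraction_unfolded" if x[0] <= x[-1] else "fraction_folded"
    )
    return NormalizedCurve(
        curve.temperatures.copy(), z, orientation, curve.sample_id, curve.condition
    )


def fraction_unfolded(curve: MeltingCurve) -> NormalizedCurve:
    """Normalized curve oriented so folded -> 0 and unfolded -> 1.

    The folded coiled coil has the most negative MRE at 222 nm, so the
    signal minimum maps to 0 regardless of scan direction or sign offsets.
    """
    norm = normalize(curve)
    z = norm.z if norm.orientation == "fraction_unfolded" else 1.0 - norm.z
    return NormalizedCurve(
        norm.temperatures, z, "fraction_unfolded", curve.sample_id, curve.condition
    )


def _derivative(z: np.ndarray, t: np.ndarray, window: int) -> np.ndarray:
    """Smoothed dz/dT via local least-squares quadratic (Savitzky-Golay)."""
    steps = np.diff(t)
    if np.allclose(steps, steps[0], rtol=1e-6):
        return savgol_filter(z, window, polyorder=2, deriv=1, delta=float(steps[0]))
    smoothed = savgol_filter(z, window, polyorder=2)
    return np.gradient(smoothed, t)


def melt_tm(
    curve: MeltingCurve,
    window: int = 7,
    truncation_threshold: float = 0.2,
    refine_half_width: float = 5.0,
    edge_fraction: float = 0.05,
) -> MeltingResult:
    """Melting temperature as the maximum of the first derivative.

    The fraction-unfolded curve is smoothed with a sliding local
    least-squares quadratic (``window`` points, odd), its derivative's
    discrete maximum located, and the peak refined by a quadratic fit of
    the derivative over ``+/- refine_half_width`` degC around the maximum,
    giving sub-grid precision.

    The result is ND (``tm = None``) when the transition has already begun
    at the first grid point (smoothed fraction unfolded above
    ``truncation_threshold``; flag ``truncated_low``) or when the
    derivative maximum falls in the outermost ``edge_fraction`` of the
    grid on either side.
    """
    n = curve.n_points
    if n < MIN_FIT_POINTS:
        raise GridError(
            f"{curve.sample_id}: need >= {MIN_FIT_POINTS} points, got {n}"
        )
    if window % 2 == 0 or window < 5 or window > n // 2:
        raise ParameterError(
            f"window must be odd, >= 5 and <= n/2 = {n // 2}; got {window}"
        )
    fu = fraction_unfolded(curve)
    t, z = fu.temperatures, fu.z
    z_smooth = savgol_filter(z, window, polyorder=2)
    dz = _derivative(z, t, window)
    i_max = int(np.argmax(dz))
    peak = float(dz[i_max])

    # A missing folded baseline shows up in two ways after min-max
    # normalization: the curve is already rising at its first point (the
    # initial derivative is a sizeable fraction of the peak derivative -
    # for a two-state signal, dz/dT scales as f_U (1 - f_U), so the ratio
    # threshold below is the image of `truncation_threshold` on the
    # fraction-unfolded scale), or the derivative maximum is pressed
    # against the low edge of the grid.
    start_ratio = float(np.median(dz[:3])) / peak if peak > 0 else 0.0
    ratio_threshold = truncation_threshold * (1.0 - truncation_threshold) / 0.25
    truncated_low = (
        bool(z_smooth[0] > truncation_threshold)
        or start_ratio > ratio_threshold
        or i_max < edge_fraction * n
    )
    truncated_high = i_max > (1.0 - edge_fraction) * n
    if truncated_low or truncated_high:
        return MeltingResult(
            curve.sample_id,
            curve.condition,
            tm=None,
            derivative_peak_height=peak,
            smoothing_window=window,
            truncated_low=truncated_low,
            truncated_high=truncated_high,
        )

    tm = _refine_peak(t, dz, i_max, refine_half_width)
    return MeltingResult(
        curve.sample_id,
        curve.condition,
        tm=tm,
        derivative_peak_height=peak,
        smoothing_window=window,
    )


def _refine_peak(
    t: np.ndarray, dz: np.ndarray, i_max: int, half_width: float
) -> float:
    """Sub-grid peak position from a quadratic fit around the maximum."""
    mask = np.abs(t - t[i_max]) <= half_width
    if mask.sum() >= 5:
        a, b, _ = np.polyfit(t[mask], dz[mask], 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            if t[mask][0] <= vertex <= t[mask][-1]:
                return float(vertex)
    # fall back to a three-point parabola through the discrete maximum
    if 0 < i_max < t.size - 1:
        y0, y1, y2 = dz[i_max - 1], dz[i_max], dz[i_max + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0:
            offset = 0.5 * (y0 - y2) / denom
            step = 0.5 * (t[i_max + 1] - t[i_max - 1])
            return float(t[i_max] + np.clip(offset, -1, 1) * step)
    return float(t[i_max])


def vanthoff_fit(curve: MeltingCurve) -> VantHoffFit:
    """Least-squares fit of the two-state model with linear baselines.

    Serves as an independent estimator of Tm (and of the van't Hoff
    enthalpy) against which the derivative-maximum estimate can be
    cross-checked. Requires both baselines to be present in the data.
    """
    n = curve.n_points
    if n < MIN_FIT_POINTS:
        raise GridError(f"{curve.sample_id}: need >= {MIN_FIT_POINTS} points")
    t, x = curve.temperatures, curve.signal

    # initial guesses: end-segment baselines and the coarse derivative max
    k = max(3, n // 6)
    bf1, bf0 = np.polyfit(t[:k], x[:k], 1)
    bu1, bu0 = np.polyfit(t[-k:], x[-k:], 1)
    fu = fraction_unfolded(curve)
    window = min(11, (n // 2) | 1)
    window = max(window, 5)
    dz = _derivative(fu.z, t, window)
    tm0 = float(t[int(np.argmax(dz))])
    p0 = [tm0, 350.0, bf0, bf1, bu0, bu1]

    def model(tt, tm, dh, b_f0, b_f1, b_u0, b_u1):
        return two_state_signal(tt, tm, dh, (b_f0, b_f1), (b_u0, b_u1))

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            x,
            p0=p0,
            bounds=(
                [t[0] - 50.0, 1.0, -np.inf, -np.inf, -np.inf, -np.inf],
                [t[-1] + 50.0, 5000.0, np.inf, np.inf, np.inf, np.inf],
            ),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"{curve.sample_id}: van't Hoff fit failed to converge "
            f"(initial Tm guess {tm0:.1f} degC): {exc}"
        ) from exc
    residual = float(np.linalg.norm(model(t, *popt) - x))
    return VantHoffFit(
        tm=float(popt[0]),
        dh_vh=float(popt[1]),
        folded_baseline=(float(popt[2]), float(popt[3])),
        unfolded_baseline=(float(popt[4]), float(popt[5])),
        residual_norm=residual,
    )


def delta_tm_report(
    results: list[MeltingResult], reference_id: str
) -> pd.DataFrame:
    """Tabulate Tm and its differences against a reference sample.

    For every result the report carries ``dtm_vs_reference = Tm(reference,
    same condition) - Tm(sample)``, so a destabilizing mutation appears as
    a positive decrease, and ``dtm_nonreduced_minus_reduced = Tm(no DTT) -
    Tm(DTT)`` for the sample, the stabilization conferred by the
    N-terminal disulfide cross-link. ND propagates as missing values.
    """
    by_key: dict[tuple[str, str], MeltingResult] = {}
    for r in results:
        by_key[(r.sample_id, r.condition)] = r
    ref_conditions = {c for (s, c) in by_key if s == reference_id}
    if not ref_conditions:
        raise ReportError(f"reference sample {reference_id!r} absent from results")

    rows = []
    for r in results:
        ref = by_key.get((reference_id, r.condition))
        if ref is None:
            raise ReportError(
                f"reference {reference_id!r} has no {r.condition} measurement "
                f"to compare with {r.sample_id}"
            )
        d_ref = (
            ref.tm - r.tm if (ref.tm is not None and r.tm is not None) else None
        )
        non_red = by_key.get((r.sample_id, "non_reduced"))
        red = by_key.get((r.sample_id, "reduced"))
        d_cond = None
        if (
            non_red is not None
            and red is not None
            and non_red.tm is not None
            and red.tm is not None
        ):
            d_cond = non_red.tm - red.tm
        rows.append(
            {
                "sample_id": r.sample_id,
                "condition": r.condition,
                "tm": r.tm if r.tm is not None else np.nan,
                "not_determined": not r.determined,
                "dtm_vs_reference": d_ref if d_ref is not None else np.nan,
                "dtm_nonreduced_minus_reduced": (
                    d_cond if d_cond is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def helicity_222(
    mre222: float,
    n_residues: int,
    temperature: float = 0.0,
    constants: HelicityConstants | None = None,
) -> float:
    """Fraction helix from the 222 nm MRE, clipped to [0, 1].

    ``f_H = (MRE - coil) / (helix - coil)`` with the chain-length-corrected
    helix limit and temperature-dependent coil baseline of ``constants``.
    The convention (the constants) is explicit because published percent
    figures depend on it; a zero-baseline relative change of the raw MRE
    is a different, also common, convention.
    """
    if n_residues < 2:
        raise DomainError("n_residues must be >= 2")
    c = constants or HelicityConstants()
    helix = c.helix_limit(n_residues)
    coil = c.coil_limit(temperature)
    f = (mre222 - coil) / (helix - coil)
    return float(np.clip(f, 0.0, 1.0))


def t_test(group_a, group_b, mode: str = "unpaired") -> TTestResult:
    """Two-sided t-test of two replicate groups.

    ``unpaired`` uses the unequal-variance (Welch) statistic with
    Welch-Satterthwaite degrees of freedom; ``paired`` tests the
    differences. A zero-variance situation (e.g. paired groups differing
    by an exact constant) yields a degenerate result rather than an
    exception.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs at least 2 observations")
    if mode == "paired":
        if a.size != b.size:
            raise SampleSizeError("paired mode requires equal group lengths")
        d = a - b
        if np.var(d, ddof=1) == 0.0:
            return TTestResult(
                t=float("nan"),
                df=float(a.size - 1),
                p=float("nan"),
                mode=mode,
                degenerate=True,
                note="zero variance of paired differences",
            )
        res = stats.ttest_rel(a, b)
        return TTestResult(
            float(res.statistic), float(a.size - 1), float(res.pvalue), mode
        )
    if mode == "unpaired":
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            return TTestResult(
                t=float("nan"),
                df=float("nan"),
                p=float("nan"),
                mode=mode,
                degenerate=True,
                note="zero variance in both groups",
            )
        res = stats.ttest_ind(a, b, equal_var=False)
        return TTestResult(
            float(res.statistic), float(res.df), float(res.pvalue), mode
        )
    raise ValidationError(f"mode must be 'paired' or 'unpaired', got {mode!r}")
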