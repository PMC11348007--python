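"""Spectral parameterization: aperiodic + Gaussian-peak decomposition.

A power spectrum inside the fit range (3-35 Hz by default) is modelled in
log10-power space as

    model(f) = L(f) + sum_n G_n(f)
    L(f)     = b - x * log10(f)                      (aperiodic, 'fixed' mode)
    G_n(f)   = a_n * exp(-(f - mu_n)^2 / (2 sigma_n^2))   (periodic peaks)

where ``b`` is the aperiodic offset, ``x`` the aperiodic exponent (the
negative log-log slope), and each peak has amplitude ``a_n`` (log10-power
above the aperiodic floor), center ``mu_n`` (Hz), and bandwidth ``sigma_n``
(Gaussian SD, Hz).  The fitting procedure mirrors the canonical iterative
algorithm for this decomposition:

1. initial least-squares line in log10-log10 space;
2. robust refit using only points whose positive residual falls below a
   small percentile of the flattened spectrum (removes peak bins);
3. iterative peak extraction from the flattened spectrum: take the largest
   residual maximum, stop when it drops below
   ``max(min_peak_height, peak_threshold * SD(residual))``, seed a Gaussian
   with a half-height width heuristic, subtract, repeat up to
   ``max_n_peaks``;
4. drop peaks hugging the range edge or overlapping a larger peak, then
   jointly refine all retained Gaussians by bounded least squares;
5. subtract the peak model from the original spectrum and refit the
   aperiodic line on the peak-removed spectrum.

Goodness of fit is the squared Pearson correlation between observed and
modelled log10 power on the fit grid, plus the mean absolute error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DataError, FitError, InputError
from .spectral import PowerSpectrum
from .synth import aperiodic_log_power, gaussian

__all__ = [
    "FitSettings",
    "SpectralModel",
    "SpectralFitResults",
    "fit_spectrum",
    "fit_aperiodic_initial",
    "fit_aperiodic_robust",
    "extract_peaks",
    "exponent_table",
    "brainwide_means",
]


@dataclass(frozen=True)
class FitSettings:
    """Settings of the decomposition (defaults are the study configuration).

    ``peak_width_limits`` bounds the full width (2*sigma) of peaks in Hz;
    ``min_peak_height`` is in log10-power units; ``peak_threshold`` is in
    multiples of the flattened spectrum's SD; ``proximity_guard`` is the
    minimum center separation between peaks in units of the larger peak's
    bandwidth; ``robust_percentile`` controls which positive residuals are
    discarded in the robust aperiodic refit.
    """

    freq_range: tuple[float, float] = (3.0, 35.0)
    aperiodic_mode: str = "fixed"
    peak_width_limits: tuple[float, float] = (2.0, 8.0)
    max_n_peaks: int = 8
    min_peak_height: float = 0.05
    peak_threshold: float = 2.0
    proximity_guard: float = 0.75
    edge_guard_bw: float = 1.0
    robust_percentile: float = 2.5

    def __post_init__(self):
        if self.aperiodic_mode != "fixed":
            raise InputError("only the 'fixed' aperiodic mode is supported")
        lo, hi = self.peak_width_limits
        if not (0 < lo < hi):
            raise InputError("peak_width_limits must be positive and ordered")
        if self.freq_range[0] >= self.freq_range[1]:
            raise InputError("freq_range must be an increasing interval")

    @property
    def std_limits(self) -> tuple[float, float]:
        """Gaussian-SD bounds implied by the full-width limits."""
        return (self.peak_width_limits[0] / 2.0, self.peak_width_limits[1] / 2.0)


# ---------------------------------------------------------------------------
# elementary fits (exposed for testing and reuse)
# ---------------------------------------------------------------------------

def _line_fit(log_freqs: np.ndarray, log_power: np.ndarray) -> tuple[float, float]:
    # closed-form least squares for log10P = b - x*log10 f
    slope, intercept = np.polyfit(log_freqs, log_power, 1)
    return float(intercept), float(-slope)


def fit_aperiodic_initial(log_freqs: np.ndarray, log_power: np.ndarray) -> tuple[float, float]:
    """Initial aperiodic fit: least-squares line in log-log space.

    Returns (offset, exponent).  The model is linear in both parameters, so
    the closed-form solution is exact regardless of seeding.
    """
    log_freqs = np.asarray(log_freqs, float)
    log_power = np.asarray(log_power, float)
    if len(log_freqs) < 3:
        raise FitError("need at least 3 frequency points for an aperiodic fit")
    return _line_fit(log_freqs, log_power)


def fit_aperiodic_robust(
    log_freqs: np.ndarray,
    log_power: np.ndarray,
    initial: tuple[float, float] | None = None,
    percentile_thresh: float = 2.5,
) -> tuple[float, float]:
    """Robust aperiodic refit that ignores peak-contaminated bins.

    Residuals above the initial line are clipped at zero and thresholded at
    ``percentile_thresh`` of the clipped distribution; only points at or
    below the threshold (i.e., on or under the line) are refit.  This pulls
    the line to the spectrum's lower envelope, removing the upward exponent
    bias caused by oscillatory peaks.
    """
    log_freqs = np.asarray(log_freqs, float)
    log_power = np.asarray(log_power, float)
    if initial is None:
        initial = fit_aperiodic_initial(log_freqs, log_power)
    b, x = initial
    flat = log_power - (b - x * log_freqs)
    flat = np.where(flat < 0, 0.0, flat)
    thresh = np.percentile(flat, percentile_thresh)
    # fp tolerance so exact (noise-free) lines keep all their points
    mask = flat <= thresh + 1e-12
    if mask.sum() < 2:
        raise FitError("robust refit excluded all frequency points")
    return _line_fit(log_freqs[mask], log_power[mask])


def _guess_std(freqs: np.ndarray, flat: np.ndarray, max_ind: int,
               height: float, settings: FitSettings) -> float:
    """Half-height width heuristic for a peak guess, clipped to limits."""
    half = 0.5 * height
    le = ri = None
    for j in range(max_ind - 1, -1, -1):
        if flat[j] <= half:
            le = freqs[max_ind] - freqs[j]
            break
    for j in range(max_ind + 1, len(flat)):
        if flat[j] <= half:
            ri = freqs[j] - freqs[max_ind]
            break
    sides = [s for s in (le, ri) if s is not None]
    lo, hi = settings.std_limits
    if not sides:
        return (lo + hi) / 2.0
    fwhm = 2.0 * min(sides)
    std = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return float(np.clip(std, lo, hi))


def extract_peaks(freqs: np.ndarray, flattened: np.ndarray,
                  settings: FitSettings | None = None) -> np.ndarray:
    """Iteratively extract Gaussian peaks from a flattened log10 spectrum.

    Returns an (n_peaks, 3) array of (center, amplitude, bandwidth) after
    edge/overlap pruning and joint bounded least-squares refinement.  An
    empty (0, 3) array is a valid result.
    """
    settings = settings or FitSettings()
    freqs = np.asarray(freqs, float)
    flat_iter = np.array(flattened, float, copy=True)
    guesses: list[tuple[float, float, float]] = []

    for _ in range(settings.max_n_peaks):
        max_ind = int(np.argmax(flat_iter))
        max_height = flat_iter[max_ind]
        if max_height <= settings.peak_threshold * np.std(flat_iter):
            break
        if max_height <= settings.min_peak_height:
            break
        cf = float(freqs[max_ind])
        std = _guess_std(freqs, flat_iter, max_ind, max_height, settings)
        guesses.append((cf, float(max_height), std))
        flat_iter -= gaussian(freqs, max_height, cf, std)

    if not guesses:
        return np.empty((0, 3))

    g = np.array(guesses)
    g = _drop_edge_peaks(g, freqs, settings)
    g = _drop_overlapping(g, settings)
    if len(g) == 0:
        return np.empty((0, 3))
    return _refine_gaussians(freqs, np.asarray(flattened, float), g, settings)


def _drop_edge_peaks(g: np.ndarray, freqs: np.ndarray,
                     settings: FitSettings) -> np.ndarray:
    lo, hi = freqs[0], freqs[-1]
    margin = settings.edge_guard_bw * g[:, 2]
    keep = (np.abs(g[:, 0] - lo) > margin) & (np.abs(g[:, 0] - hi) > margin)
    return g[keep]


def _drop_overlapping(g: np.ndarray, settings: FitSettings) -> np.ndarray:
    if len(g) < 2:
        return g
    order = np.argsort(g[:, 0])
    g = g[order]
    drop = np.zeros(len(g), bool)
    for i in range(len(g) - 1):
        lo_hi = g[i, 0] + settings.proximity_guard * g[i, 2]
        hi_lo = g[i + 1, 0] - settings.proximity_guard * g[i + 1, 2]
        if lo_hi > hi_lo:  # bounds overlap: drop the smaller peak
            drop[i if g[i, 1] <= g[i + 1, 1] else i + 1] = True
    return g[~drop]


def _gauss_model(freqs: np.ndarray, params: np.ndarray) -> np.ndarray:
    p = params.reshape(-1, 3)
    if len(p) == 0:
        return np.zeros_like(freqs)
    d = freqs[None, :] - p[:, 0:1]
    return (p[:, 1:2] * np.exp(-d ** 2 / (2 * p[:, 2:3] ** 2))).sum(axis=0)


def _refine_gaussians(freqs: np.ndarray, flat: np.ndarray, g: np.ndarray,
                      settings: FitSettings) -> np.ndarray:
    lo_std, hi_std = settings.std_limits
    f_lo, f_hi = freqs[0], freqs[-1]
    lo, hi, p0 = [], [], []
    for cf, amp, std in g:
        lo += [max(f_lo, cf - 2 * std), 0.0, lo_std]
        hi += [min(f_hi, cf + 2 * std), np.inf, hi_std]
        p0 += [float(np.clip(cf, lo[-3], hi[-3])), amp,
               float(np.clip(std, lo_std, hi_std))]

    def resid(p):
        return _gauss_model(freqs, p) - flat

    def jac(p):
        J = np.empty((len(freqs), len(p)))
        for k in range(len(p) // 3):
            cf, amp, std = p[3 * k:3 * k + 3]
            d = freqs - cf
            e = np.exp(-d ** 2 / (2 * std ** 2))
            J[:, 3 * k] = amp * e * d / std ** 2
            J[:, 3 * k + 1] = e
            J[:, 3 * k + 2] = amp * e * d ** 2 / std ** 3
        return J

    try:
        sol = least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-8, ftol=1e-8,
                            max_nfev=200)
        params = sol.x.reshape(-1, 3)
    except Exception:  # pragma: no cover - pathological optimizer failure
        params = g
    order = np.argsort(params[:, 0])
    return params[order]


def _joint_refine(freqs: np.ndarray, log_f: np.ndarray, y: np.ndarray,
                  b: float, x: float, peaks: np.ndarray,
                  settings: FitSettings) -> tuple[float, float, np.ndarray]:
    """Final joint bounded least squares over aperiodic + peak parameters.

    The staged procedure (robust line, then peaks, then line again) leaves a
    small residual coupling between the aperiodic line and the Gaussian
    tails; one joint refinement starting from the staged solution removes it
    (and recovers noise-free spectra exactly, since the model nests them).
    The number of peaks is fixed at this point.
    """
    if len(peaks) == 0:
        return b, x, peaks
    lo_std, hi_std = settings.std_limits
    f_lo, f_hi = freqs[0], freqs[-1]
    p0 = [b, x]
    lo = [-np.inf, -np.inf]
    hi = [np.inf, np.inf]
    for cf, amp, std in peaks:
        lo += [f_lo, 0.0, lo_std]
        hi += [f_hi, np.inf, hi_std]
        p0 += [float(np.clip(cf, f_lo, f_hi)), max(amp, 0.0),
               float(np.clip(std, lo_std, hi_std))]

    def model(p):
        m = p[0] - p[1] * log_f
        return m + _gauss_model(freqs, p[2:])

    def resid(p):
        return model(p) - y

    def jac(p):
        J = np.empty((len(freqs), len(p)))
        J[:, 0] = 1.0
        J[:, 1] = -log_f
        for k in range((len(p) - 2) // 3):
            cf, amp, std = p[2 + 3 * k:5 + 3 * k]
            d = freqs - cf
            e = np.exp(-d ** 2 / (2 * std ** 2))
            J[:, 2 + 3 * k] = amp * e * d / std ** 2
            J[:, 3 + 3 * k] = e
            J[:, 4 + 3 * k] = amp * e * d ** 2 / std ** 3
        return J

    try:
        sol = least_squares(resid, p0, jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-10, ftol=1e-10,
                            max_nfev=200)
        p = sol.x
    except Exception:  # pragma: no cover
        return b, x, peaks
    new_peaks = p[2:].reshape(-1, 3)
    order = np.argsort(new_peaks[:, 0])
    return float(p[0]), float(p[1]), new_peaks[order]


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

@dataclass
class SpectralFitResults:
    """Fitted decomposition of one power spectrum.

    ``peaks`` is an (n, 3) array of (center Hz, amplitude log10-power,
    bandwidth Hz).  ``model_spectrum`` is the fitted log10 power on the fit
    grid and always equals ``aperiodic + sum of Gaussians`` pointwise.
    """

    offset: float
    exponent: float
    peaks: np.ndarray
    r_squared: float
    mae_error: float
    freqs: np.ndarray
    log_power: np.ndarray
    settings: FitSettings
    aperiodic_only: bool = False
    labels: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def aperiodic_spectrum(self) -> np.ndarray:
        return aperiodic_log_power(self.freqs, self.offset, self.exponent)

    @property
    def peak_spectrum(self) -> np.ndarray:
        total = np.zeros_like(self.freqs)
        for cf, amp, std in self.peaks:
            total += gaussian(self.freqs, amp, cf, std)
        return total

    @property
    def model_spectrum(self) -> np.ndarray:
        return self.aperiodic_spectrum + self.peak_spectrum

    def summary(self) -> str:
        lines = [
            "Spectral parameterization results",
            "=" * 46,
            f"  fit range        {self.settings.freq_range[0]:g}-"
            f"{self.settings.freq_range[1]:g} Hz ({len(self.freqs)} bins)",
            f"  aperiodic offset {self.offset: .4f}  (log10 power)",
            f"  aperiodic exponent {self.exponent: .4f}",
            f"  R^2              {self.r_squared: .4f}",
            f"  MAE              {self.mae_error: .4f}  (log10 power)",
            f"  peaks ({self.n_peaks})",
        ]
        for cf, amp, std in self.peaks:
            lines.append(f"    center {cf:6.2f} Hz  amp {amp:.3f}  "
                         f"bw(SD) {std:.2f} Hz")
        if self.aperiodic_only:
            lines.append("  [aperiodic-only fit: too few bins for peaks]")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs modelled log10 power with the aperiodic component."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.freqs, self.log_power, "k-", lw=1.5, label="observed")
        ax.plot(self.freqs, self.model_spectrum, "r-", lw=1.5, label="model")
        ax.plot(self.freqs, self.aperiodic_spectrum, "b--", lw=1.2,
                label="aperiodic")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("log10 power")
        ax.legend(frameon=False)
        return ax


class SpectralModel:
    """Aperiodic + peaks model of a single power spectrum.

    Parameters
    ----------
    freqs, power :
        Frequency grid (Hz) and linear power values, or a
        :class:`~aperiodic.spectral.PowerSpectrum` as the first argument.
    settings :
        :class:`FitSettings`; defaults follow the study configuration
        (fixed mode, 3-35 Hz, width limits [2, 8] Hz, max 8 peaks, minimum
        peak height 0.05).
    """

    def __init__(self, freqs, power=None, settings: FitSettings | None = None,
                 labels: dict | None = None):
        if isinstance(freqs, PowerSpectrum):
            labels = labels or dict(freqs.labels)
            freqs, power = freqs.freqs, freqs.power
        self.settings = settings or FitSettings()
        self.labels = labels or {}
        freqs = np.asarray(freqs, float)
        power = np.asarray(power, float)
        lo, hi = self.settings.freq_range
        m = (freqs >= lo) & (freqs <= hi)
        self.freqs = freqs[m]
        power = power[m]
        if len(self.freqs) < 3:
            raise InputError(
                f"fewer than 3 frequency bins inside {lo}-{hi} Hz"
            )
        bad = ~(power > 0)
        if np.any(bad):
            raise InputError(
                "nonpositive power inside the fit range at "
                f"{self.freqs[bad].tolist()} Hz"
            )
        self.log_power = np.log10(power)

    def fit(self) -> SpectralFitResults:
        s = self.settings
        log_f = np.log10(self.freqs)
        y = self.log_power

        aperiodic_only = len(self.freqs) <= 3
        if aperiodic_only:
            warnings.warn("too few in-range bins; returning aperiodic-only fit")
            b, x = fit_aperiodic_initial(log_f, y)
            peaks = np.empty((0, 3))
        else:
            init = fit_aperiodic_initial(log_f, y)
            b0, x0 = fit_aperiodic_robust(log_f, y, init, s.robust_percentile)
            flat = y - (b0 - x0 * log_f)
            peaks = extract_peaks(self.freqs, flat, s) if s.max_n_peaks > 0 \
                else np.empty((0, 3))
            peak_model = _gauss_model(self.freqs, peaks.ravel()) if len(peaks) \
                else np.zeros_like(self.freqs)
            # final aperiodic fit on the peak-removed spectrum, then one
            # joint refinement of all parameters together
            b, x = fit_aperiodic_initial(log_f, y - peak_model)
            b, x, peaks = _joint_refine(self.freqs, log_f, y, b, x, peaks, s)

        results = SpectralFitResults(
            offset=b, exponent=x, peaks=peaks,
            r_squared=np.nan, mae_error=np.nan,
            freqs=self.freqs, log_power=y, settings=s,
            aperiodic_only=aperiodic_only, labels=dict(self.labels),
        )
        model = results.model_spectrum
        resid = y - model
        results.mae_error = float(np.abs(resid).mean())
        if np.std(y) == 0 or np.std(model) == 0:
            results.r_squared = 1.0 if np.allclose(y, model) else 0.0
        else:
            results.r_squared = float(np.corrcoef(y, model)[0, 1] ** 2)
        return results


def fit_spectrum(spectrum, power=None,
                 settings: FitSettings | None = None) -> SpectralFitResults:
    """Convenience wrapper: build a :class:`SpectralModel` and fit it."""
    return SpectralModel(spectrum, power, settings=settings).fit()


# ---------------------------------------------------------------------------
# exponent tables
# ---------------------------------------------------------------------------

_CELL_COLS = ["participant", "drug", "prime", "flanker", "period", "electrode"]


def exponent_table(fits, missing=()) -> pd.DataFrame:
    """Long-format exponent table from a collection of labelled fits.

    ``fits`` is an iterable of :class:`SpectralFitResults` whose labels
    carry the cell index (participant, drug, prime, flanker, period,
    electrode).  Missing cells (e.g. no correct trials) are passed through
    as rows with NaN exponent so downstream code can account for them.
    Duplicate cell indices raise :class:`~aperiodic.exceptions.DataError`.
    """
    rows = []
    for fr in fits:
        row = {c: fr.labels.get(c) for c in _CELL_COLS}
        row.update(exponent=fr.exponent, offset=fr.offset,
                   r_squared=fr.r_squared, mae_error=fr.mae_error,
                   n_peaks=fr.n_peaks)
        rows.append(row)
    for mc in missing:
        labels = dict(mc.labels)
        row = {c: labels.get(c) for c in _CELL_COLS}
        row.update(exponent=np.nan, offset=np.nan, r_squared=np.nan,
                   mae_error=np.nan, n_peaks=0)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(subset=_CELL_COLS).any():
        dups = df[df.duplicated(subset=_CELL_COLS, keep=False)]
        raise DataError(f"duplicate cell indices:\n{dups[_CELL_COLS]}")
    return df


def brainwide_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average exponents across electrodes per participant x condition cell.

    Missing electrode cells (NaN) are excluded from the mean; the number of
    electrodes contributing is reported in ``n_electrodes``.
    """
    grp_cols = [c for c in _CELL_COLS if c != "electrode"]
    g = table.groupby(grp_cols, dropna=False)["exponent"]
    out = g.agg(exponent="mean", n_electrodes="count").reset_index()
    return out
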