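"""Synthetic task design and EEG generation with known aperiodic ground truth.

This module emulates a double-blind within-subject pharmaco-EEG experiment:
each participant performs a masked prime / flanker arrow task twice (once
under methylphenidate, once under placebo) while 60-channel EEG is recorded.
Trials come in the four crossings of prime congruency x flanker congruency,
presented equally often and shuffled within each block.  Two analysis
windows are cut per trial: a pre-trial window (-1200..-200 ms before target
onset) and a within-trial window (0..1000 ms after it).

The electrophysiological background is 1/f^x "aperiodic" activity.  The
generator injects a known structure into the exponent x:

    x(cell) = base + subject random effect
              + drug shift           (MPH sessions)
              + period shift         (within-trial windows)
              + prime / flanker shifts (within-trial windows only),

optionally scaled per electrode by a spatial map so that localized effects
can be planted for validating the cluster-based permutation test.  On top of
the aperiodic floor, narrowband oscillatory peaks (alpha by default) are
added.  Data can be produced either as time-domain epochs (trials x
electrodes x samples) or, in fast mode, directly as power spectra drawn from
the log-spectral model; both routes share the same ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

__all__ = [
    "TaskDesign",
    "GroundTruth",
    "EpochSet",
    "generate_design",
    "synth_spectrum",
    "synth_epochs",
    "colored_noise_epochs",
    "cell_exponent",
    "gaussian",
    "aperiodic_log_power",
]

PRIME_LEVELS = ("congruent", "incongruent")
FLANKER_LEVELS = ("congruent", "incongruent")
PERIODS = ("pre_trial", "within_trial")

#: window start relative to target onset, ms
PERIOD_T0_MS = {"pre_trial": -1200, "within_trial": 0}
#: analysis-window length, ms (both periods span 1000 ms)
WINDOW_MS = 1000


@dataclass(frozen=True)
class TaskDesign:
    """Structure of one experimental session.

    Defaults reproduce the study design: 384 trials in 4 blocks, the four
    prime x flanker conditions equally frequent and shuffled within block,
    a 1000-1200 ms jittered response-stimulus interval, and the trial event
    timing (fixation 100 ms, prime 30 ms, mask 30 ms, target 100 ms,
    2000 ms response window).
    """

    n_participants: int = 25
    sessions: tuple[str, str] = ("placebo", "mph")
    n_trials: int = 384
    n_blocks: int = 4
    rsi_jitter_ms: tuple[int, int] = (1000, 1200)
    event_timing_ms: dict = field(
        default_factory=lambda: {
            "fixation": 100,
            "prime": 30,
            "mask": 30,
            "target": 100,
            "response_window": 2000,
        }
    )
    #: probability of a correct response, overall or per (prime, flanker)
    accuracy: float | dict = 1.0

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(p, f) for p in PRIME_LEVELS for f in FLANKER_LEVELS]

    def validate(self) -> None:
        n_cond = len(self.conditions)
        if self.n_trials % self.n_blocks:
            raise ConfigurationError(
                f"n_trials={self.n_trials} not divisible by n_blocks={self.n_blocks}"
            )
        per_block = self.n_trials // self.n_blocks
        if per_block % n_cond:
            raise ConfigurationError(
                f"trials per block ({per_block}) not divisible by the "
                f"{n_cond} conditions"
            )
        if self.n_participants < 1:
            raise ConfigurationError("need at least one participant")
        lo, hi = self.rsi_jitter_ms
        if lo > hi:
            raise ConfigurationError("rsi_jitter_ms interval reversed")

    def accuracy_for(self, prime: str, flanker: str) -> float:
        if isinstance(self.accuracy, dict):
            return float(self.accuracy[(prime, flanker)])
        return float(self.accuracy)


@dataclass(frozen=True)
class GroundTruth:
    """Injected spectral ground truth for synthetic runs.

    Exponent shifts are on the dimensionless aperiodic exponent.  The drug
    and period defaults match brain-wide condition-mean contrasts reported
    for this design in the pharmaco-EEG literature (3.528 vs 3.399 for
    MPH/placebo; 3.525 vs 3.401 for within/pre-trial); prime/flanker shifts
    are configuration with small plausible defaults, applied to within-trial
    windows only.
    ``peaks`` holds (center Hz, amplitude in log10-power units, bandwidth Hz
    as Gaussian SD) triples added to every electrode.  ``spatial_effect_map``
    optionally scales all condition effects per electrode (1.0 = uniform) so
    spatially localized effects can be planted.
    """

    base_offset: float = 1.0
    base_exponent: float = 3.40
    subject_sd_exponent: float = 0.20
    effect_drug: float = 0.129
    effect_period: float = 0.124
    effect_prime: float = 0.026
    effect_flanker: float = 0.02
    peaks: tuple = ((10.0, 0.6, 1.5),)
    noise_sd: float = 0.05
    spatial_effect_map: np.ndarray | None = None

    def validate(self) -> None:
        if self.base_exponent < 0:
            raise ConfigurationError("base_exponent must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for cf, amp, bw in self.peaks:
            if bw <= 0:
                raise ConfigurationError(f"peak bandwidth must be > 0, got {bw}")
            if cf <= 0:
                raise ConfigurationError(f"peak center must be > 0, got {cf}")

    def with_(self, **kwargs) -> "GroundTruth":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Time-domain epochs for one participant-session-period cell.

    ``data`` is trials x electrodes x samples in microvolt-scale units at
    ``srate`` Hz; ``metadata`` has one row per trial with condition labels
    and the correctness flag.
    """

    data: np.ndarray
    srate: float
    window_label: str
    t0_offset_ms: int
    metadata: pd.DataFrame

    def __post_init__(self):
        if self.data.ndim != 3:
            raise InputError("epoch data must be trials x electrodes x samples")
        if len(self.metadata) != self.data.shape[0]:
            raise InputError(
                f"metadata rows ({len(self.metadata)}) != trials "
                f"({self.data.shape[0]})"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# task design
# ---------------------------------------------------------------------------

def generate_design(seed: int, design: TaskDesign | None = None) -> pd.DataFrame:
    """Generate the full trial table for all participants and sessions.

    Within each block every condition appears equally often in a seeded
    random order.  Correctness is Bernoulli per condition (default accuracy
    1.0, so the correct-trials-only filter passes everything unless errors
    are requested).

    Returns a long table with columns participant, session, drug, block,
    trial (0-based within session), prime, flanker, correct, rsi_ms.
    """
    design = design or TaskDesign()
    design.validate()
    rng = np.random.default_rng(seed)

    per_block = design.n_trials // design.n_blocks
    reps = per_block // len(design.conditions)
    block_template = np.repeat(np.arange(len(design.conditions)), reps)

    rows = []
    for p in range(design.n_participants):
        for s_idx, drug in enumerate(design.sessions):
            trial = 0
            for b in range(design.n_blocks):
                order = rng.permutation(block_template)
                for cond_idx in order:
                    prime, flanker = design.conditions[cond_idx]
                    acc = design.accuracy_for(prime, flanker)
                    correct = bool(rng.random() < acc)
                    rsi = int(rng.integers(design.rsi_jitter_ms[0],
                                           design.rsi_jitter_ms[1] + 1))
                    rows.append((p, s_idx, drug, b, trial, prime, flanker,
                                 correct, rsi))
                    trial += 1
    return pd.DataFrame(
        rows,
        columns=["participant", "session", "drug", "block", "trial",
                 "prime", "flanker", "correct", "rsi_ms"],
    )


# ---------------------------------------------------------------------------
# spectral model primitives
# ---------------------------------------------------------------------------

def aperiodic_log_power(freqs: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    """log10 power of the aperiodic component: b - x*log10(f)."""
    return offset - exponent * np.log10(freqs)


def gaussian(freqs: np.ndarray, amplitude: float, center: float, bandwidth: float) -> np.ndarray:
    """Gaussian peak in log10-power units (bandwidth = Gaussian SD in Hz)."""
    return amplitude * np.exp(-((freqs - center) ** 2) / (2.0 * bandwidth ** 2))


def synth_spectrum(
    freqs: np.ndarray,
    offset: float,
    exponent: float,
    peaks=(),
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Draw one power spectrum from the aperiodic-plus-peaks model.

    log10 power = (b - x*log10 f) + sum of Gaussians + N(0, noise_sd) i.i.d.
    per frequency bin; the returned spectrum is in linear power units.

    ``peaks`` is an iterable of (center Hz, amplitude log10-power,
    bandwidth Hz) triples.  ``seed`` may be an int, a Generator, or None.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or len(freqs) == 0:
        raise InputError("freqs must be a non-empty 1-D array")
    if np.any(freqs <= 0):
        raise InputError("all frequencies must be > 0 for the 1/f model")
    if np.any(np.diff(freqs) <= 0):
        raise InputError("freqs must be strictly increasing")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")

    logp = aperiodic_log_power(freqs, offset, exponent)
    for cf, amp, bw in peaks:
        logp = logp + gaussian(freqs, amp, cf, bw)
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        logp = logp + rng.normal(0.0, noise_sd, size=len(freqs))
    return 10.0 ** logp


# ---------------------------------------------------------------------------
# ground-truth exponent per design cell
# ---------------------------------------------------------------------------

def cell_exponent(
    truth: GroundTruth,
    subject_effect: float,
    drug: str,
    period: str,
    prime: str,
    flanker: str,
    spatial_scale: float = 1.0,
) -> float:
    """Target aperiodic exponent for one design cell.

    Drug and period shifts apply to their respective levels; prime and
    flanker shifts apply in the within-trial period only (pre-trial activity
    precedes stimulus onset and cannot carry congruency information).
    ``spatial_scale`` multiplies all condition effects (not the base or the
    subject effect), emulating a localized scalp distribution.
    """
    x = truth.base_exponent + subject_effect
    eff = 0.0
    if drug == "mph":
        eff += truth.effect_drug
    if period == "within_trial":
        eff += truth.effect_period
        if prime == "incongruent":
            eff += truth.effect_prime
        if flanker == "incongruent":
            eff += truth.effect_flanker
    return x + spatial_scale * eff


# ---------------------------------------------------------------------------
# time-domain generation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _welch_response_kernel(n_samples: int, srate: float, nperseg: int,
                           noverlap: int, nfft: int,
                           window: str) -> tuple[np.ndarray, np.ndarray]:
    """Linear response of the default Welch estimator to per-bin power.

    The pooled Welch density estimate of an epoch synthesized from
    independent complex generation bins is, in expectation, a linear map of
    the per-bin generation power: E P = K q.  K is computed column-wise by
    pushing unit cosine/sine basis bins through the exact segment pipeline
    (mean detrend, taper, zero-padded transform, density scaling).
    Returns (welch frequency grid, K).
    """
    from scipy import signal as sps

    win = sps.get_window(window, nperseg)
    scale = 1.0 / (srate * (win ** 2).sum())
    hop = nperseg - noverlap
    n_seg = 1 + (n_samples - nperseg) // hop
    idx = (np.arange(n_seg) * hop)[:, None] + np.arange(nperseg)[None, :]

    def pooled(x):
        seg = x[idx]
        seg = seg - seg.mean(-1, keepdims=True)
        sp = np.fft.rfft(seg * win, n=nfft, axis=-1)
        p = (sp.real ** 2 + sp.imag ** 2) * scale
        p[..., 1:] *= 2.0
        if nfft % 2 == 0:
            p[..., -1] /= 2.0
        return p.mean(0)

    n_rfft = n_samples // 2 + 1
    n_out = nfft // 2 + 1
    K = np.zeros((n_out, n_rfft))
    e = np.zeros(n_rfft, complex)
    for j in range(1, n_rfft):
        e[:] = 0
        e[j] = 1.0
        pc = pooled(np.fft.irfft(e, n=n_samples))
        e[j] = 1j
        ps = pooled(np.fft.irfft(e, n=n_samples))
        K[:, j] = (pc + ps) / 2.0
    fw = np.fft.rfftfreq(nfft, d=1.0 / srate)
    return fw, K


@lru_cache(maxsize=512)
def _calibrated_gen_power(offset: float, exponent: float, n_samples: int,
                          srate: float, nperseg: int, noverlap: int,
                          nfft: int, window: str,
                          cal_lo: float, cal_hi: float,
                          plateau_hz: float) -> np.ndarray:
    """Per-bin generation power q such that the *measured* Welch PSD of the
    synthesized epochs has expected log-log slope/offset (b, x) over the
    calibration band.

    Raw f^(-x) shaping is biased by the estimator itself (segment
    windowing smears steep spectra; per-segment detrending depresses the
    lowest bins), so the generating slope/offset are adjusted by a short
    fixed-point iteration against the analytic Welch response kernel.  The
    generating spectrum is plateaued below ``plateau_hz`` to stop
    out-of-band leakage dominating the lowest in-band bins.
    """
    fw, K = _welch_response_kernel(n_samples, srate, nperseg, noverlap,
                                   nfft, window)
    fgen = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    band = (fw >= cal_lo) & (fw <= cal_hi)
    lf = np.log10(fw[band])

    def qvec(b, x):
        q = np.zeros(len(fgen))
        q[1:] = (10.0 ** (b - x * np.log10(np.maximum(fgen[1:], plateau_hz)))
                 * srate * n_samples / 2.0)
        return q

    bg, xg = offset, exponent
    for _ in range(4):
        out = K @ qvec(bg, xg)
        slope, intercept = np.polyfit(lf, np.log10(out[band]), 1)
        bg += offset - intercept
        xg = max(xg + (exponent - (-slope)), 0.0)
    q = qvec(bg, xg)
    q.setflags(write=False)
    return q


def colored_noise_epochs(
    n_trials: int,
    n_electrodes: int,
    n_samples: int,
    srate: float,
    offset: float,
    exponent: float,
    peaks=(),
    seed=None,
    center_jitter_hz: float = 0.5,
    calibrate: bool = True,
    cal_range: tuple[float, float] = (3.0, 35.0),
) -> np.ndarray:
    """Generate 1/f^x epochs by spectral shaping of white Gaussian noise.

    White complex spectra are scaled so the expected one-sided periodogram
    density equals 10^(b - x*log10 f) and inverse-transformed per trial and
    electrode; phases are uniform, so trials are independent stationary
    Gaussian processes.  With ``calibrate=True`` (default) the generating
    spectrum is additionally corrected for the default Welch estimator's
    own bias, so the slope *measured* by the analysis pipeline over
    ``cal_range`` matches the requested exponent (see
    :func:`_calibrated_gen_power`).

    Oscillatory peaks are then added in the time domain as amplitude- and
    frequency-jittered sinusoids (one per trial and peak), which produces
    Gaussian-like bumps in the trial-averaged PSD rather than a spectral
    line.  Returns trials x electrodes x samples.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_rfft = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, d=1.0 / srate)

    if calibrate:
        # default analysis-path Welch parameters for this srate
        nperseg = int(round(0.25 * srate))
        q = _calibrated_gen_power(
            float(offset), float(exponent), n_samples, float(srate),
            nperseg, nperseg // 2, max(256, nperseg), "hamming",
            float(cal_range[0]), float(cal_range[1]), float(cal_range[0]),
        )
        amp = np.sqrt(q)
    else:
        # raw shaping: expected one-sided periodogram density equals
        # 10^(b - x*log10 f); P = 2|X|^2/(fs*N)
        target = np.zeros(n_rfft)
        target[1:] = 10.0 ** (offset - exponent * np.log10(f[1:]))
        amp = np.sqrt(target * srate * n_samples / 2.0)
        amp[0] = 0.0

    z = rng.standard_normal((n_trials, n_electrodes, n_rfft)) \
        + 1j * rng.standard_normal((n_trials, n_electrodes, n_rfft))
    z *= amp / np.sqrt(2.0)
    z[..., 0] = 0.0
    if n_samples % 2 == 0:
        # Nyquist bin must be real; keep its expected power
        z[..., -1] = z[..., -1].real * np.sqrt(2.0)
    data = np.fft.irfft(z, n=n_samples, axis=-1)

    if peaks:
        t = np.arange(n_samples) / srate
        floor = 10.0 ** aperiodic_log_power(f[1:], offset, exponent)
        for cf, a_log, bw in peaks:
            # sinusoid amplitude chosen so the trial-averaged PSD bump at the
            # center frequency is ~10^a_log times the aperiodic floor there
            p_floor = np.interp(cf, f[1:], floor)
            # power spreads over ~ sqrt(2*pi)*sigma_eff Hz of the averaged PSD
            sigma_eff = max(bw, center_jitter_hz)
            extra = p_floor * (10.0 ** a_log - 1.0) * np.sqrt(2 * np.pi) * sigma_eff
            a_sin = np.sqrt(2.0 * max(extra, 0.0))
            cfs = cf + center_jitter_hz * rng.standard_normal((n_trials, n_electrodes))
            phases = rng.uniform(0, 2 * np.pi, (n_trials, n_electrodes))
            amps = a_sin * np.abs(1.0 + 0.3 * rng.standard_normal((n_trials, n_electrodes)))
            data += amps[..., None] * np.sin(
                2 * np.pi * cfs[..., None] * t[None, None, :] + phases[..., None]
            )
    return data


def synth_epochs(
    trial_table: pd.DataFrame,
    truth: GroundTruth,
    window_label: str,
    seed,
    subject_effect: float = 0.0,
    n_electrodes: int = 60,
    srate: float = 256.0,
    min_samples: int = 96,
) -> EpochSet:
    """Generate epochs for one participant-session table and one period.

    ``trial_table`` holds the trials of a single participant x session (as
    produced by :func:`generate_design`, already filtered if desired).  Each
    trial's epoch is spectrally shaped noise at that cell's ground-truth
    exponent (see :func:`cell_exponent`), with the configured oscillatory
    peaks.  Both periods span 1000 ms; the pre-trial window is stationary
    background (first trials of a block are not treated specially).
    """
    if window_label not in PERIODS:
        raise InputError(f"unknown window_label {window_label!r}")
    truth.validate()
    n_samples = int(round(WINDOW_MS / 1000.0 * srate))
    if n_samples < min_samples:
        raise ConfigurationError(
            f"window of {n_samples} samples is shorter than two Welch "
            f"segments ({min_samples} samples)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    smap = truth.spatial_effect_map
    if smap is not None:
        smap = np.asarray(smap, float)
        if len(smap) != n_electrodes:
            raise ConfigurationError(
                "spatial_effect_map length must equal n_electrodes"
            )

    n_trials = len(trial_table)
    data = np.empty((n_trials, n_electrodes, n_samples))
    drugs = trial_table["drug"].to_numpy()
    primes = trial_table["prime"].to_numpy()
    flankers = trial_table["flanker"].to_numpy()

    # group electrodes by identical target exponent to batch the generation
    for i in range(n_trials):
        scales = smap if smap is not None else np.ones(n_electrodes)
        exps = np.array([
            cell_exponent(truth, subject_effect, drugs[i], window_label,
                          primes[i], flankers[i], spatial_scale=s)
            for s in scales
        ])
        for x in np.unique(exps):
            idx = np.flatnonzero(exps == x)
            data[i, idx] = colored_noise_epochs(
                1, len(idx), n_samples, srate, truth.base_offset, x,
                peaks=truth.peaks, seed=rng,
            )[0]
    return EpochSet(
        data=data,
        srate=srate,
        window_label=window_label,
        t0_offset_ms=PERIOD_T0_MS[window_label],
        metadata=trial_table.reset_index(drop=True),
    )
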