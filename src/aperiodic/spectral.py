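"""Welch power spectral density estimation per design cell.

PSDs are estimated with the Welch method using a 0.25-second Hamming window
and 50% overlap.  At 256 Hz that native segment (64 samples) gives only 4-Hz
resolution, too coarse for a multi-peak spectral model, so segments are
zero-padded to ``n_fft = max(256, nperseg)`` by default, yielding a 1-Hz
grid (33 bins inside the 3-35 Hz fit range).  Segments are mean-detrended
before tapering.

Per analysis cell (participant x electrode x condition x period) the
segments of all correct trials are pooled and averaged into a single
spectrum; when every trial contributes the same number of segments this is
identical to averaging per-trial Welch spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError, InputError
from .synth import EpochSet

__all__ = [
    "WelchSettings",
    "PowerSpectrum",
    "MissingCell",
    "welch_psd",
    "pooled_psd",
    "condition_psd",
    "spectra_to_frame",
]


@dataclass(frozen=True)
class WelchSettings:
    """Welch estimator configuration (defaults follow the analysis recipe)."""

    segment_s: float = 0.25
    window: str = "hamming"
    overlap_fraction: float = 0.5
    srate: float = 256.0
    n_fft: int | None = None  # None -> max(256, nperseg)

    def __post_init__(self):
        if not (0 <= self.overlap_fraction < 1):
            raise ConfigurationError("overlap_fraction must be in [0, 1)")
        if self.nperseg < 8:
            raise ConfigurationError("segment must be at least 8 samples")
        if self.nfft < self.nperseg:
            raise ConfigurationError("n_fft must be >= segment length")

    @property
    def nperseg(self) -> int:
        return int(round(self.segment_s * self.srate))

    @property
    def noverlap(self) -> int:
        return int(round(self.overlap_fraction * self.nperseg))

    @property
    def hop(self) -> int:
        return self.nperseg - self.noverlap

    @property
    def nfft(self) -> int:
        return self.n_fft if self.n_fft is not None else max(256, self.nperseg)

    def n_segments(self, n_samples: int) -> int:
        if n_samples < self.nperseg:
            return 0
        return 1 + (n_samples - self.nperseg) // self.hop


@dataclass
class PowerSpectrum:
    """One PSD: frequency grid (Hz) and linear power density (uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments_averaged: int = 1
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise InputError("freqs and power must have identical shape")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise InputError("power must be finite and nonnegative")

    def in_range(self, lo: float, hi: float) -> "PowerSpectrum":
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[m], self.power[m],
                             self.n_segments_averaged, dict(self.labels))


@dataclass(frozen=True)
class MissingCell:
    """Explicit marker for a design cell with no usable trials."""

    labels: tuple
    reason: str = "no correct trials"


def welch_psd(x: np.ndarray, settings: WelchSettings | None = None,
              labels: dict | None = None) -> PowerSpectrum:
    """Welch PSD of a single signal (density scaling, one-sided).

    Mean-detrended, Hamming-tapered, 50%-overlapping modified periodograms
    are averaged; for white noise of variance s^2 the spectrum integrates
    to approximately s^2.
    """
    settings = settings or WelchSettings()
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise InputError("welch_psd expects a 1-D signal")
    if len(x) < settings.nperseg:
        raise InputError(
            f"signal of {len(x)} samples is shorter than one segment "
            f"({settings.nperseg} samples)"
        )
    freqs, power = sps.welch(
        x, fs=settings.srate, window=settings.window,
        nperseg=settings.nperseg, noverlap=settings.noverlap,
        nfft=settings.nfft, detrend="constant", scaling="density",
    )
    return PowerSpectrum(freqs, power, settings.n_segments(len(x)),
                         labels or {})


def pooled_psd(trials: np.ndarray, settings: WelchSettings | None = None,
               labels: dict | None = None) -> PowerSpectrum:
    """Welch PSD pooling segments across trials (trials x samples input).

    Every segment of every trial is mean-detrended, tapered and transformed,
    and all modified periodograms are averaged together.  With equal trial
    lengths this equals the plain mean of per-trial Welch spectra.
    """
    settings = settings or WelchSettings()
    trials = np.atleast_2d(np.asarray(trials, float))
    n_samples = trials.shape[-1]
    n_seg = settings.n_segments(n_samples)
    if n_seg == 0:
        raise InputError("trials shorter than one Welch segment")

    win = sps.get_window(settings.window, settings.nperseg)
    scale = 1.0 / (settings.srate * (win ** 2).sum())
    starts = np.arange(n_seg) * settings.hop
    # segments: (trials, n_seg, nperseg)
    idx = starts[:, None] + np.arange(settings.nperseg)[None, :]
    seg = trials[:, idx]
    seg = seg - seg.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(seg * win, n=settings.nfft, axis=-1)
    p = (spec.real ** 2 + spec.imag ** 2) * scale
    p[..., 1:] *= 2.0
    if settings.nfft % 2 == 0:
        p[..., -1] /= 2.0
    power = p.reshape(-1, p.shape[-1]).mean(axis=0)
    freqs = np.fft.rfftfreq(settings.nfft, d=1.0 / settings.srate)
    return PowerSpectrum(freqs, power, n_seg * trials.shape[0], labels or {})


def condition_psd(
    epochs: EpochSet,
    settings: WelchSettings | None = None,
    electrode_names: list[str] | None = None,
) -> tuple[list[PowerSpectrum], list[MissingCell]]:
    """Per-cell PSDs for one participant-session EpochSet.

    For each electrode x prime x flanker cell, segments of all *correct*
    trials are pooled into one spectrum.  Cells without any correct trial
    are returned as explicit :class:`MissingCell` markers, never as NaN
    spectra.
    """
    settings = settings or WelchSettings()
    meta = epochs.metadata
    if "correct" not in meta.columns:
        raise InputError("trial metadata lacks a 'correct' column")
    if electrode_names is None:
        electrode_names = [f"E{i + 1:02d}" for i in range(epochs.n_electrodes)]
    if len(electrode_names) != epochs.n_electrodes:
        raise InputError("electrode_names length mismatch")

    spectra: list[PowerSpectrum] = []
    missing: list[MissingCell] = []
    base_labels = {
        "participant": meta["participant"].iloc[0] if len(meta) else None,
        "drug": meta["drug"].iloc[0] if len(meta) else None,
        "period": epochs.window_label,
    }
    for (prime, flanker), grp in _iter_condition_groups(meta):
        keep = grp.index[grp["correct"].astype(bool)].to_numpy()
        for e, name in enumerate(electrode_names):
            labels = dict(base_labels, electrode=name, prime=prime,
                          flanker=flanker)
            if len(keep) == 0:
                missing.append(MissingCell(tuple(sorted(labels.items()))))
                continue
            ps = pooled_psd(epochs.data[keep, e, :], settings, labels)
            spectra.append(ps)
    return spectra, missing


def _iter_condition_groups(meta: pd.DataFrame):
    # cells are the conditions the session actually contains
    conds = (meta[["prime", "flanker"]].drop_duplicates()
             .sort_values(["prime", "flanker"]))
    for prime, flanker in conds.itertuples(index=False):
        grp = meta[(meta["prime"] == prime) & (meta["flanker"] == flanker)]
        yield (prime, flanker), grp


def spectra_to_frame(spectra: list[PowerSpectrum]) -> pd.DataFrame:
    """Long-format table (one row per spectrum x frequency) for serialization."""
    frames = []
    for ps in spectra:
        df = pd.DataFrame({"freq": ps.freqs, "power": ps.power})
        for k, v in ps.labels.items():
            df[k] = v
        df["n_segments"] = ps.n_segments_averaged
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["freq", "power", "n_segments"])
    return pd.concat(frames, ignore_index=True)


def frame_to_spectra(frame: pd.DataFrame) -> list[PowerSpectrum]:
    """Inverse of :func:`spectra_to_frame` (round-trip reader)."""
    label_cols = [c for c in frame.columns
                  if c not in ("freq", "power", "n_segments")]
    out = []
    for key, grp in frame.groupby(label_cols, sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        out.append(PowerSpectrum(
            grp["freq"].to_numpy(), grp["power"].to_numpy(),
            int(grp["n_segments"].iloc[0]),
            dict(zip(label_cols, key)),
        ))
    return out
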