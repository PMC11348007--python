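"""Study-scale validation harnesses.

Two quantities summarize how the pipeline behaves at the scale of the
original study design, both computed from scratch by simulation:

* :func:`fit_quality_ensemble` — mean R^2 of the spectral parameterization
  over an ensemble of synthetic spectra drawn from the aperiodic-plus-peaks
  model with realistic parameter ranges and measurement noise.
* :func:`cluster_fwer` — empirical family-wise false-positive rate of the
  electrode-space cluster-based permutation test under a global null
  (paired exchangeable noise, no true effect anywhere).
"""

from __future__ import annotations

import numpy as np

from .specparam import FitSettings, SpectralModel
from .stats import MontageAdjacency, cluster_permutation_test, equidistant_montage
from .synth import synth_spectrum

__all__ = ["fit_quality_ensemble", "cluster_fwer"]


def fit_quality_ensemble(
    n_spectra: int = 1000,
    seed: int = 0,
    noise_sd: float = 0.05,
    freqs: np.ndarray | None = None,
    settings: FitSettings | None = None,
) -> dict:
    """Mean R^2 of spectral fits over a random synthetic ensemble.

    Each spectrum draws offset ~ U(-1, 2), exponent ~ U(0.5, 3.5) and 1-3
    Gaussian peaks (centers inside the fit band with a 2-Hz margin,
    amplitudes U(0.1, 0.8) log10-power, bandwidths U(1, 3) Hz), plus i.i.d.
    log-power noise of SD ``noise_sd`` per bin, and is fitted with the
    default settings.  Returns summary statistics of the fit quality.
    """
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = np.arange(1.0, 46.0)
    settings = settings or FitSettings()
    lo, hi = settings.freq_range
    r2 = np.empty(n_spectra)
    err = np.empty(n_spectra)
    for i in range(n_spectra):
        b = rng.uniform(-1.0, 2.0)
        x = rng.uniform(0.5, 3.5)
        peaks = [(rng.uniform(lo + 2, hi - 2), rng.uniform(0.1, 0.8),
                  rng.uniform(1.0, 3.0))
                 for _ in range(int(rng.integers(1, 4)))]
        power = synth_spectrum(freqs, b, x, peaks=peaks, noise_sd=noise_sd,
                               seed=rng)
        res = SpectralModel(freqs, power, settings=settings).fit()
        r2[i] = res.r_squared
        err[i] = res.mae_error
    return {
        "mean_r2": float(r2.mean()),
        "median_r2": float(np.median(r2)),
        "min_r2": float(r2.min()),
        "mean_mae": float(err.mean()),
        "n": n_spectra,
    }


def cluster_fwer(
    n_replicates: int = 2000,
    n_subjects: int = 25,
    n_electrodes: int = 60,
    n_permutations: int = 1000,
    sample_alpha: float = 0.005,
    alpha: float = 0.05,
    seed: int = 0,
    stat: str = "F",
    adjacency: MontageAdjacency | None = None,
) -> dict:
    """Family-wise false-positive rate of the cluster test under the null.

    Each replicate draws two paired conditions of i.i.d. standard-normal
    noise (exchangeable: no effect anywhere) and runs the cluster-based
    permutation test through the public inference path.  Returns the
    fraction of replicates with at least one cluster flagged significant,
    plus its Monte-Carlo standard error.
    """
    adjacency = adjacency or equidistant_montage(n_electrodes)
    ss = np.random.SeedSequence(seed)
    data_rng = np.random.default_rng(ss.spawn(1)[0])
    perm_seeds = ss.generate_state(n_replicates)
    hits = 0
    for r in range(n_replicates):
        a = data_rng.standard_normal((n_subjects, n_electrodes))
        b = data_rng.standard_normal((n_subjects, n_electrodes))
        res = cluster_permutation_test(
            a, b, adjacency, stat=stat, sample_alpha=sample_alpha,
            n_permutations=n_permutations, alpha=alpha,
            seed=int(perm_seeds[r]),
        )
        hits += bool(res.significant_clusters)
    fwer = hits / n_replicates
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {"fwer": fwer, "n_false_positive": hits, "mc_se": mc_se,
            "n": n_replicates}
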