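"""End-to-end orchestration: simulate -> PSD -> fit -> stats -> report.

A run is described by a :class:`RunConfig` (fully serializable to YAML,
written verbatim into the output directory) and produces a fixed on-disk
layout::

    outdir/
      config.yaml     run configuration (verbatim)
      trials.tsv      simulated trial table
      epochs/         epoch bundles (epoch mode only, optional)
      spectra.tsv     per-cell power spectra (long format)
      fits.tsv        per-cell spectral fits (offset, exponent, R^2, peaks)
      exponents.tsv   long-format exponent table
      anova.tsv       omnibus + follow-up ANOVA tables
      clusters.tsv    cluster-based permutation test summaries
      report.md       human-readable report

Two generation modes share the same ground truth: ``spectra`` draws each
cell's power spectrum directly from the log-spectral model (fast; the
default), while ``epochs`` synthesizes time-domain trials and estimates
Welch PSDs from them (slow; exercises the full spectral path).  Every
stage derives its RNG stream from the run seed, so a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .exceptions import InputError
from .spectral import WelchSettings, condition_psd, spectra_to_frame
from .specparam import (FitSettings, SpectralModel, brainwide_means,
                        exponent_table)
from .stats import (AnovaResults, MontageAdjacency, electrodewise_condition_tests,
                    equidistant_montage, follow_up_anovas, rm_anova)
from .synth import (GroundTruth, PERIODS, TaskDesign, cell_exponent,
                    generate_design, synth_epochs, synth_spectrum)

logger = logging.getLogger("aperiodic")

__all__ = ["StatsSettings", "RunConfig", "RunReport", "run_pipeline",
           "filter_correct"]


@dataclass(frozen=True)
class StatsSettings:
    """Inference configuration for the stats stage."""

    sample_alpha_f: float = 0.005
    sample_alpha_t: float = 0.05
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    cluster_stat: str = "paired_t"


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    mode: str = "spectra"  # 'spectra' (fast) | 'epochs' (time-domain)
    n_electrodes: int = 60
    design: TaskDesign = field(default_factory=TaskDesign)
    truth: GroundTruth = field(default_factory=GroundTruth)
    welch: WelchSettings = field(default_factory=WelchSettings)
    fit: FitSettings = field(default_factory=FitSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)
    freq_lo: float = 1.0
    freq_hi: float = 45.0
    freq_step: float = 1.0
    save_epochs: bool = False
    stages: tuple = ("simulate", "spectra", "fit", "anova", "cluster",
                     "report")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + 1e-9, self.freq_step)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        t = d["truth"]
        if t["spatial_effect_map"] is not None:
            t["spatial_effect_map"] = [float(v) for v in t["spatial_effect_map"]]
        t["peaks"] = [list(p) for p in t["peaks"]]
        d["design"]["sessions"] = list(d["design"]["sessions"])
        d["design"]["rsi_jitter_ms"] = list(d["design"]["rsi_jitter_ms"])
        d["fit"]["freq_range"] = list(d["fit"]["freq_range"])
        d["fit"]["peak_width_limits"] = list(d["fit"]["peak_width_limits"])
        d["stages"] = list(d["stages"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        def build(klass, key, tuple_keys=()):
            sub = dict(d.get(key) or {})
            for k in tuple_keys:
                if k in sub and sub[k] is not None:
                    sub[k] = tuple(sub[k])
            return klass(**sub)

        design = build(TaskDesign, "design", ("sessions", "rsi_jitter_ms"))
        truth_d = dict(d.get("truth") or {})
        if "peaks" in truth_d:
            truth_d["peaks"] = tuple(tuple(p) for p in truth_d["peaks"])
        if truth_d.get("spatial_effect_map") is not None:
            truth_d["spatial_effect_map"] = np.asarray(
                truth_d["spatial_effect_map"], float)
        truth = GroundTruth(**truth_d)
        welch = build(WelchSettings, "welch")
        fit = build(FitSettings, "fit", ("freq_range", "peak_width_limits"))
        stats = build(StatsSettings, "stats")
        top = {k: v for k, v in d.items()
               if k not in ("design", "truth", "welch", "fit", "stats")}
        if "stages" in top:
            top["stages"] = tuple(top["stages"])
        return cls(design=design, truth=truth, welch=welch, fit=fit,
                   stats=stats, **top)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(aio.read_yaml(path) or {})


@dataclass
class RunReport:
    """Aggregated run outcome; every number traces to a stage output file."""

    n_trials_total: int
    n_trials_correct: int
    n_cells_fit: int
    n_cells_missing: int
    condition_means: pd.DataFrame
    anova: AnovaResults
    followups: dict
    cluster_summary: pd.DataFrame
    recovery: dict
    outdir: Path

    def to_markdown(self) -> str:
        md = ["# Synthetic aperiodic-exponent run report", ""]
        md += [f"- trials simulated: {self.n_trials_total}",
               f"- trials surviving correct-only filter: {self.n_trials_correct}",
               f"- spectra fitted: {self.n_cells_fit}"
               f" (missing cells: {self.n_cells_missing})", ""]
        md += ["## Condition means (brain-wide exponent, mean +/- SEM)", ""]
        cm = self.condition_means.copy()
        cm["mean +/- SEM"] = cm.apply(
            lambda r: f"{r['mean']:.3f} +/- {r['sem']:.3f}", axis=1)
        md += [cm[["drug", "period", "prime", "flanker", "mean +/- SEM"]]
               .to_markdown(index=False), ""]
        md += ["## Omnibus within-subject ANOVA", "", "```",
               self.anova.summary(), "```", ""]
        for lev, res in self.followups.items():
            md += [f"## Follow-up ANOVA: period = {lev} "
                   "(Bonferroni-corrected p)", "", "```", res.summary(),
                   "```", ""]
        md += ["## Cluster-based permutation tests (MPH - placebo)", ""]
        if len(self.cluster_summary):
            md += [self.cluster_summary.to_markdown(index=False), ""]
        else:
            md += ["no suprathreshold clusters", ""]
        md += ["## Ground truth vs recovered (synthetic run)", ""]
        for k, v in self.recovery.items():
            md += [f"- {k}: truth {v[0]:+.3f}, recovered {v[1]:+.3f}"]
        md += [""]
        return "\n".join(md)


def filter_correct(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Keep correct-response trials only (the exponent analysis convention).

    Removal counts are logged per participant x session cell; an
    all-incorrect table returns empty with a warning.
    """
    if "correct" not in trial_table.columns:
        raise InputError("trial table lacks a 'correct' column")
    keep = trial_table[trial_table["correct"].astype(bool)]
    removed = len(trial_table) - len(keep)
    if removed:
        per_cell = (trial_table[~trial_table["correct"].astype(bool)]
                    .groupby(["participant", "session"]).size())
        logger.info("correct-only filter removed %d trials:\n%s", removed,
                    per_cell.to_string())
    if len(keep) == 0 and len(trial_table) > 0:
        logger.warning("correct-only filter removed every trial")
    return keep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("design", "subjects", "data", "cluster")
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s) for n, s in zip(names, state)}


def _spatial_scale(truth: GroundTruth, n_electrodes: int) -> np.ndarray:
    if truth.spatial_effect_map is None:
        return np.ones(n_electrodes)
    smap = np.asarray(truth.spatial_effect_map, float)
    if len(smap) != n_electrodes:
        raise InputError("spatial_effect_map length != n_electrodes")
    return smap


def _expected_cells(cfg: RunConfig, all_trials: pd.DataFrame,
                    correct: pd.DataFrame) -> list:
    """Cells of the full design with zero correct trials -> missing markers."""
    from .spectral import MissingCell

    names = [f"E{i + 1:02d}" for i in range(cfg.n_electrodes)]
    have = set(map(tuple, correct[["participant", "drug", "prime",
                                   "flanker"]].drop_duplicates().to_numpy()))
    missing = []
    for key in map(tuple, all_trials[["participant", "drug", "prime",
                                      "flanker"]].drop_duplicates().to_numpy()):
        if key in have:
            continue
        p, drug, prime, flanker = key
        for period in PERIODS:
            for ename in names:
                labels = (("drug", drug), ("electrode", ename),
                          ("flanker", flanker), ("participant", p),
                          ("period", period), ("prime", prime))
                missing.append(MissingCell(labels))
    return missing


def _simulate_spectra(cfg: RunConfig, trials: pd.DataFrame,
                      subj_eff: np.ndarray, seed: int) -> pd.DataFrame:
    """Fast mode: draw one spectrum per cell directly from the model."""
    rng = np.random.default_rng(seed)
    freqs = cfg.freqs
    smap = _spatial_scale(cfg.truth, cfg.n_electrodes)
    names = [f"E{i + 1:02d}" for i in range(cfg.n_electrodes)]
    counts = (trials.groupby(["participant", "drug", "prime", "flanker"])
              .size())
    frames = []
    for (p, drug, prime, flanker), n_corr in counts.items():
        for period in PERIODS:
            for e, ename in enumerate(names):
                x = cell_exponent(cfg.truth, subj_eff[p], drug, period,
                                  prime, flanker, spatial_scale=smap[e])
                power = synth_spectrum(freqs, cfg.truth.base_offset, x,
                                       peaks=cfg.truth.peaks,
                                       noise_sd=cfg.truth.noise_sd, seed=rng)
                frames.append(pd.DataFrame({
                    "participant": p, "drug": drug, "prime": prime,
                    "flanker": flanker, "period": period,
                    "electrode": ename, "n_segments": int(n_corr),
                    "freq": freqs, "power": power,
                }))
    return pd.concat(frames, ignore_index=True)


def _simulate_epoch_spectra(cfg: RunConfig, trials: pd.DataFrame,
                            subj_eff: np.ndarray, seed: int,
                            outdir: Path) -> tuple[pd.DataFrame, list]:
    """Epoch mode: synthesize trials, then Welch PSD per cell."""
    rng = np.random.default_rng(seed)
    all_spectra = []
    all_missing = []
    for (p, drug), grp in trials.groupby(["participant", "drug"]):
        for period in PERIODS:
            es = synth_epochs(grp, cfg.truth, period, rng,
                              subject_effect=subj_eff[p],
                              n_electrodes=cfg.n_electrodes,
                              srate=cfg.welch.srate)
            if cfg.save_epochs:
                aio.write_epochs(es, outdir / "epochs",
                                 f"sub{p:02d}_{drug}_{period}")
            spectra, missing = condition_psd(es, cfg.welch)
            all_spectra.extend(spectra)
            all_missing.extend(missing)
    return spectra_to_frame(all_spectra), all_missing


def _fit_stage(cfg: RunConfig, spectra: pd.DataFrame,
               missing=()) -> pd.DataFrame:
    cell_cols = ["participant", "drug", "prime", "flanker", "period",
                 "electrode"]
    fits = []
    for key, grp in spectra.groupby(cell_cols, sort=True):
        labels = dict(zip(cell_cols, key))
        res = SpectralModel(grp["freq"].to_numpy(), grp["power"].to_numpy(),
                            settings=cfg.fit, labels=labels).fit()
        fits.append(res)
    table = exponent_table(fits, missing)
    peak_rows = []
    for fr in fits:
        flat = {}
        for i, (cf, amp, bw) in enumerate(fr.peaks):
            flat[f"peak{i + 1}_cf"] = cf
            flat[f"peak{i + 1}_amp"] = amp
            flat[f"peak{i + 1}_bw"] = bw
        peak_rows.append(flat)
    peaks_df = pd.DataFrame(peak_rows)
    return pd.concat([table.reset_index(drop=True), peaks_df], axis=1)


def _condition_means(bw: pd.DataFrame) -> pd.DataFrame:
    g = (bw.groupby(["drug", "period", "prime", "flanker"])["exponent"]
         .agg(["mean", "sem"]).reset_index())
    return g


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Execute the configured stages and write the on-disk layout."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aio.write_yaml(config.to_dict(), outdir / "config.yaml")
    seeds = _stage_seeds(config.seed)
    logger.info("run seed=%d stage seeds=%s", config.seed, seeds)

    trials = generate_design(seeds["design"], config.design)
    aio.write_table(trials, outdir / "trials.tsv")
    correct = filter_correct(trials)

    rng_subj = np.random.default_rng(seeds["subjects"])
    subj_eff = rng_subj.normal(0.0, config.truth.subject_sd_exponent,
                               config.design.n_participants)

    if config.mode == "spectra":
        spectra = _simulate_spectra(config, correct, subj_eff, seeds["data"])
        missing = _expected_cells(config, trials, correct)
    elif config.mode == "epochs":
        spectra, missing = _simulate_epoch_spectra(config, correct, subj_eff,
                                                   seeds["data"], outdir)
    else:
        raise InputError(f"unknown mode {config.mode!r}")
    aio.write_table(spectra, outdir / "spectra.tsv")

    fits = _fit_stage(config, spectra, missing)
    aio.write_table(fits, outdir / "fits.tsv")
    exponents = fits[["participant", "drug", "prime", "flanker", "period",
                      "electrode", "exponent", "r_squared"]]
    aio.write_table(exponents, outdir / "exponents.tsv")

    bw = brainwide_means(exponents)
    anova = rm_anova(bw, factors=["period", "drug", "prime", "flanker"])
    followups = follow_up_anovas(bw, split_by="period")
    anova_df = anova.to_frame()
    anova_df.insert(0, "analysis", "omnibus")
    fu_frames = [anova_df]
    for lev, res in followups.items():
        f = res.to_frame()
        f.insert(0, "analysis", f"period={lev}")
        fu_frames.append(f)
    aio.write_table(pd.concat(fu_frames, ignore_index=True),
                    outdir / "anova.tsv")

    cluster_frames = []
    if "cluster" in config.stages:
        adjacency = equidistant_montage(config.n_electrodes)
        ctests = electrodewise_condition_tests(
            exponents, adjacency, stat=config.stats.cluster_stat,
            sample_alpha=(config.stats.sample_alpha_f
                          if config.stats.cluster_stat == "F"
                          else config.stats.sample_alpha_t),
            n_permutations=config.stats.n_permutations,
            alpha=config.stats.cluster_alpha, seed=seeds["cluster"],
        )
        for (prime, flanker, period), res in ctests.items():
            f = res.to_frame()
            f.insert(0, "period", period)
            f.insert(0, "flanker", flanker)
            f.insert(0, "prime", prime)
            cluster_frames.append(f)
    cluster_summary = (pd.concat(cluster_frames, ignore_index=True)
                       if cluster_frames else pd.DataFrame(
                           columns=["prime", "flanker", "period",
                                    "electrodes", "n_electrodes", "mass",
                                    "p_value", "sign", "significant"]))
    aio.write_table(cluster_summary, outdir / "clusters.tsv")

    cm = _condition_means(bw)
    piv = bw.pivot_table(index="participant", columns="drug",
                         values="exponent")
    drug_rec = float(piv["mph"].mean() - piv["placebo"].mean())
    pivp = bw.pivot_table(index="participant", columns="period",
                          values="exponent")
    per_rec = float(pivp["within_trial"].mean() - pivp["pre_trial"].mean())
    # marginal period contrast also carries half of the within-trial-only
    # prime/flanker shifts; scale everything by the mean spatial map
    sc = float(np.mean(_spatial_scale(config.truth, config.n_electrodes)))
    per_truth = sc * (config.truth.effect_period
                      + (config.truth.effect_prime
                         + config.truth.effect_flanker) / 2.0)
    recovery = {
        "drug contrast (MPH - placebo)": (sc * config.truth.effect_drug,
                                          drug_rec),
        "period contrast (within - pre)": (per_truth, per_rec),
    }

    report = RunReport(
        n_trials_total=len(trials), n_trials_correct=len(correct),
        n_cells_fit=int(fits["exponent"].notna().sum()),
        n_cells_missing=int(fits["exponent"].isna().sum()),
        condition_means=cm, anova=anova, followups=followups,
        cluster_summary=cluster_summary, recovery=recovery, outdir=outdir,
    )
    (outdir / "report.md").write_text(report.to_markdown())
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return report
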