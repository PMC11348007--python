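# aperiodic

Aperiodic (1/f) EEG analysis for within-subject pharmaco-EEG designs:
spectral parameterization of power spectra into aperiodic and oscillatory
components, plus the inferential machinery to test condition effects on the
aperiodic exponent — electrode-space cluster-based permutation tests and a
fully within-subject factorial ANOVA.  A synthetic-data generator with
known ground truth makes every stage testable end to end without access to
raw recordings.

## The scientific problem

The broadband background of the EEG power spectrum falls off as a power
law, `P(f) ~ 1/f^x`.  The exponent `x` (the negative slope in log-log
space) is a compact index of "cortical noise": flatter spectra (small `x`)
indicate noisier, more desynchronized population activity; steeper spectra
indicate stronger noise suppression.  Pharmaco-EEG studies of
catecholaminergic drugs such as methylphenidate (MPH) ask whether the drug
shifts this exponent, brain-wide and electrode-by-electrode, across the
conditions of a masked prime / flanker conflict task measured in pre-trial
(−1200..−200 ms) and within-trial (0..1000 ms) windows.

The spectrum inside the 3–35 Hz analysis band is modelled in log10-power
space as an aperiodic component plus Gaussian oscillatory peaks:

    PSD(f) = L(f) + Σₙ Gₙ(f)
    L(f)   = b − x·log10(f)
    Gₙ(f)  = aₙ · exp(−(f − μₙ)² / (2σₙ²))

with offset `b`, exponent `x`, and per-peak amplitude `aₙ` (log10-power),
center `μₙ` (Hz) and bandwidth `σₙ` (Hz).  Power spectra are estimated per
participant × electrode × condition × period with the Welch method
(0.25-s Hamming windows, 50 % overlap) from correct trials only; each
spectrum is decomposed by an iterative fit (robust aperiodic line →
iterative Gaussian peak extraction → joint refinement); the exponents feed
a 2 (time) × 2 (drug) × 2 (prime) × 2 (flanker) within-subject ANOVA and
cluster-based sign-flip permutation tests over the 60-electrode montage.

## Worked example

Fit one synthetic spectrum with a known ground truth (offset 1.0, exponent
3.4, one alpha peak at 10 Hz, bin noise SD 0.05):

```python
import numpy as np
import aperiodic as ap

freqs = np.arange(1.0, 46.0)                      # 1-Hz grid
power = ap.synth_spectrum(freqs, offset=1.0, exponent=3.4,
                          peaks=[(10.0, 0.6, 1.5)], noise_sd=0.05, seed=42)
res = ap.SpectralModel(freqs, power).fit()
print(res.summary())
```

```
Spectral parameterization results
==============================================
  fit range        3-35 Hz (33 bins)
  aperiodic offset  0.9931  (log10 power)
  aperiodic exponent  3.3981
  R^2               0.9987
  MAE               0.0304  (log10 power)
  peaks (2)
    center  10.13 Hz  amp 0.595  bw(SD) 1.57 Hz
    center  30.63 Hz  amp 0.070  bw(SD) 1.00 Hz
```

The injected parameters come back almost exactly (3.398 vs 3.40; the small
second peak is a noise excursion the iterative extractor picked up —
expected behaviour at this noise level, see `docs/methods.md`).

A full synthetic experiment — 25 participants, placebo/MPH sessions, the
four prime × flanker conditions, two analysis periods, injected drug
(+0.129) and period (+0.124) exponent shifts — runs end to end with:

```python
cfg = ap.RunConfig(seed=1, mode="spectra", n_electrodes=8,
                   design=ap.TaskDesign(n_participants=25, n_trials=16,
                                        n_blocks=4),
                   stages=("simulate", "spectra", "fit", "anova"))
rep = ap.run_pipeline(cfg, "out/demo")
print(rep.anova.summary())
```

```
Within-subject ANOVA (period x drug x prime x flanker), n=25
--------------------------------------------------------------
effect                          F       df          p     pes
period                  13431.246   (1,24)      <.001   0.998
drug                     7663.872   (1,24)      <.001   0.997
...
drug contrast (MPH - placebo): truth +0.129, recovered +0.130
period contrast (within - pre): truth +0.147, recovered +0.146
```

Both injected main effects are recovered with the correct sign and
magnitude.  The same pipeline runs from time-domain epochs
(`mode="epochs"`), and a CLI mirrors the stages:

```bash
aperiodic all --config config.yaml --seed 1 --outdir out/run
```

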