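# tfkit

Transfer-function estimation between paired time series, built for
neurovascular-coupling analysis: given an input signal (e.g. a
neuronal calcium fluorescence trace) and an output signal (e.g. red
blood cell velocity in a nearby capillary), estimate the kernel h —
the *transfer function* (TF) — of the linear convolution model

    y(t) = (x * h)(t) + ε(t).

The TF lumps every cellular cascade between neuronal activation and
the vascular response into one impulse response; in blood-flow-based
neuroimaging its parametric form is the gamma-variate hemodynamic
response function

    TF(t; p1, p2, p3, p4) = H(t − p3) · p4 · (t − p3)^(p1−1) · p2^p1
                            · e^(−p2 (t − p3)) / Γ(p1),

with shape p1, rate p2 (1/s), onset time shift p3 (s) and amplitude
scale p4, peaking at p3 + (p1 − 1)/p2.

Two estimation routes are provided, with the tooling to choose
between them:

* **Direct deconvolution** (causal Toeplitz least squares, or Fourier
  division with a water-level guard) — assumption-free and excellent
  in-sample, but it amplifies high-frequency noise into the kernel.
* **Parametric optimization** of the one-Γ family (or any user-defined
  family) by Nelder-Mead, quasi-Newton, or a multi-run simulated-
  annealing protocol that screens every candidate against two
  biological-consistency rules: a strictly positive onset delay and at
  most one non-derivable (kink) point.

Pre-treatment (crop, median filter, Savitzky-Golay smoothing,
resampling, boxcar stimuli), Pearson/RSS evaluation, seeded
synthetic-data generation, text/HDF5 I/O and a CLI round out the
toolkit. Estimators follow the scikit-learn protocol
(`fit`/`predict`/`score`, `get_params`, clonable), so they compose
with sklearn model-selection utilities.

## Worked example

Generate a synthetic recording with a known fast kernel
(p = (2.5, 2.0, 0.2, 1.5), 20 s at 50 ms, light noise), then fit and
deconvolve:

```bash
$ tfkit simulate --out-prefix demo --seed 1 --noise-sigma 0.02
wrote demo_input.txt, demo_output.txt, demo_tf.txt

$ tfkit fit --input demo_input.txt --output demo_output.txt \
      --algorithm annealing --runs 10 --iterations 2 --seed 0
iterations 2 (stop: converged)
params     2.66771 2.0916 0.170853 1.49742
pearson    0.9954
residual   0.161898
consistent True

$ tfkit deconvolve --input demo_input.txt --output demo_output.txt --method toeplitz
pearson    0.9978
residual   0.0762018
consistent False  (zero onset delay; non-derivable points > 1)
```

The annealing protocol recovers parameters close to the ground truth
(onset delay 0.17 s vs 0.2 s true; peak (p1−1)/p2 + p3 ≈ 0.97 s vs
0.95 s true) and the kernel passes the biological screen. Plain
deconvolution predicts the *training* data slightly better (Pearson
0.9978 vs 0.9954) precisely because it absorbs the noise into the
kernel — which is why its kernel starts at 0 s, is full of kinks, and
is rejected as biologically inconsistent. `tfkit recommend` walks
through the method-selection questionnaire:

```bash
$ tfkit recommend --shape-prior --noise high --need-dynamics --time-budget slow
annealing_protocol
```

The same workflow in Python:

```python
import tfkit

inp, out, truth = tfkit.reference_dataset(noise_sigma_frac=0.1, seed=11)
est = tfkit.AnnealingProtocol(n_runs=50, max_iterations=2, master_seed=2)
est.fit(inp, out)
print(est.params_, est.score(inp, out))
```

## Layout

* `src/tfkit/signals.py` — `TimeSeries` container and pre-treatment
* `src/tfkit/models.py` — one-Γ family, custom parametric models
* `src/tfkit/evaluation.py` — convolution prediction, Pearson, RSS
* `src/tfkit/deconvolution.py` — Toeplitz and Fourier routes
* `src/tfkit/optimization.py` — optimizers and the run/iteration protocol
* `src/tfkit/consistency.py` — biological-consistency screen
* `src/tfkit/estimators.py` — scikit-learn-style estimator classes
* `src/tfkit/synthetic.py` — seeded ground-truth generators
* `src/tfkit/io.py`, `src/tfkit/cli.py` — files, records, logging, CLI

See `docs/methods.md` for the model assumptions, parameter defaults
and numerical choices.
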