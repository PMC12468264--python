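# Methods

## The decomposition model

`mvmdeeg.mvmd` solves the multivariate variational mode decomposition
problem: given a C-channel signal x(t) = [x_1(t), …, x_C(t)], find K
narrow-band modes u_k(t) = [u_k,1(t), …, u_k,C(t)] and K shared center
frequencies ω_k minimizing the summed bandwidth of the baseband-shifted
analytic mode signals,

    min  Σ_k Σ_c ‖ ∂_t [ u⁺_k,c(t) e^{-jω_k t} ] ‖²
    s.t. Σ_k u_k,c(t) = x_c(t)  for every channel c,

where u⁺ denotes the Hilbert-transform analytic signal. The single
shared ω_k per mode index is the point of the multivariate variant: mode
k describes the *same* oscillation on every channel, so the decomposition
is mode-aligned by construction and per-mode features can be stacked
across channels without frequency mismatch. C = 1 reduces the problem to
ordinary single-channel VMD, which the tests exploit as an independent
oracle.

The augmented Lagrangian (bandwidth penalty α, channel duals λ_c) is
optimized by ADMM entirely on the discrete nonnegative-frequency grid of
the (mirror-extended) signal, iterating three closed-form updates:

* **Mode update (Wiener filter).** Sequentially in k (Gauss–Seidel, so
  mode k+1 sees mode k's fresh value):
  û_k,c(ω) ← [x̂_c(ω) − Σ_{i≠k} û_i,c(ω) + λ̂_c(ω)/2] / [1 + 2α(ω − ω_k)²].
* **Center-frequency update.** Power-weighted mean frequency pooled over
  channels: ω_k ← Σ_c Σ_ω ω|û_k,c|² / Σ_c Σ_ω |û_k,c|². A mode whose
  spectrum is identically zero keeps its previous ω_k (guard) and warns.
* **Dual ascent.** λ̂_c ← λ̂_c + τ (x̂_c − Σ_k û_k,c).

Iteration stops when the relative change
Σ_k Σ_c ‖Δû_k,c‖²/‖û_k,c‖² drops below `tol` (zero-norm terms
contribute 0). Time-domain modes are the inverse real FFT of the half
spectra (implicit conjugate-symmetric extension), trimmed of the mirror
padding, sorted by ascending center frequency (stable, so ties keep the
original mode order).

### Solver parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 2000 | bandwidth penalty; larger → narrower modes. 2000 is the analysis value used throughout this package for EEG-band signals. |
| `tau` | 0 | dual-ascent step. 0 disables exact-reconstruction enforcement, which is the robust choice when the input carries broadband noise (the Wiener filters then act as denoisers). For noiseless, band-limited inputs set τ > 0 (e.g. 0.5): the dual then drives the reconstruction error to ≈1%, whereas with τ = 0 leakage skirts attenuated by the Wiener denominators can leave 5–10% residual. |
| `tol` | 1e-7 | relative-change stopping threshold; tone fixtures converge in tens of iterations. |
| `max_iter` | 500 | cap; an unconverged result is still returned, flagged. |
| `init_scheme` | `uniform` | ω initialized evenly over the open interval (0, 0.5) cycles/sample — deterministic and reproducible; `zero` and seeded `random` alternatives are provided. |
| `mirror_extend` | on | half-length reflection at both ends before the FFT, trimmed after inversion; reduces boundary leakage in the bandwidth estimates. |

Numerical notes: the frequency grid is the `rfft` half grid (F = T/2+1
bins including DC and Nyquist); the integrals of the update formulas are
plain sums over it. No dedicated DC mode is allocated — band-pass
preprocessing removes near-DC energy upstream. With τ = 0 convergence is
abrupt (the statistic plunges below `tol` within a couple of iterations
of the center frequencies locking); with τ > 0 the statistic exhibits a
long, cleanly non-increasing geometric tail, which is where the
monotone-tail regression test operates.

## Preprocessing

Power-line interference is removed with a quality-factor-30 IIR notch
(50 or 60 Hz), and the analysis band 0.5–50 Hz is selected with a
4th-order Butterworth band-pass. Both are zero-phase. The notch runs
forward-backward (`filtfilt`). The band-pass applies the
forward-backward magnitude response |H(ω)|² spectrally on a
mirror-extended copy of the signal: the recursion's low-edge pole at
0.5 Hz has a multi-second time constant and its state transient would
otherwise ring across an entire short record; the spectral realization
is the filtfilt steady state with exactly zero phase, exact linearity
and no transient. The causal (`zero_phase=False`) variant is an ordinary
`sosfilt`.

Recordings are cut into one-second epochs (trailing remainder dropped).
Minority classes can be augmented by overlapped sliding windows
(default overlap 0.5); overlap 0 reduces to plain segmentation. Channel
selection matches electrode labels case-insensitively and tolerates
`EEG `-prefixes and reference suffixes (`-REF`, `-LE`, …), returning
channels in the requested order — the seven-channel scalp montage FP1,
F4, C3, P4, O1, F7, T6 is the intended use.

## Spectrogram features

Every mode of every channel becomes a Hann-windowed STFT magnitude map
(`scipy.signal.stft`, magnitude not power, `scaling="spectrum"`). The
dialect is pinned by two requirements: with transform length equal to
the sampling rate the bins land on a 1 Hz grid, so the inclusive 0–50 Hz
crop keeps exactly 51 bins at both 512 Hz and 256 Hz; and zero boundary
padding of half a window at each end makes a one-second epoch yield
ceil(N/hop)+1 = 9 frames under both window settings (128/64 at 512 Hz,
64/32 at 256 Hz). Slabs are stacked channel-major, mode-minor, giving
(K·C) × 51 × 9 tensors — (8, 51, 9) for the 2-channel/4-mode binary
task and (56, 51, 9) for the 7-channel/8-mode six-class task. Features
are raw magnitudes; an optional `normalize` flag divides by the global
standard deviation (scaling only, preserving nonnegativity).

## The classifier

`mvmdeeg.model.HybridClassifier` is a CNN → BiGRU → Transformer stack
built on the package's own reverse-mode automatic-differentiation engine
(`mvmdeeg.autodiff`, float64 numpy):

1. **Convolution block** — one 3×3 convolution (padding 1, stride 1)
   preserving the 51×9 map, batch normalization, ReLU, then adaptive
   average pooling to a 6×6 grid (cell i spans ⌊iH/6⌋…⌈(i+1)H/6⌉).
   16 filters for the binary configuration, 128 for the six-class one:
   (8,51,9) → (16,6,6) and (56,51,9) → (128,6,6).
2. **Map-to-sequence** — the pooled time-frame axis becomes the step
   axis; features are (filter, pooled-frequency) row-major, so
   (16,6,6) → 6 steps × 96 features.
3. **BiGRU** — 2 stacked bidirectional layers, hidden size 512, per-step
   concatenation of both directions: (6, 1024). The gates follow
   z = σ(W_z[h,x]), r = σ(W_r[h,x]), h̃ = tanh(W_h[r∗h, x]),
   h = (1−z)∗h_prev + z∗h̃. With `use_residual` the input sequence is
   linearly projected to 1024 and added.
4. **Tokens** — row-major re-chunk into 48 tokens of width 128; a
   learned class token (zero-init plus small noise) is prepended (49
   tokens) and sinusoidal positions PE(pos,2i) = sin(pos/10000^{2i/d}),
   PE(pos,2i+1) = cos(·) are added to every token including the class
   token.
5. **Transformer encoder** — 3 post-norm layers (8-head self-attention
   + 4× feed-forward, internal residuals); with `use_residual` the
   encoder input sequence (class token position included) is added to
   the encoder output.
6. **Head** — dense layer on the index-0 (class) token, softmax over 2
   or 6 classes.

Ablation switches: `use_cnn=False` replaces the convolution block with a
dimension-matching linear projection of the flattened input;
`use_bigru=False` projects the step features to 1024 linearly;
`use_transformer=False` bypasses the encoder; `use_residual=False`
removes both outer skips. Every variant constructs and runs. Dropout is
not used. Checkpoints are `.npz` containers holding the config as JSON
plus named weight and batch-norm-statistic arrays.

## Training and evaluation

Adam (lr 1e-3) with a step schedule multiplying the rate by 0.1 every 5
epochs (driving it to ~0 by epoch ~40 over a 200-epoch run; an optional
`lr_floor` clamps it, default off), batch size 64, cross-entropy loss.
Batches are reshuffled per epoch from the run seed; identical seeds give
bit-identical loss histories. NaN loss aborts with a diagnostic.

Metrics: ACC; SEN = recall of class 1 (focal anchored as the positive
class on binary tasks) and SPE = recall of class 0; on multi-class tasks
both are macro one-vs-rest averages and per-class recalls are exported
for confusion-matrix comparison; weighted F1 = Σ_c (n_c/N)·F1_c, which
coincides with macro F1 on exactly balanced data. Confusion matrices are
reported raw and row-normalized.

Protocols: subject-dependent evaluation uses epoch-level stratified
five-fold splits (seeded); subject-independent evaluation shuffles the
unique patient ids with the seed and splits them into three near-equal
groups, so every patient's epochs land in exactly one fold and test
folds contain only unseen patients.

## Synthetic data

`gen_multichannel_tones` emulates the shared-oscillator structure the
joint decomposition assumes: every channel carries the same tones with
channel-specific amplitudes and phases, optionally amplitude-modulated,
plus white (or 1/f) Gaussian noise calibrated to a whole-record SNR. The
per-component ground truth and the noise are returned, and components +
noise reconstruct the signal exactly. The standard fixture is 2 channels
× 4 s at 128 Hz sharing 10 Hz and 25 Hz tones at 20 dB SNR.

`gen_classification_set` produces balanced labeled one-second epochs
whose classes occupy distinct bands — by default a continuous
alpha-band oscillation (8–12 Hz) against gated beta bursts (18–25 Hz),
a 6 Hz margin between band edges — with per-epoch random carrier
frequency, phases and channel gains over 6 dB noise. A six-class,
7-channel, 256 Hz variant mirrors the multi-class task's shape. A Welch
band-power discriminant separates the two-class fixture with ≥95%
accuracy, so learnability does not hinge on the network.

What these fixtures do *not* emulate: nonstationary spectra, artifacts
(eye blink, EMG), inter-channel propagation delays, volume conduction,
1/f background with realistic slope, or patient heterogeneity. Passing
the desk-scale tests therefore demonstrates that the pipeline is wired
correctly and can learn spectrally coded classes — not that it attains
any particular accuracy on clinical recordings.

## Problem sizes used in the checks

The printed-dimension chain runs full-size architectures forward-only
(single example). Learning checks use a reduced architecture (8 conv
filters, GRU hidden 32, token width 64, 4 heads, 1 encoder layer) on the
2-channel 128 Hz fixture with 40 epochs per class, 10 training epochs,
batch 16, 5-fold cross-validation — sizes chosen so the whole suite runs
in seconds on one CPU core while still exercising every stage, including
the joint decomposition of every epoch.

## Known limitations

* The number of modes K is fixed by the user; there is no adaptive
  selection, and no dedicated DC or residual mode.
* The spectral zero-phase band-pass assumes offline (whole-record)
  processing; streaming use would need the causal variant.
* The autodiff engine implements exactly the operations the model needs;
  it is float64 and CPU-only, so full-size training is slow compared to
  GPU frameworks — architecture and training logic are identical at any
  scale, only throughput differs.
* EDF support covers plain EDF with per-channel physical scaling; EDF+
  annotations are ignored. Seizure-type labels are supplied via a
  manifest, not parsed from annotation files.
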