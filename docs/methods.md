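# Methods

## The estimation problem

Multichannel local field potentials (LFPs) recorded from a microelectrode
array are modelled as a multivariate autoregressive (MVAR) process

    X(t) = Σ_{n=1..p} A_n X(t−n) + E(t),

where `X(t)` is the M-channel sample vector, each `A_n` is an M×M
coefficient matrix and `E(t)` is white noise with covariance Σ.  In the
frequency domain `A(f) = I − Σ_n A_n exp(−i2πfn/fs)` and the transfer
matrix is `H(f) = A(f)⁻¹`.  The normalized directed transfer function
(DTF)

    γ²_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²

is the fraction of the total inflow to sink *i* at frequency *f* that
originates in source *j*; each row of γ² sums to one by construction, the
module's fundamental invariant (asserted to 1e−10 on every computed
result).  The normalizing sum runs over all sources including *i* itself —
with self-inflow dominating at M = 16 this explains why mean off-diagonal
DTF values are small (~0.01–0.05).  Band summaries average γ²(f) over the
grid frequencies inside theta (3–10 Hz) and gamma (55–75 Hz), zero the
diagonal (self-loops are not connectivity between electrodes), and are
reported as the mean of the M(M−1) off-diagonal entries.

## Estimation choices

* **Fit.** Ordinary least squares on the lagged design matrix with an
  intercept, one model per 3 s section (6000 samples comfortably support
  p ≤ 20 at M = 16; a pooled multi-epoch fit is a one-line extension of the
  same design matrix).  The residual covariance uses the unbiased
  denominator `n_eff − (pM + 1)`.  The normal-equations solve is used when
  the Gram matrix is well conditioned and falls back to an SVD solve
  otherwise — near-unit-root oscillatory regressors square the design's
  condition number in the Gram matrix, and only genuine rank deficiency
  (e.g. duplicated channels, which the error names) is treated as an error.
* **Order selection.** `BIC(p) = n_eff·log det Σ̂_p + pM²·log n_eff` with
  the maximum-likelihood residual covariance and `n_eff = n − p_max` held
  fixed across candidate orders so the criteria are comparable; ties go to
  the smaller order.  On the synthetic study BIC picks the generator's true
  order (4).
* **Frequency grid.** 1–100 Hz at 0.5 Hz steps by default.  Because band
  averages only use grid points inside the bands, the pipeline can restrict
  evaluation to the band interiors (`grid="bands"`) with bit-identical band
  matrices at roughly a quarter of the cost; the study analyses do so.
* **Band analysis order.** Bands are analysed by averaging the broadband
  model's DTF over band frequencies, not by fitting MVAR models to
  band-pass-filtered signals: a heavily oversampled narrowband series makes
  the lagged regression catastrophically ill-conditioned, while spectral
  band-averaging uses one well-posed model for all bands.  The time-domain
  band-pass filters exist (and are fully tested) for time-frequency
  inspection of the filtered rhythms.

## Causal-network metrics

A band matrix defines a weighted digraph (`weights[i, j]`: source *j* →
sink *i*).  Raw DTF entries are generically all positive, so binary edges
require a threshold θ:

* **Clustering coefficient C** — on the binary graph, node *i*'s
  neighbourhood is the union of its in- and out-neighbours (size e_i);
  c_i is the fraction of ordered neighbour pairs (u, v) joined by a
  directed edge u→v, defined 0 when e_i < 2; C is the mean over all nodes.
* **Density D** — binary edges / N(N−1).
* **Global efficiency E_global** — edge lengths are the reciprocal of
  max-normalized weights (the strongest suprathreshold edge has length 1),
  directed shortest paths are computed exactly (Dijkstra), unreachable
  pairs contribute 0, and E is the mean inverse distance over ordered
  pairs.  Without the max-normalization, raw DTF weights of ~0.01 would pin
  E near 0.01 regardless of topology; with it, E lands in the 0.1–0.8 range
  a binary-flavoured efficiency occupies.  All three metrics are invariant
  to scaling all weights and the threshold by a common factor.  Note that
  max-normalization makes "adding an edge never decreases E" true only
  when the added edge does not itself become the new maximum weight.

**Thresholding.**  A network's own median off-diagonal value is scale-free
but fixes the binary density at exactly 0.5 on every single network, which
erases all between-group structure.  Group analyses therefore share one
threshold per band: the *pooled* median off-diagonal value over every
section's band matrix in the comparison.  Control-group networks then sit
above 0.5 density and coupling-attenuated networks below it, while the
threshold remains adaptive to the overall DTF scale.  Fixed numeric
thresholds and the per-network median remain available.

## The synthetic study generator

No recordings are deposited with the study this pipeline re-implements, so
ground truth is synthesized *inside the model class the estimator assumes*:

* **Channels.** Each channel's own dynamics are the product of two damped
  AR(2) resonators, one per band, giving an order-4 diagonal.  Pole radii
  default to 0.992 (theta) and 0.96 (gamma).  The theta radius cannot be
  much lower: an AR(2) pole at angle 2π·6.5/2000 has no interior spectral
  peak at all below r ≈ 0.984, so a broad "default" radius would silently
  violate the requirement that each channel's spectrum peak inside 3–10 Hz.
  Resonator centre frequencies are staggered across channels over the
  middle 40 % of each band — real electrodes do not oscillate at one
  identical frequency, and exactly coincident poles on all channels make
  the joint system's stationarity pathologically sensitive to coupling (a
  repeated eigenvalue of multiplicity M moves like the M-th root of the
  perturbation).
* **Coupling.** Directed edges are injected as short off-diagonal lag
  polynomials ("band-matched kernels"): each edge couples through the
  source's own resonator polynomials, scaled so that the cross-to-self
  transfer ratio at each band's resonance equals the requested strength
  (default 0.35).  This is the one genuinely delicate design choice.  The
  two bands' resonance gains differ by almost two orders of magnitude (the
  low-frequency pole pair nearly coincides with its conjugate), so a plain
  lag-1 coupling constant either saturates the theta band — where the DTF
  becomes scale-invariant and blind to attenuation — or is invisible in
  gamma; the matched kernel puts both bands in the weak-coupling regime
  where band DTF responds monotonically (≈ quadratically) to coupling
  scale.  The default graph gives every channel five pseudo-random targets
  with randomly signed strengths (signs keep coupling row sums near zero;
  DTF depends on |H|², so signs do not affect detectability); the graph is
  a fixed deterministic function of a graph seed and is part of the study
  definition.
* **Experiment.** Three groups (control, low-dose "pro", high-dose "PRO")
  × days × 6 subjects × sections of 3 s (2 s pre-event, 1 s post-event)
  at 2 kHz.  High-dose coupling is attenuated to 0.3× on day 1, 0.6× on
  day 2 and 1.0× from day 3 (recovery); the other groups are never
  attenuated.  Each subject carries a persistent multiplicative coupling
  jitter (10 % s.d.) representing between-animal variability — a declared
  convenience, not a claim about real inter-animal spread.  Every epoch's
  noise stream comes from `SeedSequence(seed, spawn_key=(group, day,
  subject, section))`, so any cell of the design can be regenerated bit
  for bit.  Burn-in is 2000 samples: with coupling the companion spectral
  radius reaches ≈0.9987, and 2000 steps shrink the slowest transient to
  under 10 %.
* **What the generator does not emulate:** 1/f background, line noise
  (available as an explicit test signal only), electrode drift, artifacts,
  non-stationarity within an epoch, volume conduction, or any behavioural
  coupling.  Passing tests demonstrate that the pipeline recovers known
  directed structure and dose effects in its own model class; they do not
  certify performance on real LFPs.

## Study analyses and their scale

The analysis scripts and acceptance checks run the study at 16 channels,
days 1–3, 6 subjects per group and 10 sections per subject per day — 60
sections per group per day, the same per-day group sample that the
published F statistics' (2, 177) degrees of freedom imply, and 540 epochs
(3.9 GB of raw samples per master seed) regenerated on the fly.  The full
five-day design remains available through `ExperimentDesign` defaults.

Group tests are one-way ANOVA across the three groups per day followed by
the Newman–Keuls step-down studentized-range procedure (quantiles from
`scipy.stats.studentized_range`; harmonic-mean n for unbalanced groups; a
non-significant stretch is never subdivided).  A pair is reported
significant only when the omnibus ANOVA is also significant at α = 0.05.
The unit of analysis for the study is the *subject* (sections averaged
within subject, n = 6 per group): subjects carry persistent coupling
jitter, so treating sections as independent would pseudoreplicate and
inflate false positives.  Section-level analysis (the published df) is
implemented and appropriate when subjects are exchangeable, e.g. with
jitter disabled.

## Numerical conventions and degenerate inputs

* Transfer matrices are checked with a per-frequency 1-norm condition
  estimate (limit 1e10); an ill-conditioned A(f) raises an error naming
  the frequency rather than returning NaNs.
* Band averaging uses the closed frequency interval and requires ≥ 2 grid
  points; peak extraction breaks ties toward the lower frequency; the
  rhythm-dominance rule is strict (`a > 2b`).
* Zero-variance ANOVA cells: all-identical data give F = 0, p = 1 with a
  warning; zero within-group variance with distinct means gives F = ∞.
* Edgeless networks: density 0, efficiency defined 0 with a warning,
  clustering 0 (every node degenerate).
* Filters: least-squares FIR, odd tap counts, applied forward-backward
  (`filtfilt`), so effective attenuation is twice the single-pass figure
  and net phase is zero.  Notches 49–51 and 99–101 Hz with 2 Hz
  transitions and 801 taps at 2 kHz (≥ 40 dB two-way at 50/100 Hz,
  passband within ±1 dB).  Band-pass transitions span the octave outside
  the band; tap count defaults to ≈ 6.6·fs/Δf (8801 taps for theta at
  2 kHz), and `filtfilt` padding is capped at the signal length.

## Known limitations

* The DTF carries no surrogate-based edge-level significance test; edges
  are thresholded, not tested.
* The Newman–Keuls procedure does not strongly control the family-wise
  error rate for k > 3 groups; it is used here because it is the
  procedure the study design calls for.
* Per-epoch MVAR coefficients of the band-matched generator are
  individually small and highly collinear; the pipeline's claims are about
  transfer-function and DTF functionals, which are well determined, not
  about entry-wise coefficient recovery at this design size.
* The repeated-measures analysis across days is approximated by per-day
  one-way ANOVAs plus the seed sweep's trend check; a true mixed-effects
  treatment is out of scope.
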