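# Methods

## Phase extraction

Channels are decomposed with complex Morlet wavelets
Ψ(t) = e^{i2πf_k t} e^{−t²/2ς²} sampled at t = n/f_s over ±4ς, with
ς = ϱ/(2πf_k) seconds and ϱ = 4 cycles. Wavelets are normalized to unit
energy; the instantaneous phase — the only quantity the clustering
consumes — is invariant to this choice, so power maps are comparable
across bands only up to the normalization convention. Convolution uses
zero-padded boundaries; samples within 4ς of either record edge are
flagged as cone-of-influence per band and carried with the tensors. When
a wavelet's nominal support exceeds the record (low bands on short
segments), the wavelet is truncated symmetrically to fit — at the default
settings a 3 s segment truncates the 1 Hz and 1.6 Hz wavelets at ≈2.4ς
and ≈3.6ς, discarding a negligible Gaussian tail; records shorter than
one cycle of the slowest band are rejected outright.

The band grid is geometric with the endpoints pinned:
f_k = exp(ln f_min + (ln f_max − ln f_min)·k/(K−1)), k = 0…K−1. With the
default f_min = 1, f_max = 12, K = 12 the one-decimal band labels are
1.0, 1.3, 1.6, 2.0, 2.5, 3.1, 3.9, 4.9, 6.1, 7.6, 9.6, 12.0 Hz. The
divisor K−1 (rather than K, with k from 1) is deliberate: it is the only
variant whose rounded centers reproduce every band label used in the
analyses, including the 7.6 Hz steady-state band. Rounding is half-up and
used for display only.

## Clustering by circular variance

At a fixed sample and band the channel phases θ_j are points on the unit
circle; a channel set is accepted as synchronized when the magnitude of
its mean resultant vector R̄ = |mean_j e^{iθ_j}| reaches the threshold
r. The construction is two-stage:

- **Fuzzy stage.** From every channel seed, grow a candidate by
  repeatedly adding the channel that maximizes R̄ of the enlarged set;
  stop before any addition would drop R̄ below r. Duplicate member sets
  are merged. Because the greedy addition path does not depend on r, a
  stricter threshold can only truncate a seed's candidate — the largest
  candidate size is non-increasing in r (a property the tests pin).
- **Hard stage.** Candidates are accepted greedily in decreasing R̄
  (ties: larger cardinality, then smaller encoded label integer, making
  the algorithm fully deterministic); each acceptance strips its members
  from the survivors, whose R̄ is recomputed on the reduced sets; reduced
  multi-channel candidates that fall below r are dropped. Channels never
  accepted into a multi-channel cluster end as singletons (R̄ = 1 by
  definition), so the result is always a disjoint covering partition.

The hard stage makes no optimality claim; it is a greedy overlap
resolution. On unambiguous planted structure (rigid groups separated by
more than π/2 at r = 0.9) it provably coincides with the exhaustive best
feasible partition, which the tests verify for up to six channels.
Note that hard-partition membership is *not* monotone in r — greedy
reassignment can enlarge one channel's final cluster when the threshold
rises — only the fuzzy-stage growth is.

The per-record implementation vectorizes the fuzzy stage across all
samples of a band (the greedy loop runs over channels only), leaving a
small per-sample loop for overlap resolution; a full 19-channel, 90 s,
12-band record clusters in seconds.

## Labels, maps, contrasts

Cluster identity is the member set, encoded as ceil(N_ch/4) hex digits,
MSB-first in canonical montage order, padded with trailing zero bits
(19 channels → 20 bits, pad bit always 0). The all-zero word means
"unassigned". Colors interpolate linearly from dark blue (0,0,139) at the
encoded integer 1 to bright yellow (255,255,0) at the all-channel word,
ranked within the run-wide label universe; unassigned renders gray. The
endpoint RGB values are a convention (the endpoints themselves are not).

TFT maps tile the labeled record into non-overlapping, left-aligned
windows of υ samples (default 16; 62.5 ms at 256 Hz; a trailing partial
window is dropped). A channel's cell is assigned its modal label only if
the mode's count strictly exceeds ρ % of the window (default 50); ties
among equally frequent labels are unassigned, which is what rules out
bimodal cells. Intertrial maps apply the same strict-mode rule first
across epochs at each within-epoch sample (ITCM), then across time
windows; they are invariant to epoch order and duplication of the whole
epoch set. Segmentation into condition epochs happens *after* labeling,
so label words are directly comparable between conditions of one run.

TFL contrast maps compare one channel's label words between two
conditions cell-by-cell. Because label words have equal width and each
bit position is one channel, the comparison admits substitutions only and
each cell is the count of differing bits, in [0, N_ch]. The unrestricted
insert/delete/substitute dynamic program is provided for general strings,
but it is not used for labels: shift alignments could undercut the
substitution count and would break the channel-wise reading of a cell.

## Synthetic records

The forward model is instantaneous linear mixing: C = W·S with
w_ji = 1/max(d(c_j, s_i), ε)², ε = 10⁻³, electrodes on the unit sphere
(standard 10-20/10-10 positions, unit-normalized), volume conduction
homogeneous and isotropic. Weights are re-evaluated per sample for moving
sources. The evoked source is
v(n) = (2π)^{−1/2} e^{−((n−μ)/σ)²/2} sin(2πf(n/N)γ(n)) with
γ = (N − 0.5n)/N, f = 10 Hz, μ = 0.5N, σ² = 0.125N: a Gaussian packet
(σ ≈ 38 ms for 3 s epochs) whose downward chirp passes ≈1.67 Hz at the
envelope peak — inside the 1.6 Hz analysis band. It repeats identically
in every epoch. Noise kinds: harmonics (fixed amplitude, frequency,
initial phase), white Gaussian, and colored Gaussian shaped to a 1/f^α
spectrum in the FFT domain (α = 1 by default, DC removed, unit variance
before scaling). A single integer seed drives all stochastic draws in
spec order, so records are bit-reproducible; the VEP consumes no
randomness.

The default 19-channel source set plants a three-way phase structure:

- an occipital VEP source at 0.8 of the radius behind the head
  (amplitude 12 — strong enough that the occipital/parietal electrodes
  are VEP-dominated in the delta bands after a 10-epoch average);
- a frontal 5/3 Hz harmonic at 0.7 radius (amplitude 0.035·A_VEP). Its
  frequency is epoch-periodic (5 cycles per 3 s epoch), so it survives
  epoch averaging, and its initial phase constant (4.7329 rad) places it
  in antiphase with the VEP's in-band phase at the epoch midpoint. This
  is what makes "frontal electrodes lie outside the evoked cluster" a
  recoverable ground truth: with purely stochastic frontal noise the
  frontal phase would align with the VEP by chance in roughly a quarter
  of realizations, and no phase-synchrony method could separate them.
  The amplitude is small because tones integrate coherently over the
  whole wavelet while the sub-cycle VEP packet does not: per unit
  amplitude a tone yields roughly 15× the in-band response;
- scattered 8 Hz (a steady-state-stimulation stand-in) and 5 Hz
  harmonics, two white sources (one drifting linearly) and one orbiting
  1/f source, with amplitudes (≈1.2–2) kept below the level that would
  destabilize parietal cluster membership within one 62.5 ms window.

Under this configuration the broadband record SNR (VEP-mixture power vs
residual, channel-averaged, in dB) is ≈ −4.6 dB — low, because the VEP
is a sparse transient while the noise runs continuously; the per-band
picture at 1.6 Hz is strongly favorable at occipital electrodes and
strongly unfavorable at frontal ones, and that spatial contrast is what
the clustering resolves. The test suite requires recovery of the planted
structure (the three electrodes nearest the VEP source in one hard
cluster, the three farthest excluded, at the 1.6 Hz band and 1500 ms
window of a 10-epoch average, r = 0.9) in at least 18 of 20 fixed
seeds.

What the simulator does not emulate: realistic head geometry or tissue
conductivities, dipole orientations, non-stationary source spectra,
inter-epoch VEP variability (latency/amplitude jitter), eye/muscle
artifacts, and electrode noise. Passing tests therefore demonstrate that
the algorithms recover planted phase structure under the stated mixing
model, not that they are robust to every artifact of recorded EEG.

The speller schedule flashes the 6 rows then 6 columns of a 6×6 character
matrix per stimulation sequence at a 125 ms interstimulus interval; the
two flashes intersecting the target are labeled ERP, the ten others
noERP, giving the paradigm's exact 1:5 ratio (5 characters × 10 sequences
→ 100 ERP / 500 noERP events). Epochs are onset-locked, default window
(0, 1000 ms].

## Numerical choices and degenerate inputs

- Phase of a numerically zero coefficient is 0 (atan2 convention).
- R̄ comparisons use plain ≥ with no tolerance; singleton R̄ is set to
  exactly 1.0 on every path so tie-breaking cannot split on rounding.
- The strict mode rule uses integer counts (count·100 > ρ·υ), so the
  ρ = 50 boundary is exact: 9 of 16 passes, 8 of 16 does not.
- Window tiling drops a trailing partial window; υ = 1 with ρ = 0
  reduces the mode operator to the identity.
- Config validation: 0 < r < 1, 0 ≤ ρ < 100, υ ≥ 1,
  0 < f_min < f_max ≤ f_s/2, all checked before any computation.
- The distance floor ε prevents singular gains when a source touches an
  electrode; trajectories that leave the unit sphere are rejected.

## Parameters at a glance

| parameter | meaning | default | units |
|---|---|---|---|
| f_min, f_max, K | geometric band grid | 1, 12, 12 | Hz, Hz, – |
| ϱ | Morlet cycles | 4 | cycles |
| r | synchrony threshold on R̄ | 0.9 | – |
| υ | mode window | 16 | samples |
| ρ | strict mode majority | 50 | % |
| f_s | sampling rate | 256 | Hz |
| ε | mixing distance floor | 10⁻³ | sphere radii |
| α | colored-noise exponent | 1 | – |

r is the sensitive knob: raising it fragments clusters, lowering it
merges them; no automatic selection is provided (choosing r per dataset
remains the analyst's task). ρ and υ trade temporal resolution against
label stability.

## Known limitations

- The fuzzy-stage reconstruction (seed-and-grow per channel) is one
  faithful realization of the stated contracts; alternative candidate
  generators (pair seeds, exhaustive small-set search) would satisfy the
  same interface and are isolated behind `create_fuzzy_clusters`.
- Greedy hard conversion can strand a borderline channel as a singleton
  when a slightly tighter competing candidate is accepted first; on
  ambiguous (non-planted) structure the output is a deterministic but
  not globally optimal partition.
- Zero-lag mixing means volume conduction itself produces perfect
  synchrony; the method describes near-zero-lag phase relations and does
  not attempt to separate conducted from genuinely coupled activity.
- EDF records are read (via MNE) but written artifacts are TSV only.
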