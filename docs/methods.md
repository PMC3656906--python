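# Methods

## Signal model and what the simulator does (and does not) emulate

The generator draws each band component as a zero-mean multivariate
Gaussian, i.i.d. in time, with covariance equal to the inverse of a
constructed sparse precision matrix, and then passes every channel
through the same zero-phase band-pass filter. A common linear filter
rescales all channels' spectra identically, so the instantaneous
cross-channel correlation — and therefore the partial-correlation
matrix, which is what the estimator targets — is exactly preserved
within the passband. Broadband records are the sum of five independent
band components, one per canonical band (delta 0.5–4, theta 4–8, alpha
8–13, beta 13–30, gamma 30–48 Hz), each with its own precision matrix.

This emulates the covariance structure of source-space recordings, not
their physics: there is no dipole forward model, no sensor noise, no
1/f spectral shaping, no nonstationarity, and no cross-frequency
coupling. Passing tests therefore demonstrate that the estimation
pipeline recovers conditional-dependence structure from band-limited
stationary Gaussian data at the stated sample sizes — they do not
certify behavior under artifacts, volume conduction or nonstationarity
of real recordings.

Precision matrices are built with unit diagonal and −s on planted
off-diagonals, so the theoretical partial correlation on a planted edge
equals s exactly (to machine precision). Feasibility is enforced, not
patched: a spec whose smallest eigenvalue is ≤ 1e−6 is rejected as
infeasible rather than regularized, because any uniform diagonal ridge
would either change the planted partial correlations or (with
off-diagonals recomputed) amount to a pure rescaling that cannot
restore definiteness. Practical limits: with equal strength s on a
support of maximum degree d, diagonal dominance (s·d < 1) suffices.

Study layout: two groups of 14 subjects ("verum", "sham"), conditions
rest/post, 300 Hz sampling. Post-condition deltas apply only to the
designated bands and only in the effect group (default verum); the sham
group's post records are drawn from the rest distribution, making sham
a true null control. Per-recording randomness derives from the design
seed through `SeedSequence(entropy=seed, spawn_key=(group, subject,
condition, band))`, so identical seeds are bit-identical and any single
subject can be regenerated in isolation.

Record length defaults to a desk-scale 36 s (10,800 samples at 300 Hz);
the emulated recordings are 360 s (108,000 samples) and are available
via `duration_s=360`. The statistical unit of the group tests is the
subject, so the shorter records raise per-subject estimator variance
without biasing the group-level calibration.

## Filtering

Band-pass filters are Butterworth band-passes of order 5 in
second-order-section form, applied forward-backward (`sosfiltfilt`):
exactly zero phase, which matters because the connectivity measure is
the lag-zero covariance. The design contract — effective gain ≥ 0.9 at
band center and ≤ 0.1 one octave outside each edge, evaluated on the
forward-backward response |H(f)|² — is verified by tests for all five
bands at 300 Hz. Order 5 was chosen as the lowest order that keeps the
narrow delta band (0.5 Hz low edge at 300 Hz) numerically stable in SOS
form while making refiltering of an already-band-limited signal change
RMS by < 5%. A very long linear-phase FIR could meet the same contract
but would exceed the usable padding length of desk-scale records at the
delta edge.

Edge transients: filtered records are trimmed by 3 cycles of the band's
low edge at each end (6 s for delta, 0.1 s for gamma) before covariance
estimation; the band-pass operation itself preserves length, and the
simulator generates one settling length beyond each end and discards
it. Downsampling uses zero-phase FIR decimation and requires an integer
ratio. The 0.5 Hz delta low edge gives few cycles in short records;
this is a documented property, not specially treated.

## Estimation and group statistics

Sample covariance uses divisor T (the mean-over-time form); partial
correlation is the rescaled negative precision. A covariance with
condition number above 1e10 receives a diagonal ridge of 1e−6 ×
trace/n with a logged warning — at 16 regions and thousands of samples
this is never triggered, but small-T synthetic runs can hit it.

Group inference is two-sided throughout: per edge, a one-sample t-test
(df = n−1) on subjects' Fisher-z values, Benjamini–Hochberg across the
120 edges of the 16-node network at q = 0.05. The group mean is
reported on the raw r scale and set to 0 exactly where the FDR flag is
false, mirroring how masked group connectivity tables are printed.
Significance is assessed at the 16-node level, before bilateral
collapse.

Bilateral collapse takes, per ROI pair, the extremum of the 4
hemispheric cross-connections ordered by absolute value with sign
preserved; negative winners are recorded as sign-sensitive, since a
signed-maximum rule would differ there (published tables of this
analysis type contain only non-negative values, leaving the convention
open). Provenance records the winning hemispheric pair.

Paired rest-versus-post comparisons run at the 8-node level on
per-subject collapsed values with the group-level winning pair held
fixed across subjects and conditions (post-network provenance,
falling back to rest), so the paired test compares the same physical
edge in everyone. Change classification: *emerged* = absent at rest,
significant post; *suspended* = the converse; *increased*/*decreased* =
present in both with paired P < 0.05, by the sign of the change; else
*unchanged*.

The REST column pools all subjects' rest records (both groups, n = 28),
while NAP/ST36 are each group's post records (n = 14); paired tests use
only the corresponding group's 14 rest–post pairs.

## Hubs

Degree on the masked network is, by default, the binary count of
FDR-significant incident edges; a weighted mode (sum of |edge values|,
node strength) is available for sensitivity analysis. A node is a hub
when degree ≥ mean + 1 SD, with the population SD (divisor N) as
default — the network's nodes are the full population of interest — and
the sample SD available via config. When all degrees are equal
(SD = 0) the hub set is defined as empty, avoiding the degenerate
all-hubs reading. Hubs are computed on the 16-node network and reported
at ROI level (an ROI is listed if either hemispheric node is a hub).

## Component selection

Active voxels are |Z| > 1.5, strictly. The template is a union of 5 mm
spheres (radius configurable) at published DMN coordinates; a
component's score is mean(Z inside) − mean(Z outside), which is
invariant to adding a constant to the whole map. Selection is the
argmax, ties broken toward the lowest index with a warning. ROI peaks
are the largest-|Z| active voxel within a search sphere per ROI
(coordinate ties broken lexicographically; inactive ROIs dropped with a
warning). Coordinates are used in world mm as given by each map's
affine; no Talairach/MNI conversion is applied.

## Validation studies and sizes

`dmnconn.validation` holds the calibration experiments that the test
suite and `scripts/acceptance.py` run:

- **Oracle equivalence** — 50 random 8-variable SPD covariances;
  precision rescaling vs the Schur-complement (regression-residual)
  partial correlation; agreement to 1e−8 (observed ~1e−15).
- **Null FDR calibration** — 200 replicates of 16 regions × 14 subjects
  × 10,800 samples (alpha band); mean false-discovery proportion within
  2 Monte-Carlo SEs of q = 0.05.
- **Support recovery** — planted 16-edge ring at strength 0.4, 14
  subjects, 10,000 samples, 20 replicates; sensitivity ≥ 0.9 and FDP ≤
  0.15.
- **Band specificity** — three edges planted in theta only; full
  broadband-sum → per-band filter → estimate path; detection in theta
  and no planted-edge rejection off-band in ≥ 18/20 replicates.
- **End-to-end** — a 5-edge delta-band star around PCC_L (strength 0.3)
  plus a +0.3 post delta on PCC_L–STG_L; full pipeline; the hub grid
  lists PCC only in the delta row and the verum change table classifies
  PCC–STG as increased.
- **Component selection** — 100 bundles of 10 maps (in-template Z = 2,
  noise SD = 0.5, default 4 mm grid, 16-sphere template); the patterned
  map wins every time.

These sizes keep a full run at a few minutes on one CPU; every quantity
is recomputed at run time from freshly simulated data.

One property of the hub rule deserves emphasis: in an otherwise empty
network (a null band), a single chance FDR false-positive edge gives
its two endpoints degree 1 against a zero background — mean 0.125,
SD ≈ 0.33 on 16 nodes — so both endpoints exceed mean + SD and appear
as "hubs". At q = 0.05 and 15 band × condition cells, roughly half of
simulated studies show at least one such spurious off-band hub, and it
implicates any given ROI with probability ≈ 2/16 per false edge. The
replicated end-to-end experiment therefore reports the planted-hub and
planted-edge recovery rates (≈ 1) separately from the off-band
hub-free rate, which is bounded by this property of the rule rather
than by estimation error.

## Known limitations

- Gaussian stationary model only; no assessment under nonstationarity,
  artifacts or realistic source leakage.
- Adjacent bands share an edge frequency, so strong coupling in one
  band leaks a small correlated component into its neighbors'
  filters; at the simulated strengths the leaked partial correlation
  is far below detectability at n = 14, but extreme couplings could
  cross bands.
- The bilateral-collapse and hub conventions (absolute-value ordering,
  binary degree, population SD, 16-node hub level) are explicit choices
  where the analysis tradition is ambiguous; all are configurable.
- The unregularized precision estimate requires T comfortably above the
  region count; no graphical-lasso-style sparse estimation is provided.
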