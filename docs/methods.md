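# Methods

This note documents the models, parameter choices and numerical conventions
behind each module, what the synthetic generators do and do not emulate, and
the known limitations.

## Coordinates and units

Genomic coordinates are real-valued kilobases, 0-based, in half-open
intervals `[start, end)`. Spread measurements in μm convert to Kb through a
`Calibration` (default 3.9 Kb/μm, estimated from measurements of a 47.26 Kb
probe as `probe_kb / mean(measured μm)`, with the standard error propagated
first-order from the SEM of the measurements). BED output uses the same Kb
convention; a `bp` dialect (÷1000 on read) and μm input (converted through a
calibration) are supported.

## Spread generator and morphometrics

**Lognormal parameterisation.** Track lengths and gaps are lognormal. Only
arithmetic means are calibrated quantities (15 Kb tracks, 30 Kb gaps), so the
log-mean is derived as μ = ln m − σ²/2 and the log-SD is a convention,
defaulting to σ = 0.6, which gives visibly right-skewed, unimodal
distributions of the kind seen on spreads. Both σ values are exposed.

**Cluster structure.** Tracks per cluster are `round(N(8, 2))`, resampled
below the minimum of 2. Intra-cluster gaps are rejection-truncated below the
100 Kb cluster bound and inter-cluster spacers above it. The truncation makes
ground-truth clusters *exactly* recoverable by the detection rule, which is
what makes parameter-recovery tests well-posed; it also pulls the realised
mean gap to ≈29 Kb (the analytic mean of the <100 Kb-truncated lognormal with
nominal mean 30). The spacer mean of 670 Kb is chosen so one cluster unit —
8×15 Kb of track, 7×~29 Kb of gap, one spacer — is ~990 Kb with 120 Kb
active, i.e. a ~12% genome-active fraction, matching the rod fraction used by
the copolymer model. Fibres hold all generated clusters unless
`clusters_per_fibre` is set; clusters never span fibres.

**Marks.** Transcript and polymerase marks per track are Poisson with rates
0.7 and 0.8 and uniform positions inside the track. The observed dispersions
on spreads (SD ≈ 1 and 0.9) are slightly super-Poissonian; plain Poisson
(SD = √rate) is the default approximation and a negative-binomial option
(`mark_dispersion`) is exposed. Mark counting in the morphometrics module is
by half-open containment; marks outside every track are reported as orphans,
never dropped silently.

**Estimators.** The lognormal fit is the closed-form MLE (mean and population
SD of logs). All reported summary SDs are sample (n−1) SDs, the convention
for summaries of the 150–200-track samples this emulates. Cluster detection
uses gap = next.start − previous.end with a strict `< 100 Kb` comparison, so
a gap of exactly 100 Kb separates clusters.

## Sliding-window co-expression test

Windows are `[k·step, k·step + window)` for every start inside the
chromosome, truncated at the end; defaults 500 Kb / 5 Kb. The statistic is
the count of expressed genes whose midpoint falls in the window (a fraction
option is exposed; with positions fixed under permutation it orders windows
identically). The null shuffles expressed labels over gene positions, per
chromosome by default (genome-wide exposed). The empirical p of a window is
the fraction of permuted statistics strictly below the observed one, and a
window is significant when that exceeds the significance quantile (default
0.95) — i.e. the observed count beats the 0.95 quantile of its own null.
With discrete counts ties make the rule conservative: the realised
type-I rate over non-overlapping windows is at or somewhat below 5%. No
multiple-testing correction is applied beyond the quantile itself, matching
the original analysis; overlapping windows share genes, so genome-wide
significant-window counts are strongly autocorrelated and merged regions
(overlapping/book-ended significant windows) are the interpretable output.
The test needs no gene-expression model: callers provide binary calls.

## Nucleus images and focus statistics

Foci are filled ellipses of fixed area πr² (default r = 6 px) with aspect
ratio e^{|N(0, s²)|}; s defaults to 0.4665, calibrated numerically so the
analytic mean shape factor (exact elliptic-integral perimeter) equals 0.93.
Placement is uniform inside the nuclear mask with rejection to keep foci
disjoint — per-focus ground truth is only meaningful for disjoint foci — and
generation fails loudly if the requested density cannot be placed in 200
tries per focus. Gaussian pixel noise is added and images are written as
16-bit TIFF. No optical PSF, chromatic shift or 3D stack is simulated; the
images emulate contrast and shape statistics, not microscope physics, so
passing tests validate the measurement chain, not robustness to real optics.

**Shape factor.** Circularity 4πA/P² with both A and P taken from the
0.5-level contour of the lightly Gaussian-smoothed (σ = 1 px) binary region
(marching squares, shoelace area). The smoothing suppresses the pixel-lattice
staircase that inflates raw contour lengths of smooth objects by ~5%:
rasterised discs of radius ≥ 10 px score ≥ 0.98, while a 50 px square scores
0.81 against the exact π/4 ≈ 0.785 (corner rounding; within 0.03). Plain
pixel-edge counting is deliberately not used — it biases circularity far from
1 for discs. Regions too small to carry a contour (1–2 px) yield NaN.

**Segmentation and CV.** The focus threshold is Otsu's bimodal split of the
within-mask intensities; components below `min_area_px` (default 5) are
dropped. The disassembly score is CV = population SD / mean of the masked
intensities, invariant under intensity rescaling. The dispersal generator
scales focus radii by f and amplitudes by 1/f², conserving integrated signal,
so CV decreases monotonically along the series — the computational analogue
of progressive formamide disassembly. Treatment comparison reports per-group
mean/SD of per-nucleus CV and pairwise mean differences with a percentile
bootstrap; groups below the recommended 200 nuclei are analysed but flagged.

## Lattice copolymer model

The chain is a single self-avoiding walk on the simple cubic lattice with
hard walls, one bead ≈ 1 Kb, labels rod/coil from the block specification.
Energy, in kT at fixed temperature 1:

    E = −ε_rr · #{non-bonded rod–rod lattice-contact pairs}
        + κ_rod · #{non-collinear consecutive bond pairs centred on a rod}

Defaults ε_rr = 3, κ_rod = 2 sit in the phase-separated, semi-stiff regime at
desk scale. Sampling is Metropolis with symmetric proposals: corner flips,
crankshaft rotations of U-shaped bead pairs, end-bond rotations (and optional
reptation with a full energy recompute). Energy is updated incrementally from
the local neighbourhood of moved beads; the trace is verified against a
from-scratch recompute in the tests, and the sampler's stationary
distribution is verified against exhaustive Boltzmann enumeration of a 4-bead
chain on a 5³ box. The kernel is JIT-compiled (numba) and deterministic given
the seed.

**Compositions and protocol.** The paper-scale composition (15-bead rods,
30-bead intra-cluster coils, 8 rods/cluster, 670-bead spacers; 12% rod) is
the `default_block_spec`. Local-move Monte Carlo relaxes a chain in ~N³
steps, so the phase-behaviour experiments use a geometrically similar
desk-scale composition (5-bead rods, 10-bead coils, 4 rods/cluster, 117-bead
spacer; 167 beads, 12% rod) and a 50%-rod comparator with the same rod block
length, which a few million steps genuinely equilibrate. The protocol is:
melt athermally (ε = 0) from the extended start, switch on ε, and
time-average domain metrics over production snapshots; phase comparisons
average over five seeds. Treatments re-equilibrate an already phase-separated
conformation: formamide maps to ε → 0 (solvent for the self-assembled phase),
DRB/heat-shock/NaCl leave ε unchanged (they strip polymerases or labile
protein, not the acetylation-driven contact).

**Domain metrics.** Domains are connected components of rod beads under
6-adjacency. Shape is the relative anisotropy of the gyration tensor,
κ² = [(λ1−λ2)² + (λ1−λ3)² + (λ2−λ3)²] / [2(λ1+λ2+λ3)²] ∈ [0, 1] (0 isotropic,
1 collinear), size-weighted across domains; single beads contribute 0.

All conclusions from this model are qualitative analogues of the microscopy
observations (domain formation, sphericity of the minority phase, treatment
responses), not quantitative predictions; no liquid-crystalline order
parameter, multi-chain/trans interaction, or field-theoretic phase diagram is
computed.

## Pipeline

Stage seeds derive deterministically from the global seed via a stable stage
hash into `numpy.random.SeedSequence`; reruns with the same configuration
are byte-identical. All writes are atomic (temp file + rename). The
configuration round-trips losslessly through YAML.

## Desk-scale problem sizes

Recovery runs use ~10,000 tracks (1,300 clusters), 500 clusters for span
statistics, ten 100 Mb chromosomes for the active fraction (averaged to
suppress the heavy-tailed spacer noise), 200 images for the shape factor,
100 probe measurements for the calibration, and 500–1,000 permutations for
the window test. These sizes put Monte-Carlo error well inside the
dispersions being recovered.

## Known limitations

- The generator emulates summary statistics of spreads, not fibre images;
  track extraction from micrographs is out of scope.
- Gap truncation (needed for exact truth recovery) biases the realised mean
  gap ~1 Kb below nominal; the bias is analytic and documented above.
- The lognormal dispersions, window-null choices (statistic, scope,
  permutation count) and the whole lattice formalism are explicit modelling
  conventions where the original study states none.
- Single-chain simulation only; trans (inter-chromosomal) factory formation
  is not modelled.
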