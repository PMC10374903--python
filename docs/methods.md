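# Methods

## Scope and data model

`psmfeat` consumes three inputs per run: a Percolator pin file (tab-separated
PSM table whose columns between `ScanNr` and `Peptide` are rescoring
features), the matching MS/MS spectra (MGF or mzML; retention time is
normalised to minutes, ion mobility captured as 1/K0 when present), and a
predicted-property library keyed by (stripped sequence, modification set,
precursor charge) — peptides differing in PTMs or charge are distinct
entries. Each entry carries up to 12 annotated b/y fragments at charge 1–2
with predicted intensities, one predicted RT on an arbitrary normalized
scale, and optionally one predicted 1/K0. Modified peptides are written in
bracketed-delta notation (`n[42.0106]PEPC[57.02146]K`; position 0 is the
N-terminus). Modifications reported twice at one position are aggregated by
summing their deltas. Library keys round delta masses to 4 decimals so pin
files and libraries reporting different precision still meet.

## Fragment masses and PTM shifting

Fragment m/z is monoisotopic: `b_i` sums residues 1..i (plus N-terminal
modification), `y_i` sums the i C-terminal residues plus one water, plus
`z` protons over `z` (proton 1.00727646688 Da, water 18.0105646863 Da,
residue masses from pyteomics). Only b/y at charge 1–2 are modelled; neutral
losses and other ion series are out of scope.

When a PSM carries a modification the prediction model does not support
(the supported set defaults to carbamidomethyl 57.0215, oxidation 15.9949
and N-terminal acetyl 42.0106 and is configurable), the library entry for
the supported counterpart is adjusted: every fragment whose residue span
covers the modified position is shifted by delta/fragment-charge, with
intensities, predicted RT and predicted IM copied unchanged. This is an
approximation — the true intensity pattern of the modified peptide may
differ — but it preserves the m/z register that matching depends on.

## Matching and similarity

For each predicted fragment the single most intense experimental peak
within the tolerance (default 20 ppm; an absolute-Da mode exists) is
selected; ties go to the closer m/z, then to the lower m/z, so matching is
deterministic. Unmatched positions are zero-filled, producing predicted and
experimental vectors of one common length. Selection within a PSM is
non-exclusive — two predicted fragments may claim one peak. Exclusivity is
enforced only across DIA ranks: after a PSM is scored, each of its selected
peaks is deleted once from the working copy of the spectrum before the next
rank is matched. (The alternative of deleting *every* in-tolerance peak per
fragment was considered and rejected as more aggressive than needed; the
single selected peak is what carried the evidence.)

The entropy similarity uses unit-sum normalisation (the score is defined on
probability vectors); cosine uses L2. An all-zero experimental vector scores
0 rather than NaN so every PSM receives a numeric value — downstream
rescoring tools do not accept missing values. The same worst-case convention
drives all sentinels: similarities 0, deltas a large constant (default 100),
probabilities the uniform-prior floor `P_U`.

## Calibration

Confident PSMs are rank-1 targets with expectation value below 10^−3.5
(≈3.16×10⁻⁴), capped at 5000 by ascending e-value. Pin files do not
standardise an e-value column, so the column name and a transform
(`identity`, `pow10_of_negated`, `exp_of_negated`) are configuration;
the default expects a `−log10(e)`-style column. With fewer than 50
qualifying PSMs an ordinary least-squares line replaces LOESS; with none,
RT/IM features fall back to sentinels and a warning.

LOESS is local linear with tricube weights and no robustness iterations;
the span is the fraction of points per window (0.05 RT, 0.1 IM) with a floor
of 3 points. The fitted values at the training abscissae are then passed
through isotonic regression (pool-adjacent-violators), and queries
interpolate linearly between the resulting knots, clamping outside the
training domain. Ion mobility gets one model per precursor charge; charges
with fewer than 50 confident PSMs share a pooled all-charge model.
Calibration is fitted per spectral file, not globally: co-analysed files
need not share chromatography.

`delta_RT_loess` is `|f(RT_exp) − RT_pred|` on the predicted scale. The
normalized variant divides by the interquartile range of the absolute
calibration residuals — a robust spread estimate chosen here because the
normalizer is otherwise unspecified; a zero IQR (perfect training fit)
falls back to the raw delta with a warning. Models serialize to JSON
(knots, domain, diagnostics) for reproducibility.

## KDE probability with uniform prior

The experimental axis is divided into equal bins (1 min RT, 0.01 1/K0 IM,
per charge for IM). Each confident PSM adds its *predicted* value to the bin
of its *experimental* value with integer multiplicity
`clamp(floor(−log10 e), 1, 10)` — the qualitative rule is that
better-scoring PSMs count more; this specific formula is this package's
choice and is configurable. Only confident target PSMs populate bins,
matching the calibration set. Each bin's expanded sample gets a Gaussian KDE
with Silverman bandwidth `h = 1.06·σ̂·m^(−1/5)`; zero-variance bins use a
floor bandwidth of 0.1·bin-width to avoid degenerate kernels.

The prior pseudo-count `U` is the occupancy of the bin at the 10th
percentile of occupancies (nearest rank, ties toward the smaller bin), and
`P_U = 1/(range width)` where the range is the span of all predicted values
padded by 1%. The feature is `(P_U·U + P_E·E)/(U+E)`: exactly `P_U` for an
empty bin, converging to the KDE density `P_E` as the bin fills. This damps
the otherwise arbitrarily high densities of near-empty bins.

## Pipeline

Per pin/spectra pair: resolve every PSM to a library entry (shifting for
unsupported PTMs), fit calibrations and KDE bins from that file's confident
PSMs, then walk scans in ascending scan number and ranks in ascending rank,
computing the configured features; in DIA mode matched peaks are consumed
between ranks (up to the configured rank depth, 3 for narrow-window and 5
for conventional DIA being typical settings). New feature columns are
inserted immediately before `Peptide`, serialized with `%.6g`; original
columns, row order and the `Proteins` field (which may itself contain tabs)
are preserved verbatim, so a read–write cycle without new features is
byte-identical. There is no randomness anywhere in the feature path: two
runs on the same inputs produce identical bytes.

## Synthetic data generator

The simulator emulates the full input triple with known ground truth. Target
peptides are random tryptic-like sequences (length 7–15, C-terminal K/R,
charge 2:3 at 7:3); each receives a predicted spectrum (all b/y fragments
at charge 1–2, exponential random intensities, top 12 kept, base-peak
normalised), an elution time uniform over a 100-min gradient, a predicted RT
equal to a monotone warp of that time (identity, linear or sigmoid; sigmoid
default) plus Gaussian noise (σ = 1 predicted unit), and per-charge linear
IM maps (slopes 1.02/0.98, noise σ = 0.01). Target scans contain the
predicted fragments under multiplicative log-normal intensity noise
(σ = 0.3 default), 10% fragment dropout, 3 ppm m/z jitter and 10 uniform
background peaks. Decoy PSMs pair a scan with an unrelated shuffled-pool
peptide whose prediction is random, so their matched vectors and deltas
behave like chance. E-values are log-normal with overlapping target/decoy
distributions (log10 means −5 and −1.5). A tenth of target peptides carry a
phospho-like +79.96633 Da modification deliberately absent from the library,
exercising the shift path end to end. One seeded generator drives
everything; equal seeds give byte-identical files.

What the simulator does **not** emulate: instrument-specific noise shapes,
isotope envelopes, co-elution structure, retention-order errors by the
predictor, or realistic decoy fragment overlap (real decoys share short
sequence stretches with targets and score above zero). Passing tests
therefore demonstrate correctness of the mechanics and the expected
qualitative separations, not real-data identification gains.

## Problem sizes and numerical choices

The test suite and the acceptance script use 40–500 peptides and 40–1000
scans per simulated run, 20 seeds for trend assertions (noise monotonicity,
calibration RMSE vs n) — sizes chosen to make the statistics stable while
keeping a full run in seconds. Entropy similarity is clipped to [0, 1] to
absorb last-ulp excursions; identical normalized vectors score exactly 1 and
disjoint ones exactly 0. The calibration residual IQR treats values below
1e−10 of the data scale as zero. KDE densities are exact sums of Gaussians
(no grid approximation).

## Known limitations

* Fragment annotations are required for PTM shifting; unannotated library
  fragments are dropped with a warning rather than guessed.
* The e-value → multiplicity rule and the residual-IQR normalizer are
  reasonable defaults, not canonical definitions; both are configurable.
* mzML support covers the common uncompressed/zlib 32/64-bit float layout;
  exotic encodings (numpress) are not handled.
* No cross-run RT alignment, no 2-D joint RT×IM densities, no FDR
  estimation — the output is a feature table for downstream rescoring.
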