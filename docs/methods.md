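# Methods

## The scaling model

A computed isotropic shielding σ (ppm) is mapped to a chemical shift δ (ppm)
by a per-nucleus, per-model-chemistry line

    δ = (b − σ) / (−m),

with m and b obtained by unweighted ordinary least squares of σ on δ_exp
(σ = m·δ + b) pooled over all training compounds. The regression is oriented
with σ as the dependent variable because that is the direction in which the
conversion formula is algebraically stated and the direction that reproduces
the published factor magnitudes; no outlier exclusion or weighting is applied.
Fit diagnostics are n, r², and the RMSD of back-predicted shifts over the
training pairs. Fits with fewer than two points, no spread in δ_exp, or an
exactly zero slope are rejected as degenerate.

Comparing two factor pairs (f₁, f₂) over a shift interval uses the closed
form: σ := m₁δ + b₁, δ′ := (b₂ − σ)/(−m₂). The difference δ′ − δ is affine in
δ, so its maximum absolute value over a closed interval is attained at an
endpoint; both endpoints are evaluated and the larger absolute difference is
returned (identical lines short-circuit to exactly zero). The evaluation
intervals are the training set's observed per-nucleus shift ranges.

## Conformer ensembles

Populations follow w_i ∝ exp(−ΔG_i/RT) with ΔG_i the relative free energy in
kcal/mol (vibrational corrections are assumed included upstream; the module
does not distinguish G from E — the caller supplies one energy column).
Defaults: T = 298.15 K, R = 1.98720425864×10⁻³ kcal mol⁻¹ K⁻¹. Conformers
more than a 5 kcal/mol window above the minimum are excluded *before*
normalization; the retained weights sum to one. Energies are re-zeroed to the
ensemble minimum, so weighting is invariant to any constant offset. An
ensemble counts as single-conformer when the top weight reaches the 0.98
dominance threshold (ties break to the lowest conformer index).

Per-atom shieldings are population-averaged across retained conformers, then
symmetry-equivalent atoms within a site (methyl protons, symmetric ring
positions) are averaged arithmetically. Averaging happens on shieldings, not
on scaled shifts; under a fixed linear map the two orders are equivalent, and
averaging first keeps the pipeline single-pass.

## Packaged fixtures

The probe-set table is a direct transcription of published per-compound
summary statistics (20 compounds, 96–854 g mol⁻¹; RMSD/MD per method and
nucleus; absent literature cells stay absent; one conformer count is a
published lower bound, flagged as such). "Lowest-or-tied" tallies compare
RMSD cells after half-up rounding to the printed decimals (2 for ¹H, 1 for
¹³C), so a shared printed best counts for every method holding it — that
convention reproduces the published 14/20 (¹H) and 16/20 (¹³C) best-method
counts for the high-accuracy protocol.

The DELTA50 per-site list is a synthetic stand-in
(`data/delta50_synthetic_shifts.csv`): the 50 compound identities follow the
published set, per-site values are literature-typical CDCl₃ shifts, and the
table is constrained to every published summary fact — 50 compounds, 114 ¹H
and 143 ¹³C equivalence-collapsed sites, range endpoints 0.25/9.80 ppm (¹H)
and −2.9/219.4 ppm (¹³C), ¹H values at two decimals. One diastereotopic
terminal-vinyl pair (3,3-dimethyl-1-butene) is stored as two ¹H sites; all
other equivalent nuclei collapse to one site with multiple atom indices.
Atom numbering is this package's own convention (carbons 1..n_C, then
hydrogens); per-compound shift values and numbering therefore support
integrity checks, range-driven computations, and pipeline tests, but are not
a source for per-compound experimental comparisons. A manifest (counts,
ranges, SHA-256 checksums) is verified on every load.

## Synthetic data

The generator emulates the statistical structure of benchmark residuals:
shieldings on a known line σ = m·δ + b plus homoscedastic Gaussian noise
(defaults 0.08 ppm for ¹H, 1.5 ppm for ¹³C — the typical RMSD magnitudes of
good model chemistries). Shifts are drawn uniformly over the training-set
range for the nucleus when not supplied. Conformer ensembles draw relative
energies uniformly on [0, spread] and jitter per-conformer shieldings
N(0, jitter²) around the site line, recording the exact population-weighted
average for cross-checks. Real residuals additionally carry functional-group
systematics (carbonyls, olefins and sp carbons deviate most); these are
deliberately not emulated, so passing tests demonstrate correctness of the
fitting/averaging/statistics machinery, not accuracy claims about any real
model chemistry. All randomness flows through one
`numpy.random.default_rng(seed)` stream per invocation.

## Numerical choices

- OLS via `scipy.stats.linregress`; the test suite cross-checks it against an
  independent normal-equations solver to ≤ 1e−10 on the slope.
- Printed-precision comparisons use half-up rounding (`decimal`), matching
  how tables are typeset; internal arithmetic is full double precision.
- The canonical shielding table round-trips floats via `repr` and re-reads
  with pandas' round-trip parser, so write→read→write is byte-identical and
  every σ survives to full precision. Rows are canonically ordered
  (compound, conformer, atom index ascending).
- Absolute energies in hartree convert at 1 hartree = 627.5094740631 kcal/mol
  before re-zeroing.
- Difference histograms bin on a half-open grid [lo, hi) anchored at a
  configurable center (default 0), so a boundary value falls in the
  right-open bin above it.
- Weights are validated to sum to 1 within 1e−9 before ensemble averaging;
  normalization itself is exact to ≤ 1e−12.

## Problem sizes

Tests and the acceptance script run on the packaged fixtures (50 + 20
records) and synthetic sets of up to 143 sites × 200 replicates; the whole
suite completes in a few seconds on one CPU. Parameter-recovery checks use
n = 143 sites at 1.5 ppm noise — the size and scatter of the ¹³C training
problem — and require the fitted slope within 3 standard errors of truth in
≥ 99% of replicates.

## Known limitations

- The package never runs quantum chemistry; it consumes shieldings and
  energies produced elsewhere (log summary blocks or CSV tables).
- The packaged DELTA50 site list is a stand-in (above); per-compound values
  are not the measured dataset.
- Scaling is a single global line per nucleus; motif-specific multi-line
  schemes and single-reference (TMS) conversions are out of scope.
- No significance testing between methods; ranking is by point statistics.
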