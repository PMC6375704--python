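# Methods

## Model

A DNA locus with one Sox2 site and one Oct4 site is a continuous-time Markov
process on four microstates {e, s, o, so}, specified as a labeled directed
graph (the linear framework). Binding edges carry labels k⁺·[X] (on-rate ×
free TF concentration); unbinding edges carry off-rates k⁻. Assumptions
inherited from the experimental analysis: the system is at steady state over
the measurement timescale; free TF concentrations are unchanged by binding
(many more TF molecules than sites); the graph is reversible; and all
complexity beyond the two sites (chromatin, co-regulators) is coarse-grained
into effective rates.

Steady states are computed by the Matrix-Tree prescription: ζⱼ is the sum
over spanning trees rooted at j of the product of edge labels, and
Pr(j) = ζⱼ / Σᵢζᵢ. This holds whether or not detailed balance holds. At
equilibrium it reduces to multiplying label ratios K = k⁺[X]/k⁻ along any
path from e, which is path-independent exactly when every cycle satisfies
the cycle condition R = 1, with

R = k₁⁺k₃⁺k₄⁻k₂⁻ / (k₃⁻k₁⁻k₂⁺k₄⁺)

for the unique four-cycle. R equals ω_OS/ω_SO, the ratio of the two
concentration-independent cooperativities ω_SO = k₄⁺k₁⁻/(k₄⁻k₁⁺) and
ω_OS = k₃⁺k₂⁻/(k₃⁻k₂⁺); at equilibrium they coincide and their common value
is the cooperativity ω. Binding-order asymmetry is computed from the
embedded jump chain and equals
k₁⁺k₃⁺(k₂⁻+k₄⁺[S]) / (k₂⁺k₄⁺(k₁⁻+k₃⁺[O])) — a kinetic quantity independent
of R (k₄⁻ does not appear).

## TF ↔ DNA bridge and the statistics

Each scenario's measurement summarizes the TF as a two-state graph with
κ = bound time / search time, so the bound fraction of TF molecules is
κ/(1+κ). Equating the bound-complex concentration seen from the TF and DNA
viewpoints gives κ = Bα/(A + B(1−α)) with α = [DX]tot/[X]tot, A ∝ total
probability of microstates with the measured TF unbound, B ∝ bound.
Equivalently αPᵢ = κᵢ/(1+κᵢ), so the ratios P₄/P₁ and P₃/P₂ are α-free. The
package computes ρ = κ₁κ₃/(κ₂κ₄) and Γ = (P₄/P₁−1)(P₃/P₂−1) in its
α-cancelled κ form. κ is formed as a ratio of mean times (not a mean of
ratios), matching the published procedure.

Two precision modes are exposed because the published values are internally
inconsistent: full-precision κ give ρ = 3.033 and Γ = −0.2259, while the
printed two-significant-figure κ column gives κ₄/κ₁ = 0.86, κ₃/κ₂ = 2.57,
ρ = 3.000 and Γ = −0.2056; the originally published ρ = 3.05 reflects
pre-rounding intermediates not recoverable from the printed table. Γ is
reported both rounded and truncated toward zero at two decimals, since the
published −0.22 is consistent with truncation of −0.2259. No attempt is
made to reconcile these; both modes are first-class.

## Scenario semantics

"Not induced" is modeled as the other TF's concentration set to 0, reducing
the locus to two microstates — never as site saturation, which is the
assumption the re-analysis rejects. "Maximally induced" is a finite
concentration supplied by the caller. P₁ and P₂ are therefore independent of
the induced concentrations, and P₄ (P₃) depends only on [Oct4ⁱ] ([Sox2ⁱ]);
surface evaluation exploits this factorization, costing one 4-state steady
state per axis value instead of per grid point.

## Genomic diversity

Two locus types in proportions l and 1−l, independent (no inter-locus
cooperativity, pairwise cooperativity only within a locus). Independence
makes the joint graph a product graph whose steady state factorizes and
whose additive occupancy functions average additively, so the genome-wide
bound fraction is Pᵢ = l·Pᵢ,₁ + (1−l)·Pᵢ,₂. The product-graph code exists to
validate this shortcut (tested on 16-state products against per-type
computation); production computation always uses the mixture formula.
Induced concentrations are shared genome-wide — diversity enters through
rates, not local concentrations. The fig3D on-rates are written as powers of
ten (e.g. `10**-0.2`) and evaluated in double precision.

## Monte-Carlo significance

Each of the eight mean residence times is drawn independently from
Normal(mean, SEM), with SEM = SD/√N and N = 3, the conservative minimum,
because the true per-scenario sample count could not be determined from the
source data (the fixture records N = 3 with that caveat; N is overridable).
κᵢ, then ρ or Γ, are recomputed per draw; tail fractions P(ρ≤1) and P(Γ≥0)
carry binomial standard errors and running-convergence checkpoints at 10⁵
and 10⁶ draws. Nonpositive sampled times are rejected and redrawn, with the
rejection count reported — for the measured table every mean is ≥ 13 SEMs
above zero, so rejections do not occur in practice. Noise is normal on the
time scale (not log-times) for consistency with this sampling model. The
generator is numpy's seeded default (PCG64); targets are distributional, not
stream-exact. Defaults: 10⁶ draws for Γ (where the published estimate had
converged to three figures) and 10⁷ for ρ. For P(ρ≤1), only the Monte-Carlo
count is reported (zero at 10⁷ draws) plus a clearly-labeled normal-
approximation figure on request; no analytic tail bound is claimed.

## Synthetic data

The generator emulates the study's structure: a ground truth is a rate-table
pair (one per cell line), α ratios and induced concentrations; true κ/ρ/Γ
are derived through the same bridge the analysis uses. Datasets are emitted
in the fixture's CSV schema with per-scenario unbinding rates chosen so
bound times sit at 8–14 s, the scale of the real table; reported SDs equal
noise_cv × true mean and reported means average n_samples noisy replicates.
What this does *not* emulate: fluorophore photophysics, localization error,
the diffusive substructure of the unbound state, or any within-nucleus
heterogeneity — passing round-trip tests shows the inference machinery is
self-consistent, not that the two-state summary of real movies is correct.

Random rate tables are drawn log-uniformly on [0.1, 10]; equilibrium tables
are constructed by solving for k₃⁺ and k₄⁺ from a target ω (making R = 1
exactly), and non-equilibrium ones by scaling k₄⁻ to a target R, mirroring
the single-off-rate perturbation used in the figure models.

## Numerical choices

- ζ via the all-minors determinant of the reduced out-Laplacian
  (`numpy.linalg.det`); exhaustive rooted-tree enumeration is kept as a test
  oracle for ≤ 6 vertices, and a dense SVD null-space solve of the master
  equation is the independent cross-check (agreement to 1e-10 relative on
  randomized graphs). Tiny negative determinant round-off is clipped to 0.
- Zero labels are allowed and mean absent transitions (concentration 0);
  ζ may be 0 at unreachable vertices and normalization runs over nonzero ζ;
  all-zero ζ is an error.
- Detailed balance uses relative flux tolerance 1e-9 (float products over
  ≤ 8 labels); the Kolmogorov cycle criterion is tested as an equivalent
  characterization, not used as the implementation.
- Surface grids default to 50×50 log-spaced on [0.01, 100] per induced
  concentration; the published plots do not state their ranges, so the
  default brackets the −0.22 crossing generously, and grid minima are
  flagged when they land on the boundary. The acceptance script refines
  50 → 100 → 200 per axis until the minimum moves < 1e-4 relative.
- K-type quantities are always binding over unbinding (the opposite of a
  dissociation constant); an operation that needs an unknown α raises rather
  than assuming a default.

## Problem sizes

Default runs use 10⁶ draws for Γ significance and 10⁷ for ρ (vectorized in
10⁶-row chunks), 50×50 surface grids, 10⁴-point sign-theorem scans, 10⁵
first-passage trials and ~3×10⁴ time-unit trajectories; these sizes give
Monte-Carlo errors far below the effects being tested while keeping any
single run in seconds to a couple of minutes on one core.

## Known limitations

- Exhaustive tree enumeration is exponential and intended only for small
  oracle graphs; the determinant path handles everything else.
- The mixture model has exactly two locus types and no inference of l or
  per-type rates from data; real genomic diversity is far richer.
- Only pairwise, within-locus cooperativity is represented; higher-order
  effects are out of scope.
- Time-dependent (pre-steady-state) behavior and irreversible edges are not
  supported.
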