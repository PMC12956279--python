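# Methods

## Scope and models

The package covers four computations around retron-expressed single-stranded
DNA (RT-DNA) carrying a fluorogenic aptamer cargo, plus the synthetic-data
generators that make them testable without any experimental download.

### Secondary structure and insertion design

The folding engine maximizes a weighted non-crossing base-pair score
(Nussinov-style interval dynamic programming): weights G·C = 3, A·T = 2,
G·T = 1 (the G·T wobble is stable enough in DNA hairpins to score), minimum
hairpin loop 3 unpaired residues. This is a deliberate score surrogate for
a nearest-neighbor free-energy model: the design task only needs a reliable
partition of positions into stems and loops, not calibrated energies, and
the engine interface accepts any callable returning a `FoldResult` so a
thermodynamic folder can be substituted. Traceback ties are broken by
pairing the smallest index with its smallest admissible partner, which makes
predictions deterministic.

The *msr*-overlapping region of the retron ncRNA is sequestered in an
RNA/DNA duplex in vivo and must not fold intramolecularly. The default
treatment is a hard pairing mask (region kept, forbidden from pairing),
which preserves coordinates for downstream insertion design; a trim mode
(`DnaSequence.trim_mask`) removes the region instead, since folding either
the full sequence under a mask or the truncated sequence are both
defensible readings of "omitting" the overlap.

Insertion sites are midpoints of maximal unpaired runs of length ≥
`min_run` (default 3), ranked by run length, then class priority
hairpin loop > exterior > internal loop/bulge, then position. The ranking
is a reported heuristic — longer single-stranded stretches have more room
to absorb a cargo without rearranging the scaffold — not an asserted
biological ordering. Fold preservation is the fraction of scaffold pairs
that reappear, index-shifted by the cargo length, in the refolded fusion;
a pairless scaffold is vacuously preserved (1.0).

### qPCR abundance

Comparative-CT with an amplification efficiency fixed at 2.0 per cycle
(exposed as a parameter): technical CT replicates are averaged
arithmetically, ΔC_T = inside − outside, ΔΔC_T = induced − uninduced, fold
F = 2^(−ΔΔC_T), summarized per biological replicate as mean ± SD. Because
the inside amplicon counts RT-DNA + plasmid templates and the outside
amplicon counts plasmid only, N_rt = (F − 1)·N_p; F < 1 (normal in
uninduced samples) is flagged and clamped to zero copies rather than
raised. Concentration uses N_A = 6.02214076e23 /mol and a default
cytoplasmic volume of 7e-16 L. Defaults for the plasmid copy number
(15–20, pBR322 origin) bound the estimate from both sides.

### Equilibrium binding

Because aptamer K_d values are comparable to the reagent concentrations,
depletion matters and the exact single-site (quadratic) isotherm is used.
All series share C₀, C₁ and the fluorogen concentration B_t; B_t is
nominally known (1 µM in the presets) but carries stock-concentration
uncertainty, so it is fitted inside a ±20% relative box — a concrete
quantification of "strong constraints" chosen as typical pipetting/stock
error. Fitting is bounded trust-region least squares over
(C₀, C₁, B_t, K_d…) with 8 multi-starts, K_d initialized log-uniformly in
[0.01, 100] µM (seeded), C₀ at min(F) and C₁ at the observed span; the
lowest residual sum wins, ties to the earliest start. Multi-start matters
because the isotherm is weakly identifiable when K_d ≫ max(A_t). The
radicand is clamped at zero to absorb floating-point negatives at exact
saturation. A series with zero fluorescence span is flagged degenerate
(C₁ → 0, K_d unidentifiable).

Confidence intervals are percentile intervals from a residual-resampling
bootstrap (default B = 1000, minimum 100). Bootstrap refits warm-start
from the point estimate with a single start; the multi-start search is only
needed for the cold initial fit. The CI method is this package's choice —
the numbers it produces are internally calibrated, not comparable to any
externally reported interval for the same constructs.

Numerical note: as K_d → 0 the isotherm converges to the stoichiometric
piecewise-linear limit C₀ + C₁·min(A_t, B_t)/B_t at rate O(K_d) away from
the kink but only O(√(K_d·B_t)) at A_t = B_t, where the radicand vanishes;
tests tolerate accordingly.

### Half-life

Growth is fitted first (logistic: OD_max, r, t₀ by least squares;
initialization from the curve's maximum, half-maximum crossing, and span),
then substituted into the decay model — no joint fit, matching the
sequential structure of the procedure. The decay model's "+1" floor is
interpreted as the plasmid contribution to the qPCR fold change (an
uninduced culture sits at fold 1). The reference time of the dilution
ratio OD(t_ref)/OD(t) is the first sampling time of the decay series; it
is a distinct quantity from the logistic midpoint t₀ even though both are
conventionally written t₀. k is bounded to [0, 1] /min (no negative
degradation); fits start from both the pure-dilution and a fast-decay
initial point. Fitted k below 1e-6 /min — chosen far below 1/(10× the
~23 min doubling time implied by the default growth rate) — is reported as
an infinite half-life ("beyond the detection limit"). Fixed-half-life
refits solve the then-linear amplitude in closed form and report the
residual sum for comparison against the free fit.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); the noise-free mode of
each round-trips exactly through its fitter, which the tests assert.

- **CT tables**: CT = 35 − log₂(templates) + Normal(0, 0.15 cycles); the
  intercept is arbitrary and cancels in ΔΔC_T (asserted by test). Additive
  Gaussian cycle noise is the standard CT error model. Default condition:
  120 RT-DNA molecules against a 17-copy plasmid (an ~8-fold enrichment).
- **Titrations**: isotherm × (1 + Normal(0, 2%)) on a 12-point log grid
  0.05–40 µM at B_t = 1 µM; presets `FL` (K_d 0.12 µM) and `4LEv4`
  (K_d 6 µM) span the tight- and weak-binding regimes of the study
  conditions, with plateaus C₀ = 100, C₁ = 1000 on an arbitrary
  plate-reader-like scale.
- **Growth/decay**: logistic OD (OD_max 2.5, r 0.03 /min, t₀ 150 min —
  a rich-medium batch culture with a ~25–30 min midpoint doubling time)
  with 2% multiplicative noise; decay series with amplitude 7 (an ~8-fold
  induced signal over the plasmid floor) and 5% noise, sampled every
  20 min for 4 h.
- **Scaffolds**: GC-clamped stems joined by all-A loops and spacers, a
  synthetic stand-in for the real msd sequence (which is not reproduced
  here). Their designed hairpins are the maximum-score structure under the
  default weights, verified against a brute-force enumeration oracle.

What passing on this synthetic data does **not** show: real qPCR suffers
efficiency drift and pipetting covariance, real titrations have
construct-dependent plateaus and occasional aggregation artifacts, real
growth deviates from the logistic at diauxie and stationary entry, and the
base-pair-maximization fold is not a free-energy minimum. Recovery results
here certify the estimators' correctness under their own assumptions, not
instrument-level accuracy.

## Problem sizes

Stochastic suites use: 100 seeded titrations per binding regime; 50
replicates for K_d- and half-life-recovery medians; 500 random sequences
(length ≤ 18) for the folding-oracle comparison; a scaled-down bootstrap
coverage check (25 replicates at B = 200, threshold 80%, the binomial
relaxation of 90% coverage at that replicate count). These sizes keep the
full suite near half a minute while leaving every median estimate stable
to well under the tolerance it is tested against.

## Known limitations

- No pseudoknots, no RNA–DNA hybrid or 2'–5'-branched structure modeling,
  no nearest-neighbor energies, no melting-data calibration.
- No amplification-curve processing (CT values in, numbers out) and no
  densitometry (gel intensities are consumed as numbers).
- Single-site binding only; no cooperativity, kinetics, or ΔG
  interpretation.
- Deterministic population-level decay only; promoter leakiness after
  washout is not modeled.
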