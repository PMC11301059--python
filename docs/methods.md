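# Methods

## Site divergence between two ortholog groups

The statistic is the symmetric Kullback–Leibler divergence between the
per-column amino-acid compositions of two predefined sequence groups in
a pooled multiple sequence alignment,

KL(n) = Σᵢ p(i) log(p(i)/q(i)) + Σᵢ q(i) log(q(i)/p(i)),

summed over the 20 standard amino acids. It is zero iff the two
compositions are equal and grows with compositional contrast; it is a
ranking statistic, not a test — no null distribution or multiple-testing
correction is attached, and the package deliberately reports ranks, KL
values and conservation rather than p-values.

**Composition estimation.** Gaps and unknown residues (X) are excluded
from counts. Raw column frequencies typically contain zeros, for which
KL is undefined, so probabilities are estimated with an additive
pseudocount per amino acid: p(i) = (cᵢ + α)/(N + 20α), default α = 0.5
(a Jeffreys-style prior). α is exposed everywhere (`--pseudocount`); the
planted-site ranking is insensitive to α over 0.1–1 because the signal
is the contrast between modal residues, not the tail mass.

**Gap handling.** A column is evaluable only when both groups have
occupancy (non-gap, non-X fraction) ≥ `min_occupancy`, default 0.5.
Without this gate a column that is mostly gaps in one group receives a
composition estimated from a handful of residues and can top the ranking
spuriously.

**Log base.** Natural log by default. Changing the base rescales every
KL by the same constant, so the ranking is base-invariant; to make this
exact in floating point the ranking is always computed on natural-log
values and the requested base only rescales the reported numbers.

**Ties and determinism.** Ranking ties are broken by ascending column
index. All outputs (TSV report with a JSON parameter header) are
byte-identical across reruns for identical inputs and parameters.

**Conservation.** Per group and column: the modal residue's frequency
among non-gap, non-X residues, reported as a nearest-integer percentage;
modal ties break alphabetically.

**Coordinates.** Alignment columns are mapped to the 1-based ungapped
residue numbering of one reference sequence per group (the map is the
cumulative count of non-gap reference letters); columns where the
reference is gapped report "gap".

## Redundancy filtering and identity

Ortholog sets are thinned so that all pairwise identities fall below a
threshold (default 40%), because composition statistics are biased when
one subfamily is padded with near-identical sequences. Identity is
defined as (identical non-gap columns)/(columns with ≥ 1 residue), with
X never matching; for unaligned sequences a global pairwise alignment is
built first (match +1, mismatch 0, gap open −10, extend −1 — coarse
classical protein scoring, adequate because the 40% threshold is
coarse). The filter is greedy longest-first with lexicographic
tie-breaks: deterministic and seed-free, at the cost of not maximising
the kept-set size (greedy keeps a maximal, not maximum, set). Filtering
defaults to within-group scope, i.e. redundancy is judged against
members of the same ortholog group only; `--scope pooled` filters across
the union instead.

## Kinetics chain

**Initial velocity.** Ordinary least squares of signal vs time over the
earliest 20% of points (minimum 3), overridable by an explicit window or
fraction; v₀ = |slope| × conversion. The window choice trades bias
(curvature entering late points) against variance (few points); r² is
reported per trace so poor windows are visible, and a low r² warns
rather than fails. v₀ is invariant to a constant signal baseline.

**Conversion factors.** The molar-per-absorbance factor is a required
per-assay input, 1/(ε·l). The config defaults — 5.6×10⁻⁵ M/AU for
4-nitrophenol at 400 nm (ε ≈ 1.8×10⁴ /M/cm) and 1×10⁻⁴ M/AU for
phenylglyoxal at 250 nm (ε ≈ 1×10⁴ /M/cm), 1 cm path — are approximate
literature-order values supplied for convenience; any quantitative use
on real data should substitute instrument-calibrated values. Kₘ is
independent of the conversion factor; V_max and hence k_cat scale
linearly with it.

**Michaelis–Menten fit.** Nonlinear least squares of v = V·S/(Kₘ+S)
(scipy trust-region-reflective, both parameters bounded positive, tight
tolerances), initialised from the Hanes–Woolf linearisation
S/v = S/V_max + Kₘ/V_max, with a coarse fallback (V₀ = 1.2·max v,
Kₘ₀ = median S) when the linearisation is degenerate. Fits are
unweighted. Standard errors come from the covariance of the converged
solution. Requires ≥ 4 distinct substrate concentrations.
k_cat = V_max/[E]₀ and k_cat/Kₘ are computed as exact identities, never
refit. Replicates are fitted one by one and summarised as mean ± SD of
the parameters across replicates, rather than pooled into one fit.

## Synthetic data

**Alignments.** Per column, one of three regimes: conserved (a consensus
residue shared by both groups, carried by each sequence with probability
`background_conservation` = 0.9, otherwise a uniformly random other
residue), variable (uniform over the 20 amino acids in both groups;
fraction 0.1 of columns), or planted (group A carries its modal residue
with frequency `freq_a`, group B with `freq_b`; defaults 0.82 and 0.99,
the conservation regime in which specificity-determining positions are
typically reported). Gaps are injected i.i.d. at rate 0.02, except in
the two reference rows at planted columns so coordinates there are
always reportable. Group sizes default to 27 and 24. Sequences are drawn
independently — no phylogenetic correlation is simulated. This matches
the statistic's own assumption (the KL scan ignores phylogeny), but it
means passing tests demonstrate recovery under exchangeable sequences
only: on real data, clades of related sequences can inflate apparent
group contrast, and the within-group <40%-identity filter is the
mitigation. Real indel structure, alignment errors and long-branch
composition bias are likewise not emulated.

**Traces.** signal(t) = baseline ± min(v·t, S)/conversion + Gaussian
noise, with v = V·S/(Kₘ+S). The linear early-phase model (rather than
the integrated progress curve) is used because the pipeline consumes
only initial slopes; the truncation guard prevents unphysical
consumption, and the simulated curvature onset exercises the window
logic. For consumption assays the baseline defaults to S/conversion (the
substrate's own absorbance), for formation assays to 0.05 AU.

## Problem sizes and numerical choices

Validation studies use 51 sequences × 300 columns for the alignment scan
(the study-scale comparison), 100 seeded replicates for the planted-site
recovery rate, 8 log-spaced substrate levels spanning 0.2–5×Kₘ with 200
seeded replicates for the noisy Kₘ-recovery study, and assay durations
chosen so ≤ 20% of substrate is consumed at the lowest level (keeping
the fitted window in the linear phase). Noiseless rate data regenerate
(V_max, Kₘ) to relative 1e-6; "5% noise" means multiplicative Gaussian
noise on velocities in the rate-level study, and absorbance noise equal
to 5% of the mid-design signal swing in the trace-level study.

## Known limitations

- The divergence scan has no phylogenetic weighting; heavily sampled
  clades bias compositions (mitigated, not removed, by redundancy
  filtering).
- KL ranks sites but carries no significance level; the top site of an
  alignment with no true differentiation still exists.
- The greedy identity filter is order-dependent by design (longest
  first) and does not maximise the retained set.
- The kinetics model assumes steady-state Michaelis–Menten behaviour and
  ignores product inhibition, enzyme inactivation and substrate
  depletion beyond the linear window.
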