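# Methods

## Pause-escape kinetics

Paused elongation complexes escape the pause site as a pseudo-first-order
process, so in a single-round assay the fraction of signal in the paused
band follows

    f(t) = (f0 − c)·exp(−k·t) + c,        t½ = ln 2 / k.

`paused_fraction` defines f(t) = paused/(paused + escaped) — a bounded
proportion, which is how the decay of the paused species is described in
the literature this package serves; the unbounded ratio paused/escaped is
deliberately not used (the exponential model would then have no [0, 1]
interpretation). Time points with zero total signal are dropped with a
warning rather than imputed; a series keeps at least 4 usable points or is
rejected.

`fit_half_life` fits by unweighted nonlinear least squares
(`scipy.optimize.curve_fit`, bounded at f0 ∈ [0, 1.5], k ≥ 0) with f0
free, initialized from a log-linear regression of log f on t over the
positive fractions. The plateau c is fixed at 0 by default — single-round
assays decay to background — and freed by `with_plateau=True` for assays
with a non-escaping subpopulation. Two outcomes are distinguished: a fit
failure or a rate indistinguishable from zero yields a "no pause
detected" result (`pause_detected=False`, infinite half-life), not an
exception, because flat series are a real experimental outcome. The
detection rule is k·(t_max − t_min) ≥ 0.01, i.e. at least 1% decay over
the observed span; a bounded optimizer otherwise reports an arbitrarily
tiny positive rate for flat data, and no experiment resolves less decay
than that.

Conditions are compared as mean_ratio = mean(t½ condition)/mean(t½
reference) with Welch's unequal-variance t-test (Welch–Satterthwaite
degrees of freedom, two-sided p) computed on the untransformed
per-replicate half-lives; significance defaults to p < 0.05. When both
groups have zero variance the statistic is reported as t = 0, p = 1
(non-significant) rather than NaN.

## Folding window and coordinates

Genomic coordinates are 1-based; relative coordinates skip 0, with −1 the
pause nucleotide (3′ end of the paused transcript) and +1 the next
position to be incorporated. The folding window defaults to −30..−11: the
−10..−1 RNA is held in the RNA:DNA hybrid and cannot fold, and sequence
upstream of −30 belongs to contexts (or, in assay constructs, a designed
stem-loop) assumed not to interfere. Minus-strand windows are
reverse-complemented so every window reads 5′→3′ on the nascent
transcript; T→U happens only here. Sites whose window leaves the sequence
are flagged as edge sites and excluded from downstream statistics with a
reported count.

## Built-in hairpin folder

`fold_builtin` computes the exact minimum-free-energy structure over all
**single-hairpin** topologies: one helix of Watson–Crick/G·U pairs, with
bulges or internal loops of up to `max_bulge` (default 3) unpaired nt per
side between consecutive pairs, and a terminal loop of ≥3 nt. The
restriction is deliberate: 20-nt windows cannot accommodate multibranch
structures, so the single-hairpin space is complete at this scale and the
search (a memoized dynamic program over closing pairs, O(n²·max_bulge²))
is exact against brute-force enumeration — the test suite verifies
equality with an explicit enumeration oracle on 1000 random sequences up
to 14 nt.

Energies are an embedded, approximate Turner-2004-style table
(`energy_params.py`): stacking increments for all 6×6 pair combinations,
hairpin-loop initiation by loop size, bulge and internal-loop penalties
by unpaired size with Jacobson–Stockmayer extrapolation
(1.75·RT·ln(n/n_max)) beyond the table, and a 0.5 kcal/mol helix-end
penalty for A·U/G·U-closed ends. Coaxial stacking, dangles and
sequence-dependent loop terms are omitted. Consequently ΔG values differ
from ViennaRNA by up to ~1 kcal/mol, and the cross-engine contract is
agreement on the four stability bins, not on ΔG; the external engine
(`fold_external`, ViennaRNA bindings or `RNAfold` subprocess, parsed
verbatim) is the reference for exact published energies. If no structure
has negative energy, the unfolded structure (all dots, ΔG = 0) is
returned.

Energy bins partition ΔG at −1, −3 and −6 kcal/mol; boundary values are
assigned to the more stable bin (−3 → Stable). These half-open choices
are a package decision — the bins are stated in the literature as ranges
without boundary ownership.

## Hairpin geometry

`hairpin_features` parses the dot-bracket into the helix chain enclosing
the 3′-most hairpin loop: stem_bp counts its pairs, loop_nt the unpaired
span inside the innermost pair, bulge_nt all unpaired nt between
consecutive chain pairs. distance_to_pause_nt counts nt strictly between
the 3′-most paired base and −1, plus one: a stem ending at −11 has
distance 10, the length of the hybrid it must clear. Multi-hairpin
dot-brackets (possible from the external engine) are measured on the
3′-most hairpin — the one positioned to contact the polymerase — and
flagged.

## Consensus classes

The three elements are evaluated on the coding (transcript-sense) strand:
G at −10, pyrimidine (C/T) at −1, G at +1. The eight presence patterns
are kept as atomic, mutually exclusive classes; a display-grouping map
pools the single-element and G₋₁₀G₊₁ classes for bar-chart parity with
published summaries. Under uniform base composition the none class has
analytic frequency 0.75·0.5·0.75 ≈ 28.1% and the complete class 1/32 —
both used as test oracles.

## Controls and enrichment

Control datasets are uniform-random genomic positions (both windows
in-bounds, strand uniform), not shuffled sequences, preserving genome
composition. Defaults are 100 datasets of 26 222 sites — the combined
size of the three published NET-Seq pause lists the design mirrors.
Enrichment is the descriptive fold change observed/control-mean per
category, with the control SD reported for context; no hypothesis testing
is attached, as the fold changes are summaries, not inferences. A
category absent from all controls but observed is reported as `inf`.

## Liftover and overlap

Liftover extracts the strand-aware 50-nt window −49..+1 and exact-matches
it against both strands of the target genome; only a unique hit maps the
site (at the position aligning the −1 base), and 0 or ≥2 hits are
reported as unmapped with a reason. Exact matching suits near-identical
strains; a mismatch-tolerant search is a possible extension, not
implemented. Overlaps match two sites when they share sequence and strand
within |Δposition| ≤ tolerance (0–4 nt); matching is greedy by ascending
|Δ| (ties to lower coordinates) and one-to-one, so Venn counts are
well-defined; linked sites across sets form components, each counted once
in the region named by the datasets it spans. Tolerance 0 reduces to
exact intersection, and counts are permutation-invariant and monotone in
tolerance (all property-tested).

## Screening

The strict preset encodes the hisL architecture exactly: complete
consensus, 5-bp stem, 8-nt loop, distance 10, no bulges, and at least the
Stable bin (the published screen was conducted within the
stable-structure group). The relaxed preset — stem 4–7 bp, loop 4–10 nt,
distance 10–12 nt, Stable or better, consensus still required — is a
package decision: the original relaxed parameters were never published,
so these brackets widen each criterion symmetrically and every value is
exposed for exploration. Mechanism categories use consensus = complete or
partial Y₋₁G₊₁, hairpin = Stable/Hyperstable bin; the four categories
partition any site set.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* Genomes: i.i.d. bases at a chosen GC fraction (default test scale
  0.508, E. coli-like). No repeat structure, codon bias or transcription
  units — so passing tests demonstrate correctness of the annotation
  machinery, not robustness to genomic autocorrelation.
* Planted sites: consensus bases written at −10/−1/+1 and, when planned,
  a designed −30..−11 window. Hairpin stems are found by seeded random
  composition search using `fold_builtin` as the arbiter, which
  guarantees generator/annotator consistency by construction rather than
  by analytic design; a verification pass re-annotates every planted site
  and hard-asserts the truth table. Planted loci are ≥60 nt apart, so the
  31-nt footprints (−30..+1) cannot overlap.
* Kinetics: f(t) as above, with paused = S·f·ε₁ and escaped = S·(1−f)·ε₂,
  ε mean-one lognormal with coefficient of variation `cv` (default 0.10,
  a realistic densitometry error) — multiplicative noise applied
  independently to the two bands, as band quantification errors are.
  The default grid is 8 log-spaced points over [5 s, 4·t½]: early points
  constrain f0, the span covers ~94% of the decay. No time-zero loading
  artifacts, band overlap or background subtraction are modelled.
* Construct layout: promoter + 14-nt initiation + 10-nt spacer + pause
  region (−30..+5) + 18-nt downstream run-off, giving the 54-nt paused
  and 77-nt full-length transcripts of the standard assay; sequences are
  synthetic placeholders and the lengths are the contract.

## Problem sizes and numerical notes

The test suite and acceptance script run at desk scale by design:
kinetics recovery uses 50 replicate series (10 per group for the fold
change); the control-null and screening checks use a 1-Mb genome with
10⁵ control sites and 20 planted hisL-like sites among 500 random
background sites — large enough for the binomial SE on a ~28% frequency
(~0.14 percentage points at n = 10⁵) and for chance strict-screen false
positives to be negligible, while completing in seconds. The full
published control design (100 × 26 222 on 4.6 Mb) is the library default
and runs unchanged when asked for.

Numerical choices: fits are unweighted (gel quantification error is
roughly proportional, and fractions bound the scale); curve_fit failures
are caught, not retried with jitter; folding energies are compared to the
enumeration oracle at 1e-9; the planting search caps at 500 compositions
before declaring a target bin infeasible for the requested geometry.

## Known limitations

The built-in energy model is approximate (see above); predicted ΔG is
qualitative and cotranscriptional folding kinetics are not modelled. The
consensus is evaluated at exactly three positions — no extended motif
model. Liftover requires exact 50-mer identity. Controls are genome-wide,
not restricted to transcribed regions. The kinetics model assumes a
single paused species and first-order escape; multi-exponential escape is
out of scope.
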