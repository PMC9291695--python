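# pausekit

Tools for characterizing bacterial transcriptional pause sites — for
molecular biologists and bioinformaticians who work with in vitro
transcription kinetics and genome-wide (NET-Seq-style) pause maps.

RNA polymerase pauses at defined template positions, and two features
recur at well-studied pauses such as *E. coli hisL*: a DNA consensus
G₋₁₀Y₋₁G₊₁ (G ten nt upstream, a pyrimidine at the pause position −1, G at
the next incorporated position +1) and a nascent-RNA hairpin folding just
upstream of the RNA:DNA hybrid that stabilizes the paused complex, often
further stabilized by the elongation factor NusA. `pausekit` provides the
computational side of studying both features:

* **Kinetics** — paused elongation complexes escape with pseudo-first-order
  kinetics, so the paused fraction of gel signal decays as
  `f(t) = f0·exp(−ln2·t/t½)`. The package converts band intensities to
  fractions, fits `t½` by nonlinear least squares, and compares conditions
  with a fold change of mean half-lives plus Welch's unequal-variance
  *t*-test.
* **Structure** — extracts the −30..−11 folding window upstream of each
  pause (the −10..−1 hybrid is unavailable for folding), predicts its
  minimum-free-energy hairpin with either an exact built-in single-hairpin
  folder or ViennaRNA, sorts ΔG into four stability bins (Unstructured
  > −1, Weak −1..−3, Stable −3..−6, Hyperstable ≤ −6 kcal/mol), and parses
  stem/loop/distance geometry from the dot-bracket.
* **Consensus** — strand-aware classification of every site into the eight
  presence patterns of the three consensus elements.
* **Controls & enrichment** — ensembles of uniform-random genomic control
  sites and descriptive fold changes of consensus-class or energy-bin
  frequencies against the control mean.
* **Dataset comparison** — liftover between reference genomes by unique
  50-nt (−49..+1) window matching, and Venn overlap counts with a 0–4 nt
  positional tolerance.
* **Screening** — the *hisL*-like screen (complete consensus + 5-bp stem +
  8-nt loop ending 10 nt upstream, in at least the Stable bin; a relaxed
  preset widens the geometry) and the 2×2 mechanism categories
  (consensus-only / hairpin-only / both / neither).
* **Synthetic data** — random genomes, pause sites planted with known
  consensus class and hairpin geometry/stability (verified on creation),
  simulated kinetics tables, and the single-round assay construct layout
  (54-nt paused / 77-nt full-length transcripts).

Coordinates are 1-based on the reference; relative positions follow the
pause-map convention in which −1 is the pause nucleotide and there is no
position 0.

## Worked example

```python
from pausekit import (KineticsSimSpec, simulate_kinetics, paused_fraction,
                      fit_half_life, welch_fold_change)

wt = simulate_kinetics(KineticsSimSpec("WT", true_half_life_s=8.5, cv=0.10,
                                       replicates=5, seed=1))
nusa = simulate_kinetics(KineticsSimSpec("NusA", true_half_life_s=17.3, cv=0.10,
                                         replicates=5, seed=2))
fits_wt = [fit_half_life(s) for s in paused_fraction(wt)]
fits_nusa = [fit_half_life(s) for s in paused_fraction(nusa)]
res = welch_fold_change(fits_nusa, fits_wt)
```

Running this (`python examples/fit_pause_half_life.py`) prints:

```
    WT: fitted t1/2 = 8.1 ± 0.6 s (5 replicates)
 +NusA: fitted t1/2 = 18.5 ± 1.2 s (5 replicates)
fold change (+NusA / WT) = 2.27, Welch t = 16.89 (df 6.1), p = 2.2e-06
```

The simulated truth (8.5 s without NusA, 17.3 s with) is recovered within
noise, and the ~2-fold, significant increase is the kinetic signature of a
NusA-stabilized upstream hairpin. The other scripts in `examples/` walk
through window folding and binning (`fold_upstream_windows.py`),
control-based enrichment (`consensus_enrichment.py`), the *hisL*-like
screen and mechanism categories (`screen_hisl_like.py`), and
liftover/overlap (`compare_datasets.py`). A thin CLI mirrors the library:
`pausekit fold|classify|compare|controls|screen|fit|simulate` (see
`pausekit --help`).

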