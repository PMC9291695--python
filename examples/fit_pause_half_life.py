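"""Estimate pause half-lives from single-round transcription kinetics.

Simulates quantified gel-band time courses for a hairpin-stabilized pause
without and with the elongation factor NusA (which roughly doubles the
pause duration), fits each replicate to the pseudo-first-order escape
model f(t) = f0·exp(−ln2·t/t½), and compares conditions with Welch's
t-test on the per-replicate half-lives.
"""

import numpy as np

from pausekit import (
    KineticsSimSpec,
    fit_half_life,
    paused_fraction,
    simulate_kinetics,
    welch_fold_change,
)

wt = simulate_kinetics(KineticsSimSpec("WT", true_half_life_s=8.5, cv=0.10, replicates=5, seed=1))
nusa = simulate_kinetics(KineticsSimSpec("NusA", true_half_life_s=17.3, cv=0.10, replicates=5, seed=2))

fits_wt = [fit_half_life(s) for s in paused_fraction(wt)]
fits_nusa = [fit_half_life(s) for s in paused_fraction(nusa)]

for label, fits in (("WT", fits_wt), ("+NusA", fits_nusa)):
    hl = [f.half_life_s for f in fits]
    print(f"{label:>6}: fitted t1/2 = {np.mean(hl):.1f} ± {np.std(hl, ddof=1):.1f} s "
          f"({len(hl)} replicates)")

res = welch_fold_change(fits_nusa, fits_wt)
print(f"fold change (+NusA / WT) = {res.mean_ratio:.2f}, "
      f"Welch t = {res.welch_t:.2f} (df {res.welch_df:.1f}), p = {res.p_value:.2g}")
print("-> a ~2-fold, significant half-life increase is the signature of a "
      "NusA-stabilized upstream hairpin")
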