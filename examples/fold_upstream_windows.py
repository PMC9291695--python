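"""Predict the upstream hairpin of each pause site and bin its stability.

Builds a small synthetic genome with planted pause sites, extracts each
site's −30..−11 folding window (the 20 nt just upstream of the RNA:DNA
hybrid), folds it with the built-in single-hairpin folder, and reports the
dot-bracket, ΔG, stability bin and hairpin geometry.
"""

from pausekit import (
    ConsensusClass,
    EnergyBin,
    assign_energy_bin,
    extract_window,
    fold_builtin,
    generate_genome,
    hairpin_features,
    plant_pause_sites,
)
from pausekit.synthetic_data import HairpinPlan, PlantSpec, SitePlan, truth_sites

genome, truth = plant_pause_sites(
    generate_genome(10_000, gc_fraction=0.5, seed=5),
    PlantSpec(
        [
            SitePlan(ConsensusClass.COMPLETE, HairpinPlan(5, 8, -11, EnergyBin.STABLE)),
            SitePlan(ConsensusClass.COMPLETE, HairpinPlan(6, 4, -12, EnergyBin.HYPERSTABLE)),
            SitePlan(ConsensusClass.NONE, None),
        ]
    ),
    seed=6,
)

for site in truth_sites(truth):
    window = extract_window(genome, site)
    structure = fold_builtin(window)
    feats = hairpin_features(structure, window)
    bin_ = assign_energy_bin(structure.energy_kcal_mol)
    geom = (
        f"stem {feats.stem_bp} bp, loop {feats.loop_nt} nt, "
        f"distance {feats.distance_to_pause_nt} nt"
        if feats.stem_bp
        else "no hairpin"
    )
    print(f"{site.site_id}: {window.rna_sequence}")
    print(f"          {structure.dot_bracket}  ΔG = {structure.energy_kcal_mol:.1f} "
          f"kcal/mol [{bin_.value}]  ({geom})")
print("-> 'distance' counts from the 3' end of the stem to the pause site; "
      "10 nt means the stem ends right at the hybrid boundary, as for hisL")
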