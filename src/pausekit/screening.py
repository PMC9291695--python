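"""hisL-like hairpin-stabilized pause screening and mechanism categories.

The archetypal hairpin-stabilized pause (hisL) combines the complete
G₋₁₀Y₋₁G₊₁ consensus with a 5-bp stem / 8-nt loop hairpin whose stem ends
10 nt upstream of the pause (just clearing the RNA:DNA hybrid). The strict
screen looks for exactly this architecture; the relaxed screen widens
every geometric criterion. Mechanism categories split any site set by the
2×2 of (complete-or-partial consensus) × (stable-or-better hairpin).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import pandas as pd

from .consensus import ConsensusClass, classify_consensus
from .io_formats import Genome, PauseSite
from .structure import (
    BIN_ORDER,
    EdgeSiteError,
    EnergyBin,
    assign_energy_bin,
    extract_window,
    fold_builtin,
    hairpin_features,
)


@dataclass(frozen=True)
class ScreenCriteria:
    require_complete_consensus: bool = True
    stem_bp: tuple[int, int] = (5, 5)
    loop_nt: tuple[int, int] = (8, 8)
    distance_nt: tuple[int, int] = (10, 10)
    min_energy_bin: EnergyBin = EnergyBin.UNSTRUCTURED
    max_bulge_nt: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_bp", "loop_nt", "distance_nt"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty")


#: exact hisL architecture: complete consensus, 5-bp stem, 8-nt loop, stem
#: ending right at the hybrid boundary, no bulges; screened within the
#: stable-structure group, so the window must reach at least the Stable bin
STRICT = ScreenCriteria(min_energy_bin=EnergyBin.STABLE)

#: widened geometry; the energy must still reach the Stable bin
RELAXED = ScreenCriteria(
    stem_bp=(4, 7),
    loop_nt=(4, 10),
    distance_nt=(10, 12),
    min_energy_bin=EnergyBin.STABLE,
    max_bulge_nt=0,
)


class MechanismCategory(str, Enum):
    CONSENSUS_ONLY = "consensus_only"
    HAIRPIN_ONLY = "hairpin_only"
    BOTH = "both"
    NEITHER = "neither"


_CONSENSUS_OK = {ConsensusClass.COMPLETE, ConsensusClass.Y1_G1}
_HAIRPIN_OK = {EnergyBin.STABLE, EnergyBin.HYPERSTABLE}


def site_features(genome: Genome, site: PauseSite, engine=fold_builtin) -> dict:
    """Fold, parse geometry and classify one site; raises EdgeSiteError."""
    window = extract_window(genome, site)
    structure = engine(window)
    feats = hairpin_features(structure, window)
    cls = classify_consensus(genome, site)
    return {
        "site_id": site.site_id,
        "seq_name": site.seq_name,
        "position": site.position,
        "strand": site.strand,
        "consensus_class": cls.value,
        "dot_bracket": structure.dot_bracket,
        "energy_kcal_mol": structure.energy_kcal_mol,
        "energy_bin": assign_energy_bin(structure.energy_kcal_mol).value,
        "stem_bp": feats.stem_bp,
        "loop_nt": feats.loop_nt,
        "bulge_nt": feats.bulge_nt,
        "distance_to_pause_nt": feats.distance_to_pause_nt,
    }


def _passes(row: dict, criteria: ScreenCriteria) -> bool:
    if criteria.require_complete_consensus and row["consensus_class"] != ConsensusClass.COMPLETE.value:
        return False
    if row["stem_bp"] == 0:
        return False
    if not criteria.stem_bp[0] <= row["stem_bp"] <= criteria.stem_bp[1]:
        return False
    if not criteria.loop_nt[0] <= row["loop_nt"] <= criteria.loop_nt[1]:
        return False
    if not criteria.distance_nt[0] <= row["distance_to_pause_nt"] <= criteria.distance_nt[1]:
        return False
    if row["bulge_nt"] > criteria.max_bulge_nt:
        return False
    observed = BIN_ORDER.index(EnergyBin(row["energy_bin"]))
    return observed >= BIN_ORDER.index(criteria.min_energy_bin)


def screen_sites(
    genome: Genome,
    sites: list[PauseSite],
    criteria: ScreenCriteria = STRICT,
    engine=fold_builtin,
) -> pd.DataFrame:
    """Full feature row per site with a ``candidate`` pass/fail flag.

    Edge sites (windows out of bounds) are excluded; their count is in the
    DataFrame ``attrs['n_edge_excluded']``.
    """
    rows = []
    n_edge = 0
    for site in sites:
        try:
            row = site_features(genome, site, engine)
        except EdgeSiteError:
            n_edge += 1
            continue
        row["candidate"] = _passes(row, criteria)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["n_edge_excluded"] = n_edge
    return df


def classify_mechanism(
    genome: Genome, site: PauseSite, engine=fold_builtin
) -> MechanismCategory:
    """2×2 mechanism category of one pause site.

    Consensus present = complete or partial Y₋₁G₊₁ class; hairpin present
    = upstream window folds into the Stable or Hyperstable bin.
    """
    has_consensus = classify_consensus(genome, site) in _CONSENSUS_OK
    window = extract_window(genome, site)
    has_hairpin = assign_energy_bin(engine(window).energy_kcal_mol) in _HAIRPIN_OK
    if has_consensus and has_hairpin:
        return MechanismCategory.BOTH
    if has_consensus:
        return MechanismCategory.CONSENSUS_ONLY
    if has_hairpin:
        return MechanismCategory.HAIRPIN_ONLY
    return MechanismCategory.NEITHER


def widen(criteria: ScreenCriteria, **ranges) -> ScreenCriteria:
    """Convenience for exploring relaxed presets."""
    return replace(criteria, **ranges)
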