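"""Random genomic control datasets and fold-change enrichment.

Observed pause-site feature frequencies (consensus classes or upstream
energy bins) are compared against the mean frequency over an ensemble of
control datasets, each a set of uniform-random genomic positions with
uniform strand. Fold changes are descriptive (observed / control mean),
with the control standard deviation reported for context.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import ConsensusClass, classify_consensus
from .io_formats import Genome, PauseSite
from .structure import (
    EdgeSiteError,
    EnergyBin,
    assign_energy_bin,
    extract_window,
    fold_builtin,
)

#: default ensemble size mirrors the combined size of typical NET-Seq pause lists
DEFAULT_N_DATASETS = 100
DEFAULT_DATASET_SIZE = 26222

#: margin keeping both the −49..+1 liftover window and the −30..−11 folding
#: window in-bounds on either strand
EDGE_MARGIN = 50


@dataclass
class ControlEnsemble:
    genome_id: str
    seed: int
    datasets: list[list[PauseSite]]

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)


@dataclass
class EnrichmentTable:
    feature: str
    table: pd.DataFrame  # category, observed_freq, control_mean, control_sd, fold_change


def sample_controls(
    genome: Genome,
    n_datasets: int = DEFAULT_N_DATASETS,
    dataset_size: int = DEFAULT_DATASET_SIZE,
    seed: int = 0,
) -> ControlEnsemble:
    """Draw ``n_datasets`` control sets of uniform-random genomic sites.

    Positions are uniform over coordinates whose −49..+1 and −30..−11
    windows are fully in-bounds on either strand; strand is uniform over
    {+, −}. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    valid: list[tuple[str, int, int]] = []  # (name, lo, hi) inclusive position range
    for name, seq in genome.sequences.items():
        lo, hi = 1 + EDGE_MARGIN, len(seq) - EDGE_MARGIN
        if hi >= lo:
            valid.append((name, lo, hi))
    if not valid:
        raise ValueError("genome too short: no position with in-bounds windows")
    sizes = np.array([hi - lo + 1 for _, lo, hi in valid])
    total = int(sizes.sum())
    if dataset_size > total:
        raise ValueError(f"dataset_size {dataset_size} exceeds {total} valid positions")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    datasets = []
    for d in range(n_datasets):
        flat = rng.integers(0, total, size=dataset_size)
        strands = rng.integers(0, 2, size=dataset_size)
        sites = []
        for i, (fp, st) in enumerate(zip(flat, strands)):
            seq_idx = int(np.searchsorted(offsets, fp, side="right") - 1)
            name, lo, _ = valid[seq_idx]
            sites.append(
                PauseSite(name, lo + int(fp - offsets[seq_idx]), "+-"[st], f"ctrl{d}_{i}")
            )
        datasets.append(sites)
    return ControlEnsemble(genome.id, seed, datasets)


def _feature_of(genome: Genome, site: PauseSite, feature: str, fold_engine) -> str:
    if feature == "consensus":
        return classify_consensus(genome, site).value
    if feature == "energy_bin":
        window = extract_window(genome, site)
        return assign_energy_bin(fold_engine(window).energy_kcal_mol).value
    raise ValueError(f"unknown feature {feature!r}")


def feature_frequencies(
    genome: Genome, sites: list[PauseSite], feature: str, fold_engine=fold_builtin
) -> dict[str, float]:
    """Frequencies of consensus classes or energy bins over one site list."""
    categories = (
        [c.value for c in ConsensusClass]
        if feature == "consensus"
        else [b.value for b in EnergyBin]
    )
    counts: Counter[str] = Counter()
    n = 0
    for site in sites:
        try:
            counts[_feature_of(genome, site, feature, fold_engine)] += 1
            n += 1
        except EdgeSiteError:
            continue
    if n == 0:
        raise ValueError("no classifiable site")
    return {cat: counts.get(cat, 0) / n for cat in categories}


def enrichment(
    observed: list[PauseSite],
    controls: ControlEnsemble,
    feature: str,
    genome: Genome,
    fold_engine=fold_builtin,
) -> EnrichmentTable:
    """Per-category fold change of observed frequency vs control-mean frequency.

    Categories absent from every control set get fold change ``inf`` when
    observed (reported with the observed frequency intact).
    """
    obs = feature_frequencies(genome, observed, feature, fold_engine)
    control_freqs = [
        feature_frequencies(genome, ds, feature, fold_engine) for ds in controls.datasets
    ]
    rows = []
    for cat in obs:
        ctrl = np.array([cf[cat] for cf in control_freqs])
        mean, sd = float(ctrl.mean()), float(ctrl.std(ddof=1)) if len(ctrl) > 1 else 0.0
        if mean > 0:
            fold = obs[cat] / mean
        else:
            fold = float("inf") if obs[cat] > 0 else float("nan")
        rows.append(
            {
                "category": cat,
                "observed_freq": obs[cat],
                "control_mean": mean,
                "control_sd": sd,
                "fold_change": fold,
            }
        )
    return EnrichmentTable(feature, pd.DataFrame(rows))
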