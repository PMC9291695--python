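"""Generators for every input the pipeline consumes.

Random genomes with i.i.d. base composition, pause sites planted with a
chosen consensus class and (optionally) an upstream hairpin of chosen
geometry and stability bin, and single-round transcription kinetics under
pseudo-first-order escape with multiplicative lognormal noise. Every
generator is bit-reproducible under a fixed seed, and planting ends with a
verification pass that re-annotates each planted site with the package's
own classifiers and asserts the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusClass, classify_consensus
from .io_formats import Genome, PauseSite, revcomp
from .structure import (
    EnergyBin,
    FoldingWindow,
    assign_energy_bin,
    extract_window,
    fold_builtin,
    hairpin_features,
)

WINDOW = (-30, -11)

_PAIR_CHOICES = {
    EnergyBin.HYPERSTABLE: ["GC", "CG"],
    EnergyBin.STABLE: ["GC", "CG", "AU", "UA", "GU"],
    EnergyBin.WEAK: ["GC", "CG", "AU", "UA", "GU", "UG"],
    EnergyBin.UNSTRUCTURED: ["AU", "UA"],
}

#: which consensus elements each class asserts present
_CLASS_FLAGS = {
    ConsensusClass.COMPLETE: (True, True, True),
    ConsensusClass.Y1_G1: (False, True, True),
    ConsensusClass.G10_Y1: (True, True, False),
    ConsensusClass.G10_G1: (True, False, True),
    ConsensusClass.G10_ONLY: (True, False, False),
    ConsensusClass.Y1_ONLY: (False, True, False),
    ConsensusClass.G1_ONLY: (False, False, True),
    ConsensusClass.NONE: (False, False, False),
}


# ---------------------------------------------------------------------------
# genomes


def generate_genome(
    length: int, gc_fraction: float = 0.5, seed: int = 0, name: str = "chr",
    genome_id: str | None = None,
) -> Genome:
    """Random genome with i.i.d. bases at the requested GC fraction."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    if length < 200:
        raise ValueError("genome length must be >= 200")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    bases = rng.choice(np.frombuffer(b"AGCT", dtype="S1"), size=length, p=p)
    return Genome(
        {name: bases.tobytes().decode()}, id=genome_id or f"synthetic_seed{seed}"
    )


# ---------------------------------------------------------------------------
# planted pause sites


@dataclass(frozen=True)
class HairpinPlan:
    stem_bp: int = 5
    loop_nt: int = 8
    end_offset: int = -11  # relative position of the 3'-most paired base
    target_bin: EnergyBin = EnergyBin.STABLE


@dataclass(frozen=True)
class SitePlan:
    consensus: ConsensusClass = ConsensusClass.COMPLETE
    hairpin: HairpinPlan | None = None
    strand: str = "+"


@dataclass
class PlantSpec:
    plans: list[SitePlan]
    min_spacing: int = 60

    @property
    def n_sites(self) -> int:
        return len(self.plans)


def hisl_like_plan(target_bin: EnergyBin = EnergyBin.STABLE, strand: str = "+") -> SitePlan:
    """The strict-screen archetype: complete consensus + 5 bp / 8 nt / −11 hairpin."""
    return SitePlan(ConsensusClass.COMPLETE, HairpinPlan(5, 8, -11, target_bin), strand)


def _design_window(plan: HairpinPlan, rng: np.random.Generator, max_tries: int = 500) -> str:
    """Search stem compositions until the built-in folder lands the window
    in the target bin with the planned geometry.

    The generator uses the annotation-side folder as the arbiter, so the
    planted truth is consistent with downstream annotation by construction.
    """
    w_len = WINDOW[1] - WINDOW[0] + 1
    footprint = 2 * plan.stem_bp + plan.loop_nt
    tail = WINDOW[1] - plan.end_offset  # nt after the hairpin inside the window
    if tail < 0:
        raise ValueError("hairpin end offset lies downstream of the window")
    start = w_len - tail - footprint
    if start < 0:
        raise ValueError(
            f"hairpin (stem {plan.stem_bp}, loop {plan.loop_nt}) does not fit "
            f"the window ending at {plan.end_offset}"
        )
    choices = _PAIR_CHOICES[plan.target_bin]
    for _ in range(max_tries):
        pairs = [choices[rng.integers(len(choices))] for _ in range(plan.stem_bp)]
        loop = "".join("AC"[rng.integers(2)] for _ in range(plan.loop_nt))
        five = "".join(p[0] for p in pairs)
        three = "".join(p[1] for p in reversed(pairs))
        filler5 = "".join("AC"[rng.integers(2)] for _ in range(start))
        filler3 = "".join("AC"[rng.integers(2)] for _ in range(tail))
        seq = filler5 + five + loop + three + filler3
        structure = fold_builtin(seq)
        feats = hairpin_features(structure, FoldingWindow(seq, *WINDOW))
        if (
            assign_energy_bin(structure.energy_kcal_mol) == plan.target_bin
            and feats.stem_bp == plan.stem_bp
            and feats.loop_nt == plan.loop_nt
            and feats.bulge_nt == 0
            and feats.distance_to_pause_nt == -plan.end_offset - 1
        ):
            return seq
    raise ValueError(
        f"target bin {plan.target_bin.value} infeasible for stem {plan.stem_bp} bp / "
        f"loop {plan.loop_nt} nt within {max_tries} tries"
    )


def _unstructured_window(rng: np.random.Generator) -> str:
    """A window that cannot base-pair at all (A/C alphabet)."""
    w_len = WINDOW[1] - WINDOW[0] + 1
    return "".join("AC"[rng.integers(2)] for _ in range(w_len))


def _rel_index(position: int, strand: str, r: int) -> int:
    """0-based genomic index of relative position r (no zero)."""
    if strand == "+":
        return position + r if r < 0 else position + r - 1
    return position - r - 2 if r < 0 else position - r - 1


def plant_pause_sites(
    genome: Genome, spec: PlantSpec, seed: int = 0
) -> tuple[Genome, pd.DataFrame]:
    """Write planted pause sites into a copy of the genome; return truth table.

    Each plan writes its consensus bases at −10/−1/+1 and, when a hairpin
    is planned, a designed −30..−11 window whose built-in fold lands in
    the target bin with the planned geometry (sites without a hairpin plan
    get an unpairable A/C window). Loci are ≥ ``min_spacing`` apart. A
    final verification pass re-annotates every site and asserts the truth.
    """
    rng = np.random.default_rng(seed)
    (name, seq), *rest = genome.sequences.items()
    if rest:
        raise ValueError("planting supports single-sequence genomes")
    chars = bytearray(seq.encode())
    margin = 60
    lo, hi = 1 + margin, len(seq) - margin
    n_slots = (hi - lo) // spec.min_spacing + 1
    if spec.n_sites > n_slots:
        raise ValueError(f"not enough room for {spec.n_sites} sites {spec.min_spacing} nt apart")
    slots = rng.choice(n_slots, size=spec.n_sites, replace=False)
    slots.sort()
    positions = [lo + int(s) * spec.min_spacing for s in slots]

    rows = []
    for idx, (plan, pos) in enumerate(zip(spec.plans, positions)):
        site = PauseSite(name, pos, plan.strand, f"planted{idx}")
        window_rna = (
            _design_window(plan.hairpin, rng) if plan.hairpin else _unstructured_window(rng)
        )
        window_dna = window_rna.replace("U", "T")
        # write the window (coding sense) strand-aware
        i0 = _rel_index(pos, plan.strand, WINDOW[0])
        i1 = _rel_index(pos, plan.strand, WINDOW[1])
        if plan.strand == "+":
            chars[i0 : i1 + 1] = window_dna.encode()
        else:
            chars[i1 : i0 + 1] = revcomp(window_dna).encode()
        # write the consensus bases
        g10, y1, g1 = _CLASS_FLAGS[plan.consensus]
        for r, base in ((-10, "G" if g10 else "A"), (-1, "C" if y1 else "A"), (1, "G" if g1 else "A")):
            i = _rel_index(pos, plan.strand, r)
            chars[i : i + 1] = (base if plan.strand == "+" else revcomp(base)).encode()
        rows.append(
            {
                "site_id": site.site_id,
                "seq_name": name,
                "position": pos,
                "strand": plan.strand,
                "consensus_class": plan.consensus.value,
                "has_hairpin": plan.hairpin is not None,
                "stem_bp": plan.hairpin.stem_bp if plan.hairpin else 0,
                "loop_nt": plan.hairpin.loop_nt if plan.hairpin else 0,
                "end_offset": plan.hairpin.end_offset if plan.hairpin else 0,
                "target_bin": plan.hairpin.target_bin.value
                if plan.hairpin
                else EnergyBin.UNSTRUCTURED.value,
            }
        )

    planted = Genome({name: chars.decode()}, id=genome.id)
    truth = pd.DataFrame(rows)
    _verify_planting(planted, truth)
    return planted, truth


def _verify_planting(genome: Genome, truth: pd.DataFrame) -> None:
    """Hard assertion that annotation recovers every planted attribute."""
    for row in truth.itertuples(index=False):
        site = PauseSite(row.seq_name, row.position, row.strand, row.site_id)
        cls = classify_consensus(genome, site)
        assert cls.value == row.consensus_class, (
            f"{row.site_id}: planted {row.consensus_class}, classified {cls.value}"
        )
        window = extract_window(genome, site)
        structure = fold_builtin(window)
        assert assign_energy_bin(structure.energy_kcal_mol).value == row.target_bin, row.site_id
        if row.has_hairpin:
            feats = hairpin_features(structure, window)
            assert feats.stem_bp == row.stem_bp, row.site_id
            assert feats.loop_nt == row.loop_nt, row.site_id
            assert feats.distance_to_pause_nt == -row.end_offset - 1, row.site_id


def truth_sites(truth: pd.DataFrame) -> list[PauseSite]:
    return [
        PauseSite(r.seq_name, r.position, r.strand, r.site_id)
        for r in truth.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# kinetics simulation


@dataclass
class KineticsSimSpec:
    """Pseudo-first-order pause escape with multiplicative gel-band noise.

    ``cv`` parameterizes a mean-one lognormal factor applied independently
    to the paused and escaped band intensities, emulating densitometry
    noise on quantified lanes.
    """

    condition: str = "WT"
    true_half_life_s: float = 8.5
    f0: float = 0.6
    plateau: float = 0.0
    times_s: np.ndarray | None = None
    n_points: int = 8
    cv: float = 0.10
    replicates: int = 3
    signal_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_half_life_s <= 0:
            raise ValueError("true_half_life_s must be positive")
        if not 0 < self.f0 <= 1:
            raise ValueError("f0 must lie in (0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.times_s is None:
            # default grid: log-spaced over [5 s, 4 half-lives]
            self.times_s = np.geomspace(5.0, 4.0 * self.true_half_life_s, self.n_points)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.times_s) < 4:
            raise ValueError("need at least 4 time points")


def simulate_kinetics(spec: KineticsSimSpec) -> pd.DataFrame:
    """Simulate a kinetics table (condition, replicate, time_s, signals)."""
    rng = np.random.default_rng(spec.seed)
    k = math.log(2) / spec.true_half_life_s
    f = (spec.f0 - spec.plateau) * np.exp(-k * spec.times_s) + spec.plateau
    sigma = math.sqrt(math.log(1.0 + spec.cv**2))
    rows = []
    for rep in range(1, spec.replicates + 1):
        eps1 = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(f))) if spec.cv else np.ones_like(f)
        eps2 = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(f))) if spec.cv else np.ones_like(f)
        paused = spec.signal_scale * f * eps1
        escaped = spec.signal_scale * (1.0 - f) * eps2
        for t, ps, es in zip(spec.times_s, paused, escaped):
            rows.append(
                {
                    "condition": spec.condition,
                    "replicate": rep,
                    "time_s": float(t),
                    "paused_signal": float(ps),
                    "escaped_signal": float(es),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in vitro construct builder


@dataclass
class ConstructLayout:
    """Template layout for single-round transcription assays.

    Promoter + 14-nt initiation sequence + spacer + pause region (−30..+5)
    + downstream run-off. With the default 10-nt spacer and 18-nt
    downstream segment the paused transcript is 54 nt (initiation + spacer
    + 30 nt up to the −1 pause base) and the full-length run-off 77 nt.
    All sequences are synthetic placeholders; lengths are the contract.
    """

    pause_region: str = "A" * 35  # −30..+5 (synthetic placeholder)
    promoter: str = "TTTACACTTTATGCTTCCGGCTCGTATAATGTGTGG"  # synthetic σ70-style
    initiation: str = "ATCGAGAGGGACAC"  # 14 nt
    spacer: str = "GCGGCAGCCG"  # 10 nt
    downstream: str = "ATCGATCGATCGATCGAT"  # 18 nt

    def __post_init__(self) -> None:
        if len(self.initiation) != 14:
            raise ValueError("initiation sequence must be 14 nt")
        if len(self.pause_region) != 35:
            raise ValueError("pause region must cover −30..+5 (35 nt)")

    @property
    def template(self) -> str:
        return self.promoter + self.initiation + self.spacer + self.pause_region + self.downstream

    @property
    def paused_transcript_nt(self) -> int:
        # transcript 3' end at the −1 pause base: 30 nt of the pause region
        return len(self.initiation) + len(self.spacer) + 30

    @property
    def full_length_nt(self) -> int:
        return len(self.initiation) + len(self.spacer) + len(self.pause_region) + len(self.downstream)


def build_construct(pause_region: str | None = None, **kwargs) -> ConstructLayout:
    """Default assay construct; optionally substitute a real pause region."""
    if pause_region is not None:
        kwargs["pause_region"] = pause_region.upper().replace("U", "T")
    return ConstructLayout(**kwargs)
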