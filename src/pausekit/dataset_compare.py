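"""Cross-dataset pause comparison: sequence liftover and tolerant overlap.

Pause lists published against different reference strains are brought onto
one genome by unique matching of the 50-nt window −49..+1 around each
site, then compared as multi-set Venn partitions where two sites match iff
they lie on the same sequence and strand within a positional tolerance
(0–4 nt).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations

from .io_formats import Genome, PauseSite, revcomp
from .structure import EdgeSiteError, genomic_window

LIFTOVER_WINDOW = (-49, 1)


@dataclass
class PauseSet:
    name: str
    genome_id: str
    sites: list[PauseSite]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pause set {self.name!r}: duplicate site ids")


@dataclass
class LiftoverReport:
    mapped: list[PauseSite]
    unmapped: list[tuple[PauseSite, str]] = field(default_factory=list)


@dataclass
class OverlapResult:
    set_names: tuple[str, ...]
    region_counts: dict[frozenset, int]
    tolerance_nt: int

    def count(self, *names: str) -> int:
        """Count of pauses found in exactly the given datasets."""
        return self.region_counts.get(frozenset(names), 0)

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def _window_index(genome: Genome, k: int) -> dict[str, list[tuple[str, int, str]]]:
    """Index every k-mer of both strands → list of (seq_name, -1 position, strand).

    For a + strand occurrence starting at 0-based offset o, the −1 base of
    a −49..+1 window is at 1-based position o + k − 1 (one before the last
    window base). For a − strand occurrence (window is the revcomp of the
    slice), the −1 base sits at 1-based position o + 2.
    """
    index: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for name, seq in genome.sequences.items():
        for o in range(len(seq) - k + 1):
            kmer = seq[o : o + k]
            index[kmer].append((name, o + k - 1, "+"))
            index[revcomp(kmer)].append((name, o + 2, "-"))
    return index


def liftover_sites(
    sites: list[PauseSite], source_genome: Genome, target_genome: Genome
) -> LiftoverReport:
    """Map pause sites between genomes by unique 50-nt window matching.

    The strand-aware −49..+1 window is extracted from the source and
    exact-matched against both strands of the target; a unique hit maps
    the site to the target position aligning the −1 base. Zero or multiple
    hits leave the site unmapped with a reason.
    """
    k = LIFTOVER_WINDOW[1] - LIFTOVER_WINDOW[0]  # 50 (relative axis skips 0)
    index = _window_index(target_genome, k)
    report = LiftoverReport(mapped=[])
    for site in sites:
        try:
            window = genomic_window(source_genome, site, *LIFTOVER_WINDOW)
        except EdgeSiteError:
            report.unmapped.append((site, "edge"))
            continue
        hits = index.get(window, [])
        if len(hits) == 1:
            name, pos, strand = hits[0]
            report.mapped.append(PauseSite(name, pos, strand, site.site_id))
        elif not hits:
            report.unmapped.append((site, "not_found"))
        else:
            report.unmapped.append((site, "ambiguous"))
    return report


def _greedy_pair_matching(
    a: list[PauseSite], b: list[PauseSite], tolerance: int
) -> list[tuple[int, int]]:
    """One-to-one matches between two site lists.

    Candidates (same sequence, same strand, |Δposition| ≤ tolerance) are
    taken greedily by ascending |Δposition|, ties broken by lower
    coordinates, each site used at most once.
    """
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for jb, sb in enumerate(b):
        by_key[(sb.seq_name, sb.strand)].append(jb)
    candidates = []
    for ia, sa in enumerate(a):
        for jb in by_key.get((sa.seq_name, sa.strand), []):
            d = abs(sa.position - b[jb].position)
            if d <= tolerance:
                candidates.append((d, sa.position, b[jb].position, ia, jb))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, _, ia, jb in candidates:
        if ia not in used_a and jb not in used_b:
            matches.append((ia, jb))
            used_a.add(ia)
            used_b.add(jb)
    return matches


def overlap_sets(sets: list[PauseSet], tolerance_nt: int = 0) -> OverlapResult:
    """Venn partition counts of 2–3 pause sets under positional tolerance.

    Pairwise one-to-one greedy matching links sites across sets; linked
    components (union-find) are the shared pauses, and each component
    contributes one count to the region named by the datasets it spans.
    """
    if not 0 <= tolerance_nt <= 4:
        raise ValueError("tolerance must be between 0 and 4 nt")
    genome_ids = {s.genome_id for s in sets}
    if len(genome_ids) > 1:
        raise ValueError(
            f"pause sets are on different genomes {sorted(genome_ids)}; "
            "run liftover_sites first"
        )
    names = tuple(s.name for s in sets)
    if len(set(names)) != len(names):
        raise ValueError("pause set names must be unique")

    # union-find over (set index, site index)
    parent: dict[tuple[int, int], tuple[int, int]] = {
        (si, i) for si, ps in enumerate(sets) for i in range(len(ps.sites))
    }
    parent = {node: node for node in parent}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for (si, sa), (sj, sb) in combinations(enumerate(sets), 2):
        for ia, jb in _greedy_pair_matching(sa.sites, sb.sites, tolerance_nt):
            union((si, ia), (sj, jb))

    members: dict[tuple[int, int], set[str]] = defaultdict(set)
    for node in parent:
        members[find(node)].add(names[node[0]])
    region_counts: dict[frozenset, int] = defaultdict(int)
    for present in members.values():
        region_counts[frozenset(present)] += 1
    return OverlapResult(names, dict(region_counts), tolerance_nt)
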