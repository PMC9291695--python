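"""Classification of pause sites by the G₋₁₀Y₋₁G₊₁ consensus elements.

The elemental pause consensus consists of three sequence elements read on
the coding (transcript-sense) strand: a G ten nucleotides upstream of the
pause (−10), a pyrimidine (C or T) at the pause position itself (−1, the
3′ end of the paused transcript), and a G at the next position to be
incorporated (+1). Each site falls into exactly one of eight classes
according to which elements are present.
"""

from __future__ import annotations

from collections import Counter
from enum import Enum

from .io_formats import Genome, PauseSite
from .structure import EdgeSiteError, _rel_to_genomic
from .io_formats import revcomp


class ConsensusClass(str, Enum):
    COMPLETE = "G10_Y1_G1"
    Y1_G1 = "Y1_G1"
    G10_Y1 = "G10_Y1"
    G10_G1 = "G10_G1"
    G10_ONLY = "G10_only"
    Y1_ONLY = "Y1_only"
    G1_ONLY = "G1_only"
    NONE = "none"


_CLASS_BY_FLAGS = {
    (True, True, True): ConsensusClass.COMPLETE,
    (False, True, True): ConsensusClass.Y1_G1,
    (True, True, False): ConsensusClass.G10_Y1,
    (True, False, True): ConsensusClass.G10_G1,
    (True, False, False): ConsensusClass.G10_ONLY,
    (False, True, False): ConsensusClass.Y1_ONLY,
    (False, False, True): ConsensusClass.G1_ONLY,
    (False, False, False): ConsensusClass.NONE,
}

#: display grouping used by bar-chart style summaries: single elements and
#: the G−10/G+1 pair are typically pooled
DISPLAY_GROUPS = {
    ConsensusClass.COMPLETE: "complete",
    ConsensusClass.Y1_G1: "partial_Y1G1",
    ConsensusClass.G10_Y1: "G10_Y1",
    ConsensusClass.G10_G1: "single_or_G10G1",
    ConsensusClass.G10_ONLY: "single_or_G10G1",
    ConsensusClass.Y1_ONLY: "single_or_G10G1",
    ConsensusClass.G1_ONLY: "single_or_G10G1",
    ConsensusClass.NONE: "none",
}


def base_at(genome: Genome, site: PauseSite, rel: int) -> str:
    """Coding-strand base at a relative position (no position 0)."""
    g = _rel_to_genomic(site.position, site.strand, rel)
    seq = genome[site.seq_name]
    if not (1 <= g <= len(seq)):
        raise EdgeSiteError(f"site {site.site_id!r}: relative {rel} out of bounds")
    b = seq[g - 1]
    return b if site.strand == "+" else revcomp(b)


def classify_from_bases(b10: str, b1: str, bp1: str) -> ConsensusClass:
    """Classify from the coding-strand bases at (−10, −1, +1)."""
    return _CLASS_BY_FLAGS[(b10 == "G", b1 in "CT", bp1 == "G")]


def classify_consensus(genome: Genome, site: PauseSite) -> ConsensusClass:
    """Strand-aware consensus class of one pause site."""
    return classify_from_bases(
        base_at(genome, site, -10), base_at(genome, site, -1), base_at(genome, site, 1)
    )


def class_frequencies(
    genome: Genome, sites: list[PauseSite]
) -> tuple[dict[ConsensusClass, float], dict[ConsensusClass, int], int]:
    """Per-class frequencies over classifiable sites.

    Returns (frequencies, counts, n_excluded); frequencies sum to 1 over
    the classifiable sites, edge sites are excluded and counted.
    """
    counts: Counter[ConsensusClass] = Counter()
    excluded = 0
    for site in sites:
        try:
            counts[classify_consensus(genome, site)] += 1
        except EdgeSiteError:
            excluded += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no classifiable site")
    freqs = {cls: counts.get(cls, 0) / total for cls in ConsensusClass}
    return freqs, {cls: counts.get(cls, 0) for cls in ConsensusClass}, excluded
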