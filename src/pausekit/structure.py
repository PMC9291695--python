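"""Upstream folding-window extraction, hairpin MFE prediction and geometry.

The nascent-RNA structure suspected to stabilize a pause folds immediately
upstream of the RNA:DNA hybrid. Because the hybrid (−10..−1) is not
available for folding, the default folding window covers positions −30 to
−11 relative to the pause site (20 nt, ending 10 nt upstream of the pause
nucleotide).

Two folding engines are provided with the same contract (dot-bracket +
ΔG in kcal/mol):

* :func:`fold_builtin` — an exact dynamic program over single-hairpin
  topologies (one helix with bounded bulges/internal loops, terminal loop
  ≥3 nt) scored with the embedded nearest-neighbour table in
  :mod:`pausekit.energy_params`.
* :func:`fold_external` — ViennaRNA (Python bindings if importable,
  otherwise the ``RNAfold`` executable).

Engines are expected to agree at the level of the four stability bins
(Unstructured / Weak / Stable / Hyperstable), not of exact ΔG.
"""

from __future__ import annotations

import functools
import re
import shutil
import subprocess
from dataclasses import dataclass
from enum import Enum

from . import energy_params as ep
from .io_formats import Genome, PauseSite, revcomp

DEFAULT_WINDOW = (-30, -11)
MAX_BUILTIN_LEN = 40


class EdgeSiteError(ValueError):
    """The requested window extends past the end of the sequence."""


class EnergyBin(str, Enum):
    UNSTRUCTURED = "Unstructured"
    WEAK = "Weak"
    STABLE = "Stable"
    HYPERSTABLE = "Hyperstable"


#: bins ordered from least to most stable, for threshold comparisons
BIN_ORDER = [EnergyBin.UNSTRUCTURED, EnergyBin.WEAK, EnergyBin.STABLE, EnergyBin.HYPERSTABLE]


@dataclass(frozen=True)
class FoldingWindow:
    rna_sequence: str
    rel_start: int
    rel_end: int
    site_id: str = ""

    def __post_init__(self) -> None:
        if set(self.rna_sequence) - set("ACGU"):
            raise ValueError("folding window must be pure ACGU")
        expected = self.rel_end - self.rel_start + (0 if self.rel_start < 0 < self.rel_end else 1)
        if len(self.rna_sequence) != expected:
            raise ValueError(
                f"window length {len(self.rna_sequence)} does not match "
                f"[{self.rel_start}, {self.rel_end}]"
            )


@dataclass(frozen=True)
class SecondaryStructure:
    dot_bracket: str
    energy_kcal_mol: float

    def __post_init__(self) -> None:
        if set(self.dot_bracket) - set(".()"):
            raise ValueError("dot-bracket may contain only '.', '(' and ')'")
        depth = 0
        for c in self.dot_bracket:
            depth += c == "("
            depth -= c == ")"
            if depth < 0:
                raise ValueError("unbalanced dot-bracket")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket")

    @property
    def is_folded(self) -> bool:
        return "(" in self.dot_bracket


@dataclass(frozen=True)
class HairpinFeatures:
    """Geometry of the (single) helix parsed from a dot-bracket.

    ``distance_to_pause_nt`` counts the nt strictly between the 3′-most
    paired base and the −1 pause position, plus one — a hairpin whose stem
    ends at −11 therefore sits at distance 10, the length of the RNA:DNA
    hybrid it must clear.
    """

    stem_bp: int
    loop_nt: int | None
    bulge_nt: int | None
    distance_to_pause_nt: int | None
    multi_hairpin: bool = False


def _rel_to_genomic(position: int, strand: str, r: int) -> int:
    """Map a relative coordinate (no zero) to a 1-based genomic position."""
    if r == 0:
        raise ValueError("relative position 0 does not exist")
    if strand == "+":
        return position + r + 1 if r < 0 else position + r
    return position - r - 1 if r < 0 else position - r


def genomic_window(genome: Genome, site: PauseSite, rel_start: int, rel_end: int) -> str:
    """Strand-aware DNA slice covering [rel_start, rel_end] around a site.

    Returned 5′→3′ on the coding (transcript-sense) strand. The relative
    axis skips 0, so a window crossing the pause position (e.g. −49..+1)
    is contiguous on the genome.
    """
    if rel_start >= rel_end:
        raise ValueError("rel_start must precede rel_end")
    seq = genome[site.seq_name]
    g1 = _rel_to_genomic(site.position, site.strand, rel_start)
    g2 = _rel_to_genomic(site.position, site.strand, rel_end)
    lo, hi = min(g1, g2), max(g1, g2)
    if lo < 1 or hi > len(seq):
        raise EdgeSiteError(
            f"site {site.site_id!r}: window [{rel_start},{rel_end}] out of bounds "
            f"({lo}..{hi} on sequence of length {len(seq)})"
        )
    dna = seq[lo - 1 : hi]
    return dna if site.strand == "+" else revcomp(dna)


def extract_window(
    genome: Genome,
    site: PauseSite,
    rel_start: int = DEFAULT_WINDOW[0],
    rel_end: int = DEFAULT_WINDOW[1],
) -> FoldingWindow:
    """Extract the upstream folding window as RNA (T→U)."""
    dna = genomic_window(genome, site, rel_start, rel_end)
    if "N" in dna:
        raise EdgeSiteError(f"site {site.site_id!r}: window contains N")
    return FoldingWindow(dna.replace("T", "U"), rel_start, rel_end, site.site_id)


# ---------------------------------------------------------------------------
# built-in single-hairpin folder


def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Score a single-hairpin structure (pairs sorted outermost-first).

    Energy = helix-end penalties on the outermost and loop-closing pairs
    + stack/bulge/internal-loop increments between consecutive pairs
    + the hairpin-loop initiation for the terminal loop.
    """
    if not pairs:
        return 0.0
    e = ep.terminal_penalty((seq[pairs[0][0]], seq[pairs[0][1]]))
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        left, right = k - i - 1, j - l - 1
        if left == 0 and right == 0:
            e += ep.stack_energy((seq[i], seq[j]), (seq[k], seq[l]))
        elif left == 0 or right == 0:
            e += ep.bulge_penalty(left + right)
        else:
            e += ep.internal_penalty(left + right)
    ki, kj = pairs[-1]
    e += ep.hairpin_penalty(kj - ki - 1)
    e += ep.terminal_penalty((seq[ki], seq[kj]))
    return e


def fold_builtin(
    window: FoldingWindow | str, max_bulge: int = 3, min_loop: int = 3
) -> SecondaryStructure:
    """Exact MFE over all single-hairpin structures of a short RNA.

    One helix of Watson–Crick/G·U pairs, with bulges/internal loops of up
    to ``max_bulge`` unpaired nt per side between consecutive pairs, and a
    terminal loop of at least ``min_loop`` nt. If no structure has
    negative energy, the unfolded structure (all dots, 0.0) is returned.
    """
    seq = window.rna_sequence if isinstance(window, FoldingWindow) else window
    if set(seq) - set("ACGU"):
        raise ValueError("fold_builtin requires a pure ACGU sequence")
    n = len(seq)
    if n > MAX_BUILTIN_LEN:
        raise ValueError(f"built-in folder is bounded at {MAX_BUILTIN_LEN} nt (got {n})")

    @functools.lru_cache(maxsize=None)
    def best_inside(i: int, j: int) -> tuple[float, tuple]:
        """Best energy inward of pair (i, j), including (i, j)'s loop terms."""
        close = ep.hairpin_penalty(j - i - 1) + ep.terminal_penalty((seq[i], seq[j]))
        best, trace = close, ()
        for k in range(i + 1, i + 2 + max_bulge):
            for l in range(j - 1, max(k + min_loop, j - 2 - max_bulge), -1):
                if k >= l or not ep.can_pair(seq[k], seq[l]):
                    continue
                left, right = k - i - 1, j - l - 1
                if left == 0 and right == 0:
                    cost = ep.stack_energy((seq[i], seq[j]), (seq[k], seq[l]))
                elif left == 0 or right == 0:
                    cost = ep.bulge_penalty(left + right)
                else:
                    cost = ep.internal_penalty(left + right)
                e_in, tr = best_inside(k, l)
                if cost + e_in < best:
                    best, trace = cost + e_in, ((k, l), tr)
        return best, trace

    best_e, best_pairs = 0.0, None
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if not ep.can_pair(seq[i], seq[j]):
                continue
            e_in, trace = best_inside(i, j)
            e = ep.terminal_penalty((seq[i], seq[j])) + e_in
            if e < best_e:
                pairs = [(i, j)]
                while trace:
                    pairs.append(trace[0])
                    trace = trace[1]
                best_e, best_pairs = e, pairs

    if best_pairs is None:
        return SecondaryStructure("." * n, 0.0)
    db = ["."] * n
    for i, j in best_pairs:
        db[i], db[j] = "(", ")"
    return SecondaryStructure("".join(db), best_e)


# ---------------------------------------------------------------------------
# external engine (ViennaRNA)


def _vienna_python(seq: str) -> tuple[str, float] | None:
    try:
        import RNA  # type: ignore
    except ImportError:
        return None
    db, mfe = RNA.fold(seq)
    return db, float(mfe)


def _vienna_subprocess(seq: str) -> tuple[str, float] | None:
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    out = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", text=True, capture_output=True, check=True
    ).stdout
    lines = [ln for ln in out.splitlines() if ln.strip()]
    m = re.match(r"([.()]+)\s+\(\s*(-?\d+\.?\d*)\s*\)", lines[-1])
    if not m:
        raise RuntimeError(f"could not parse RNAfold output: {out!r}")
    return m.group(1), float(m.group(2))


def fold_external(window: FoldingWindow | str) -> SecondaryStructure:
    """Fold with ViennaRNA (default parameters); verbatim dot-bracket + MFE."""
    seq = window.rna_sequence if isinstance(window, FoldingWindow) else window
    result = _vienna_python(seq) or _vienna_subprocess(seq)
    if result is None:
        raise RuntimeError(
            "no external folding engine found (ViennaRNA bindings or RNAfold "
            "executable); use fold_builtin instead"
        )
    db, mfe = result
    return SecondaryStructure(db, mfe)


def get_engine(name: str):
    """Resolve an engine name ('builtin' or 'external') to a fold callable."""
    if name == "builtin":
        return fold_builtin
    if name == "external":
        return fold_external
    raise ValueError(f"unknown folding engine {name!r}")


# ---------------------------------------------------------------------------
# energy bins and hairpin geometry


def assign_energy_bin(
    energy: float, thresholds: tuple[float, float, float] = (-1.0, -3.0, -6.0)
) -> EnergyBin:
    """Bin a ΔG; boundary values go to the more stable bin (−1 → Weak etc.)."""
    weak, stable, hyper = thresholds
    if energy <= hyper:
        return EnergyBin.HYPERSTABLE
    if energy <= stable:
        return EnergyBin.STABLE
    if energy <= weak:
        return EnergyBin.WEAK
    return EnergyBin.UNSTRUCTURED


def _pair_list(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            pairs.append((stack.pop(), idx))
    return sorted(pairs)


def hairpin_features(
    structure: SecondaryStructure, window: FoldingWindow
) -> HairpinFeatures:
    """Parse the stem/loop/distance geometry from a dot-bracket.

    For a multi-hairpin structure (possible from the external engine) the
    3′-most hairpin is measured and the result flagged.
    """
    pairs = _pair_list(structure.dot_bracket)
    if not pairs:
        return HairpinFeatures(0, None, None, None)

    # innermost pairs (enclosing no other pair) = hairpin loop closers
    innermost = [
        (i, j)
        for (i, j) in pairs
        if not any(i < k and l < j for (k, l) in pairs if (k, l) != (i, j))
    ]
    target = max(innermost, key=lambda p: p[1])  # 3'-most hairpin
    multi = len(innermost) > 1

    # walk outward: an enclosing pair joins the helix chain iff everything
    # strictly inside it already belongs to the chain (no branching)
    chain = [target]
    enclosing = sorted(
        (p for p in pairs if p[0] < target[0] and p[1] > target[1]),
        key=lambda p: -p[0],
    )
    for i, j in enclosing:
        inside = [p for p in pairs if i < p[0] and p[1] < j]
        if all(p in chain for p in inside):
            chain.append((i, j))
        else:
            break
    chain.sort()  # outermost first

    stem_bp = len(chain)
    inner_i, inner_j = chain[-1]
    loop_nt = inner_j - inner_i - 1
    bulge_nt = sum(
        (k - i - 1) + (j - l - 1) for (i, j), (k, l) in zip(chain, chain[1:])
    )
    # relative position of the 3'-most paired base (window is upstream: all
    # relative positions negative, no zero crossing)
    jmax = chain[0][1]
    rel_pos = window.rel_end - (len(window.rna_sequence) - 1 - jmax)
    distance = -rel_pos - 1
    return HairpinFeatures(stem_bp, loop_nt, bulge_nt, distance, multi)
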