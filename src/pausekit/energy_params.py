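"""Embedded nearest-neighbour free-energy parameters for the built-in folder.

Approximate Turner-2004 values at 37 °C, kcal/mol. The table covers
Watson–Crick and G·U wobble pairs: helix stacking increments, hairpin-loop
initiation penalties by loop size, bulge and internal-loop penalties by
total unpaired size, and a terminal-AU/GU helix-end penalty. Loop penalties
beyond the tabulated range are extrapolated with the Jacobson–Stockmayer
term 1.75·RT·ln(n/n_max).

These are deliberately a compact approximation: the built-in folder's
contract with external engines (ViennaRNA) is agreement at the level of the
four stability bins, not of exact ΔG.
"""

from __future__ import annotations

import math

RT37 = 0.6163  # kcal/mol at 310.15 K

#: allowed pairs, 5' base → 3' base
PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

#: stacking ΔG°37 for 5'-WX-3' / 3'-ZY-5', keyed by (outer pair, inner pair)
#: where a pair (p, q) has p on the 5' side of the top strand.
STACK: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "GC"): -2.2,
    ("AU", "CG"): -2.1, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "GC"): -2.4,
    ("UA", "CG"): -2.1, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "GC"): -3.3,
    ("CG", "CG"): -2.4, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "UA"): -2.2, ("GC", "GC"): -3.4,
    ("GC", "CG"): -3.3, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3, ("GU", "UA"): -1.4, ("GU", "GC"): -2.5,
    ("GU", "CG"): -2.1, ("GU", "GU"): -0.5, ("GU", "UG"): 1.3,
    ("UG", "AU"): -1.0, ("UG", "UA"): -0.6, ("UG", "GC"): -1.5,
    ("UG", "CG"): -1.4, ("UG", "GU"): 0.3, ("UG", "UG"): -0.5,
}

#: hairpin loop initiation by unpaired loop size (>=3)
HAIRPIN_LOOP = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4, 10: 6.5}

#: bulge loop penalty by bulge size
BULGE = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}

#: internal loop penalty by total unpaired size (both sides)
INTERNAL = {2: 1.5, 3: 2.0, 4: 2.5, 5: 3.0, 6: 3.3, 7: 3.6, 8: 3.9}

#: penalty for a helix terminated by an A·U or G·U pair (applied per helix end)
TERMINAL_AU = 0.5


def _extrapolate(table: dict[int, float], n: int) -> float:
    n_max = max(table)
    if n <= n_max:
        return table[n]
    return table[n_max] + 1.75 * RT37 * math.log(n / n_max)


def hairpin_penalty(loop_size: int) -> float:
    if loop_size < 3:
        raise ValueError("hairpin loop must enclose at least 3 nt")
    return _extrapolate(HAIRPIN_LOOP, loop_size)


def bulge_penalty(size: int) -> float:
    if size < 1:
        raise ValueError("bulge size must be >= 1")
    return _extrapolate(BULGE, size)


def internal_penalty(total_size: int) -> float:
    if total_size < 2:
        raise ValueError("internal loop total size must be >= 2")
    return _extrapolate(INTERNAL, total_size)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    return STACK[("".join(outer), "".join(inner))]


def terminal_penalty(pair: tuple[str, str]) -> float:
    return TERMINAL_AU if pair not in {("G", "C"), ("C", "G")} else 0.0
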