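"""Folding window, built-in hairpin folder (vs brute-force oracle), bins, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausekit import (
    EdgeSiteError,
    EnergyBin,
    FoldingWindow,
    Genome,
    PauseSite,
    SecondaryStructure,
    assign_energy_bin,
    extract_window,
    fold_builtin,
    fold_external,
    hairpin_features,
)
from pausekit import energy_params as ep
from pausekit.io_formats import revcomp

# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate every single-hairpin pair chain
# explicitly and score it with its own energy accumulation


def _oracle_score(seq, chain):
    pairs_e = ep.terminal_penalty((seq[chain[0][0]], seq[chain[0][1]]))
    for (i, j), (k, l) in zip(chain, chain[1:]):
        gl, gr = k - i - 1, j - l - 1
        if gl == gr == 0:
            pairs_e += ep.STACK[(seq[i] + seq[j], seq[k] + seq[l])]
        elif gl == 0 or gr == 0:
            pairs_e += ep.bulge_penalty(gl + gr)
        else:
            pairs_e += ep.internal_penalty(gl + gr)
    ki, kj = chain[-1]
    return (
        pairs_e
        + ep.hairpin_penalty(kj - ki - 1)
        + ep.terminal_penalty((seq[ki], seq[kj]))
    )


def oracle_mfe(seq, max_bulge=3, min_loop=3):
    """Minimum energy over the explicit list of all single-hairpin structures."""
    n = len(seq)
    best = 0.0

    def extend(chain):
        nonlocal best
        i, j = chain[-1]
        if j - i - 1 >= min_loop:
            best = min(best, _oracle_score(seq, chain))
        for k in range(i + 1, min(i + 2 + max_bulge, j)):
            for l in range(j - 1, max(j - 2 - max_bulge, k), -1):
                if l - k - 1 >= min_loop and (seq[k], seq[l]) in ep.PAIRS:
                    extend(chain + [(k, l)])

    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (seq[i], seq[j]) in ep.PAIRS:
                extend([(i, j)])
    return best


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestFoldBuiltin:
    def test_homopolymer_unfolded(self):
        s = fold_builtin("A" * 20)
        assert s.dot_bracket == "." * 20
        assert s.energy_kcal_mol == 0.0
        assert assign_energy_bin(0.0) is EnergyBin.UNSTRUCTURED

    def test_gc_hairpin_is_hyperstable(self):
        # 5 G·C pairs closing an 8-nt loop: four GC-on-GC stacks dominate
        s = fold_builtin("GGGGGAAAAAAAACCCCC")
        assert s.dot_bracket == "((((( ........ )))))".replace(" ", "")
        assert s.energy_kcal_mol < -6
        assert assign_energy_bin(s.energy_kcal_mol) is EnergyBin.HYPERSTABLE

    def test_matches_bruteforce_oracle(self, rng):
        """Exhaustive-oracle equivalence on 1000 random sequences of length <= 14."""
        for _ in range(1000):
            seq = random_rna(rng, int(rng.integers(5, 15)))
            assert fold_builtin(seq).energy_kcal_mol == pytest.approx(
                oracle_mfe(seq), abs=1e-9
            ), seq

    def test_energy_never_positive(self, rng):
        for _ in range(200):
            assert fold_builtin(random_rna(rng, 20)).energy_kcal_mol <= 0.0

    def test_appending_never_increases_mfe(self, rng):
        """A longer window folds over a superset of candidate structures."""
        for _ in range(50):
            seq = random_rna(rng, 16)
            e_short = fold_builtin(seq).energy_kcal_mol
            e_long = fold_builtin(seq + random_rna(rng, 4)).energy_kcal_mol
            assert e_long <= e_short + 1e-9

    def test_length_bound(self):
        with pytest.raises(ValueError, match="bounded"):
            fold_builtin("A" * 41)


class TestExtractWindow:
    def test_plus_strand_poly_a(self, toy_genome):
        w = extract_window(toy_genome, PauseSite("chr", 45, "+", "p"))
        assert w.rna_sequence == "A" * 20
        assert (w.rel_start, w.rel_end) == (-30, -11)

    def test_window_coordinates(self):
        # site at 40 on +: window covers genomic 11..30 (1-based)
        seq = "A" * 10 + "CGCGCGCGCGTATATATATA" + "A" * 20
        g = Genome({"chr": seq})
        w = extract_window(g, PauseSite("chr", 40, "+", "p"))
        assert w.rna_sequence == "CGCGCGCGCGUAUAUAUAUA"

    def test_minus_strand_mirrors_revcomp(self, random_genome):
        """Folding a − site equals folding the mirrored + site on the revcomp genome."""
        n = random_genome.length("chr")
        mirrored = Genome({"chr": revcomp(random_genome["chr"])}, id="mir")
        for pos in (500, 1234, 9999):
            w_minus = extract_window(random_genome, PauseSite("chr", pos, "-", "m"))
            w_plus = extract_window(mirrored, PauseSite("chr", n - pos + 1, "+", "p"))
            assert w_minus.rna_sequence == w_plus.rna_sequence
            assert (
                fold_builtin(w_minus).energy_kcal_mol
                == fold_builtin(w_plus).energy_kcal_mol
            )

    def test_edge_site_flagged(self, toy_genome):
        with pytest.raises(EdgeSiteError):
            extract_window(toy_genome, PauseSite("chr", 20, "+", "p"))


class TestEnergyBins:
    @pytest.mark.parametrize(
        "energy,expected",
        [
            (0.0, EnergyBin.UNSTRUCTURED),
            (-0.99, EnergyBin.UNSTRUCTURED),
            (-1.0, EnergyBin.WEAK),  # boundary goes to the more stable bin
            (-2.9, EnergyBin.WEAK),
            (-3.0, EnergyBin.STABLE),
            (-5.1, EnergyBin.STABLE),  # hisL-like stability
            (-6.0, EnergyBin.HYPERSTABLE),
            (-7.8, EnergyBin.HYPERSTABLE),
            (1.5, EnergyBin.UNSTRUCTURED),
        ],
    )
    def test_partition(self, energy, expected):
        assert assign_energy_bin(energy) is expected

    @given(st.floats(min_value=-50, max_value=10, allow_nan=False))
    @settings(derandomize=True, max_examples=100)
    def test_total_function(self, energy):
        assert assign_energy_bin(energy) in EnergyBin


class TestHairpinFeatures:
    def _window(self, db_len=20):
        return FoldingWindow("A" * db_len, -30, -11)

    def test_hisl_archetype_geometry(self):
        # 5-bp stem, 8-nt loop, 3'-most pair on the last window base (−11)
        db = ".." + "(((((........)))))"
        f = hairpin_features(SecondaryStructure(db, -5.0), self._window())
        assert (f.stem_bp, f.loop_nt, f.bulge_nt, f.distance_to_pause_nt) == (5, 8, 0, 10)

    def test_unfolded(self):
        f = hairpin_features(SecondaryStructure("." * 20, 0.0), self._window())
        assert f.stem_bp == 0
        assert f.loop_nt is None and f.distance_to_pause_nt is None

    def test_bulged_stem_hand_annotation(self):
        # hand-parsed: pairs (2,19),(3,18),(5,17),(6,16),(7,15),(8,14);
        # one 1-nt bulge on the 5' side; loop = 14-8-1 = 5; ends at −11
        db = "..((.((((.....))))))"
        f = hairpin_features(SecondaryStructure(db, -3.0), self._window())
        assert (f.stem_bp, f.loop_nt, f.bulge_nt, f.distance_to_pause_nt) == (6, 5, 1, 10)

    def test_offset_stem_distance(self):
        # 3'-most paired base two in from the end: rel −13 → distance 12
        db = "(((((........))))).."
        f = hairpin_features(SecondaryStructure(db, -5.0), self._window())
        assert f.distance_to_pause_nt == 12

    def test_multi_hairpin_takes_three_prime_and_flags(self):
        db = "((...))..((((....))))".ljust(21, ".")[:21]
        w = FoldingWindow("A" * 21, -31, -11)
        f = hairpin_features(SecondaryStructure(db[:21], -2.0), w)
        assert f.multi_hairpin
        assert f.stem_bp == 4
        assert f.loop_nt == 4


class TestExternalEngine:
    def test_homopolymer(self):
        s = fold_external("AAAAAAAAAAAAAAAAAAAA")
        assert s.dot_bracket == "." * 20
        assert s.energy_kcal_mol == 0.0

    def test_bin_agreement_on_planted_strong_hairpins(self, rng):
        """Engines agree at bin level (not exact ΔG) for clearly stable stems."""
        for _ in range(10):
            loop = "".join(rng.choice(list("AC"), size=8))
            seq = "GCGCGC" + loop + "GCGCGC"
            b = assign_energy_bin(fold_builtin(seq).energy_kcal_mol)
            e = assign_energy_bin(fold_external(seq).energy_kcal_mol)
            assert b is e is EnergyBin.HYPERSTABLE


def test_dot_bracket_validation():
    with pytest.raises(ValueError):
        SecondaryStructure("(((..", -1.0)
    with pytest.raises(ValueError):
        SecondaryStructure("))((", -1.0)
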