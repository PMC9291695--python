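"""Liftover by unique 50-nt window matching; tolerant Venn overlaps."""

import pytest

from pausekit import Genome, PauseSite, generate_genome, liftover_sites, overlap_sets
from pausekit.dataset_compare import PauseSet
from pausekit.io_formats import revcomp
from pausekit.structure import genomic_window


def sites_at(positions, strand="+", prefix="s"):
    return [PauseSite("chr", p, strand, f"{prefix}{i}") for i, p in enumerate(positions)]


class TestLiftover:
    def test_identity_mapping(self, random_genome):
        sites = sites_at([500, 1000, 15000]) + sites_at([700], strand="-", prefix="m")
        report = liftover_sites(sites, random_genome, random_genome)
        mapped = {s.site_id: s for s in report.mapped}
        for s in sites:
            assert mapped[s.site_id].position == s.position
            assert mapped[s.site_id].strand == s.strand
        assert not report.unmapped

    def test_planted_shifted_copy(self, random_genome):
        """A source window planted elsewhere in the target maps to the new locus."""
        site = PauseSite("chr", 5000, "+", "p0")
        window = genomic_window(random_genome, site, -49, 1)
        target_seq = generate_genome(20000, 0.5, seed=99)["chr"]
        insert_at = 12000  # 0-based
        target = Genome(
            {"chr": target_seq[:insert_at] + window + target_seq[insert_at + 50 :]},
            id="target",
        )
        report = liftover_sites([site], random_genome, target)
        assert len(report.mapped) == 1
        # −1 base sits one before the last window base: 1-based 12000 + 49
        assert report.mapped[0].position == insert_at + 49
        assert report.mapped[0].strand == "+"

    def test_planted_on_opposite_strand(self, random_genome):
        site = PauseSite("chr", 5000, "+", "p0")
        window = genomic_window(random_genome, site, -49, 1)
        target_seq = generate_genome(20000, 0.5, seed=98)["chr"]
        target = Genome(
            {"chr": target_seq[:8000] + revcomp(window) + target_seq[8050:]}, id="t"
        )
        report = liftover_sites([site], random_genome, target)
        assert len(report.mapped) == 1
        assert report.mapped[0].strand == "-"
        # minus-strand −1 base: offset o=8000 → 1-based o+2
        assert report.mapped[0].position == 8002

    def test_duplicate_window_ambiguous(self, random_genome):
        site = PauseSite("chr", 5000, "+", "p0")
        window = genomic_window(random_genome, site, -49, 1)
        target = Genome({"chr": "A" * 200 + window + "C" * 100 + window + "A" * 200})
        report = liftover_sites([site], random_genome, target)
        assert report.unmapped == [(site, "ambiguous")]

    def test_absent_window_unmapped(self, random_genome):
        site = PauseSite("chr", 5000, "+", "p0")
        target = Genome({"chr": "A" * 500})
        report = liftover_sites([site], random_genome, target)
        assert report.unmapped[0][1] == "not_found"

    def test_edge_site_reported(self, random_genome):
        report = liftover_sites(
            [PauseSite("chr", 10, "+", "e")], random_genome, random_genome
        )
        assert report.unmapped[0][1] == "edge"


def make_sets(*position_lists, tolerance_names=("A", "B", "C")):
    return [
        PauseSet(name, "g", sites_at(positions, prefix=name))
        for name, positions in zip(tolerance_names, position_lists)
    ]


class TestOverlap:
    def test_three_identical_sets(self):
        sets = make_sets([100, 200, 300], [100, 200, 300], [100, 200, 300])
        res = overlap_sets(sets, tolerance_nt=0)
        assert res.count("A", "B", "C") == 3
        assert res.union_size == 3

    def test_tolerance_boundary(self):
        a, b = make_sets([100], [103])[:2]
        assert overlap_sets([a, b], tolerance_nt=2).count("A", "B") == 0
        assert overlap_sets([a, b], tolerance_nt=3).count("A", "B") == 1

    def test_strand_and_sequence_must_match(self):
        a = PauseSet("A", "g", sites_at([100], strand="+"))
        b = PauseSet("B", "g", sites_at([100], strand="-", prefix="b"))
        res = overlap_sets([a, b], tolerance_nt=4)
        assert res.count("A", "B") == 0

    def test_planted_venn_design(self):
        """Counts equal the planted three-set Venn structure."""
        # shared by all three: 1000, 2000; A∩B only: 3000; B∩C only: 4000, 4100;
        # A∩C only: 5000; unique: A 6000,6100; B 7000; C 8000,8100,8200
        a = sites_at([1000, 2000, 3000, 5000, 6000, 6100], prefix="a")
        b = sites_at([1000, 2000, 3000, 4000, 4100, 7000], prefix="b")
        c = sites_at([1000, 2000, 4000, 4100, 5000, 8000, 8100, 8200], prefix="c")
        res = overlap_sets(
            [PauseSet("A", "g", a), PauseSet("B", "g", b), PauseSet("C", "g", c)], 0
        )
        assert res.count("A", "B", "C") == 2
        assert res.count("A", "B") == 1
        assert res.count("B", "C") == 2
        assert res.count("A", "C") == 1
        assert res.count("A") == 2
        assert res.count("B") == 1
        assert res.count("C") == 3
        assert res.union_size == 12

    def test_tolerance_zero_equals_exact_intersection(self, rng):
        pa = sorted(rng.choice(10000, size=60, replace=False) + 100)
        pb = sorted(rng.choice(10000, size=60, replace=False) + 100)
        sets = make_sets(list(pa), list(pb))[:2]
        res = overlap_sets(sets, tolerance_nt=0)
        assert res.count("A", "B") == len(set(pa) & set(pb))

    def test_permutation_invariance(self, rng):
        lists = [sorted(rng.choice(5000, size=40, replace=False) + 50) for _ in range(3)]
        sets = make_sets(*[list(p) for p in lists])
        base = overlap_sets(sets, tolerance_nt=2).region_counts
        perm = overlap_sets(sets[::-1], tolerance_nt=2).region_counts
        assert base == perm

    def test_tolerance_monotonicity(self, rng):
        lists = [sorted(rng.choice(3000, size=50, replace=False) + 50) for _ in range(2)]
        sets = make_sets(*[list(p) for p in lists])[:2]
        prev = -1
        for tol in range(5):
            shared = overlap_sets(sets, tolerance_nt=tol).count("A", "B")
            assert shared >= prev
            prev = shared

    def test_mixed_genomes_rejected(self):
        a = PauseSet("A", "g1", sites_at([100]))
        b = PauseSet("B", "g2", sites_at([100], prefix="b"))
        with pytest.raises(ValueError, match="liftover"):
            overlap_sets([a, b])

    def test_duplicate_site_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PauseSet("A", "g", [PauseSite("chr", 1, "+", "x"), PauseSite("chr", 2, "+", "x")])
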