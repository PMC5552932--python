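"""SSU recruitment: mapping acceptance rules, confirmation, composition."""

import numpy as np
import pytest

from ncyc import MappingConfig, ReferenceRecord, SequenceRead, SsuAssignment
from ncyc.ssu_profiler import (SsuDatabase, confirm_by_search, map_read,
                               summarize_composition)
from ncyc.translated_search import reverse_complement


def _ref(ref_id, seq, lineage=("Bacteria", "Proteobacteria")):
    return ReferenceRecord(ref_id, seq, "SSU", lineage, len(seq))


@pytest.fixture(scope="module")
def ssu_db():
    rng = np.random.default_rng(21)
    seqs = ["".join(rng.choice(list("ACGT"), 900)) for _ in range(3)]
    refs = [
        _ref("ssu_a", seqs[0], ("Bacteria", "Proteobacteria")),
        _ref("ssu_b", seqs[1], ("Bacteria", "Planctomycetes")),
        _ref("ssu_c", seqs[2], ("Archaea", "Thaumarchaeota")),
    ]
    return SsuDatabase(refs)


class TestMapRead:
    def test_exact_substring_accepted_with_full_identity(self, ssu_db):
        frag = ssu_db.records[0].seq[100:250]
        m = map_read(SequenceRead("r", frag), ssu_db)
        assert m is not None
        assert m.ref_id == ssu_db.records[0].ref_id
        assert m.identity_fraction == 1.0
        assert m.aligned_read_fraction == 1.0

    def test_reverse_complement_fragment_accepted(self, ssu_db):
        frag = reverse_complement(ssu_db.records[1].seq[200:400])
        m = map_read(SequenceRead("r", frag), ssu_db)
        assert m is not None
        assert m.ref_id == ssu_db.records[1].ref_id
        assert m.strand == -1

    def test_short_aligned_region_rejected_by_length_fraction(self, ssu_db):
        # 90 matching nt in a 200-nt read: aligned fraction 0.45 < 0.5
        rng = np.random.default_rng(1)
        frag = ssu_db.records[0].seq[100:190]
        read = frag + "".join(rng.choice(list("ACGT"), 110))
        assert map_read(SequenceRead("r", read), ssu_db,
                        exhaustive=True) is None

    def test_low_identity_rejected_by_similarity_fraction(self, ssu_db):
        # mutate 25% of bases: identity ~0.75 < 0.8
        rng = np.random.default_rng(2)
        frag = list(ssu_db.records[0].seq[100:300])
        for i in rng.choice(len(frag), size=len(frag) // 4, replace=False):
            frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
        assert map_read(SequenceRead("r", "".join(frag)), ssu_db,
                        exhaustive=True) is None

    def test_thresholds_are_monotone(self, ssu_db):
        # a read acceptable at (0.5, 0.8) stays acceptable at lower thresholds
        rng = np.random.default_rng(3)
        frag = list(ssu_db.records[0].seq[100:300])
        for i in rng.choice(len(frag), size=20, replace=False):
            frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
        read = SequenceRead("r", "".join(frag))
        strict = map_read(read, ssu_db)
        relaxed = map_read(read, ssu_db, MappingConfig(
            length_fraction=0.3, similarity_fraction=0.6))
        assert strict is not None and relaxed is not None
        assert relaxed.score >= strict.score

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            SsuDatabase([])


class TestConfirmBySearch:
    def test_exact_fragment_confirmed_with_tiny_evalue(self, ssu_db):
        frag = ssu_db.records[0].seq[100:250]
        hits = confirm_by_search([SequenceRead("r", frag)], ssu_db)
        best = hits["r"][0]
        assert best.subject_id == ssu_db.records[0].ref_id
        assert best.evalue < 1e-6
        assert best.identity_fraction == 1.0

    def test_random_read_dropped(self, ssu_db):
        rng = np.random.default_rng(4)
        read = SequenceRead("r", "".join(rng.choice(list("ACGT"), 200)))
        assert confirm_by_search([read], ssu_db, exhaustive=True) == {}

    def test_karlin_altschul_magnitude_for_perfect_match(self, ssu_db):
        # 150 exact matches: S = 300; S' = (0.625*300 - ln 0.41)/ln 2
        frag = ssu_db.records[0].seq[100:250]
        hit = confirm_by_search([SequenceRead("r", frag)], ssu_db)["r"][0]
        expected_bit = (0.625 * 300 - np.log(0.41)) / np.log(2)
        assert hit.bit_score == pytest.approx(expected_bit, abs=1e-9)
        m, n = 150, ssu_db.total_nt
        assert hit.evalue == pytest.approx(m * n * 2 ** (-expected_bit),
                                           rel=1e-9)


def _assign(lineage, n):
    return [SsuAssignment(f"r{lineage[-1]}{i}", "x", tuple(lineage), 1.0, 1.0)
            for i in range(n)]


class TestSummarizeComposition:
    def test_domain_proportions(self):
        assignments = _assign(("Bacteria", "Proteobacteria"), 80) + \
            _assign(("Archaea", "Thaumarchaeota"), 20)
        df = summarize_composition(assignments, "domain")
        props = dict(zip(df.taxon, df.proportion))
        assert props == {"Archaea": 0.2, "Bacteria": 0.8}

    def test_groups_below_floor_fold_into_other(self):
        assignments = _assign(("Bacteria", "Proteobacteria"), 99) + \
            _assign(("Bacteria", "Nitrospirae"), 1)
        df = summarize_composition(assignments, "phylum",
                                   reporting_floor=0.02)
        assert set(df.taxon) == {"Proteobacteria", "other"}
        assert df.set_index("taxon").proportion["other"] == 0.01

    def test_scoped_normalization(self):
        assignments = (
            _assign(("Bacteria", "Proteobacteria", "Methylococcales"), 50) +
            _assign(("Bacteria", "Proteobacteria", "Desulfobacterales"), 30) +
            _assign(("Bacteria", "Proteobacteria", "Campylobacterales"), 20) +
            _assign(("Archaea", "Euryarchaeota", "Thermoplasmatales"), 40)
        )
        df = summarize_composition(assignments, "order",
                                   scope=("Bacteria", "Proteobacteria"))
        props = dict(zip(df.taxon, df.proportion))
        assert props == {"Campylobacterales": 0.2,
                         "Desulfobacterales": 0.3,
                         "Methylococcales": 0.5}
        assert df.proportion.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicating_every_read_leaves_proportions_unchanged(self):
        assignments = _assign(("Bacteria", "Proteobacteria"), 3) + \
            _assign(("Archaea", "Euryarchaeota"), 7)
        df1 = summarize_composition(assignments, "domain")
        doubled = assignments + [
            SsuAssignment(a.read_id + "_dup", a.ref_id, a.lineage, 1.0, 1.0)
            for a in assignments
        ]
        df2 = summarize_composition(doubled, "domain")
        assert list(df1.proportion) == list(df2.proportion)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="unknown rank"):
            summarize_composition(_assign(("Bacteria",), 1), "kingdom")
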