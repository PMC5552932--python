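"""Synthetic community generator: determinism, quotas, noiseless limits."""

import numpy as np
import pytest

from ncyc import CommunitySpec, ErrorModel, MARKER_FAMILIES
from ncyc.io_formats import write_fastq
from ncyc.synthetic_community import (default_zone_specs,
                                      make_reference_sets, simulate_reads)
from ncyc.translated_search import reverse_complement


def spec_for(n_reads, amoa=0.02, ssu=0.1, decoy=0.05, error=None, **kw):
    return CommunitySpec(
        sample_id="S", n_reads=n_reads,
        family_fractions={"amoA": amoa},
        ssu_fraction=ssu,
        ssu_taxon_weights={"Nitrosopumilus": 0.5, "Methylococcus": 0.5},
        decoy_fraction=decoy,
        background_fraction=1.0 - amoa - ssu - decoy,
        error_model=error or ErrorModel(),
        **kw,
    )


class TestMakeReferenceSets:
    def test_families_named_for_the_13_marker_genes(self):
        refs = make_reference_sets(seed=1, n_families=13)
        assert refs.curated_families() == set(MARKER_FAMILIES)
        assert len(MARKER_FAMILIES) == 13

    def test_background_is_strict_superset_of_curated(self, small_refs):
        bg = {(r.ref_id, r.seq) for r in small_refs.background}
        assert {(r.ref_id, r.seq) for r in small_refs.curated} <= bg
        assert len(small_refs.background) > len(small_refs.curated)

    def test_same_seed_gives_identical_references(self):
        a = make_reference_sets(seed=9, n_taxa_per_family=2)
        b = make_reference_sets(seed=9, n_taxa_per_family=2)
        assert [(r.ref_id, r.seq) for r in a.curated] == \
            [(r.ref_id, r.seq) for r in b.curated]
        assert a.gene_nt == b.gene_nt
        assert [(r.ref_id, r.seq) for r in a.ssu] == \
            [(r.ref_id, r.seq) for r in b.ssu]

    def test_zero_divergence_decoys_identical_to_their_source(self):
        refs = make_reference_sets(seed=2, n_taxa_per_family=2,
                                   divergence=0.0)
        by_id = {r.ref_id: r for r in refs.background}
        for decoy_id in refs.decoy_ids:
            fam = decoy_id.removeprefix("decoy_")
            first_member = next(r for r in refs.curated
                                if r.gene_family == fam)
            assert by_id[decoy_id].seq == first_member.seq

    def test_ssu_references_span_three_domains(self, small_refs):
        domains = {r.lineage[0] for r in small_refs.ssu}
        assert domains == {"Bacteria", "Archaea", "Eukaryota"}

    def test_out_of_range_divergence_rejected(self):
        with pytest.raises(ValueError, match="divergence"):
            make_reference_sets(seed=1, divergence=0.95)


class TestSimulateReads:
    def test_read_count_and_truth_rows_conserved(self, small_refs):
        reads, truth = simulate_reads(spec_for(1000), small_refs, seed=5)
        assert len(reads) == 1000
        assert len(truth) == 1000
        assert set(truth.read_id) == {r.read_id for r in reads}

    def test_quota_rounding_gives_exact_planted_counts(self, small_refs):
        reads, truth = simulate_reads(spec_for(10_000, amoa=0.02),
                                      small_refs, seed=5)
        assert (truth.gene_family == "amoA").sum() == 200
        assert (truth.category == "SSU").sum() == 1000
        assert (truth.category == "decoy").sum() == 500

    def test_multinomial_counts_near_but_not_exactly_quota(self, small_refs):
        reads, truth = simulate_reads(spec_for(10_000, amoa=0.02),
                                      small_refs, seed=5, multinomial=True)
        n_amoa = (truth.gene_family == "amoA").sum()
        assert 140 <= n_amoa <= 260  # ~5 sigma around 200

    def test_deterministic_fastq_bytes(self, small_refs, tmp_path):
        spec = spec_for(400)
        for name in ("a", "b"):
            reads, _ = simulate_reads(spec, small_refs, seed=17)
            write_fastq(reads, tmp_path / f"{name}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == \
            (tmp_path / "b.fastq").read_bytes()

    def test_noiseless_reads_are_exact_substrings(self, small_refs,
                                                  zero_error):
        reads, truth = simulate_reads(spec_for(300, error=zero_error),
                                      small_refs, seed=6)
        truth = truth.set_index("read_id")
        checked = 0
        for read in reads:
            row = truth.loc[read.read_id]
            if row.category == "background":
                continue
            source = row.source_ref
            template = small_refs.gene_nt.get(source)
            if template is None:  # SSU source
                template = next(r.seq for r in small_refs.ssu
                                if r.ref_id == source)
            assert read.seq in template or \
                reverse_complement(read.seq) in template
            checked += 1
        assert checked == 51  # the planted 17% of 300 reads

    def test_error_model_introduces_differences(self, small_refs):
        noisy = ErrorModel(substitution_rate=0.05, indel_rate=0.02)
        reads, truth = simulate_reads(spec_for(200, error=noisy),
                                      small_refs, seed=6)
        truth = truth.set_index("read_id")
        diffs = 0
        for read in reads:
            row = truth.loc[read.read_id]
            if row.category == "background":
                continue
            source = row.source_ref
            template = small_refs.gene_nt.get(source) or next(
                r.seq for r in small_refs.ssu if r.ref_id == source)
            if read.seq not in template and \
                    reverse_complement(read.seq) not in template:
                diffs += 1
        assert diffs > 20

    def test_absent_family_rejected(self, small_refs):
        spec = CommunitySpec(
            sample_id="S", n_reads=10,
            family_fractions={"narG": 0.5},
            background_fraction=0.5,
        )
        bad_refs = make_reference_sets(seed=1, n_families=1)  # narG only
        ok, _ = simulate_reads(spec, bad_refs, seed=1)
        assert len(ok) == 10
        spec2 = CommunitySpec(
            sample_id="S", n_reads=10,
            family_fractions={"amoA": 0.5},
            background_fraction=0.5,
        )
        with pytest.raises(ValueError, match="absent"):
            simulate_reads(spec2, bad_refs, seed=1)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CommunitySpec(sample_id="S", n_reads=10,
                          family_fractions={"amoA": 0.5},
                          background_fraction=0.6)


class TestDefaultZoneSpecs:
    def test_three_zones_with_valid_fractions(self):
        specs = default_zone_specs(4000)
        assert set(specs) == {"OAZ", "SMTZ", "MZ"}
        for spec in specs.values():
            total = sum(spec.family_fractions.values()) + \
                spec.ssu_fraction + spec.decoy_fraction + \
                spec.background_fraction
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_depth_trends_follow_the_observed_gradient(self):
        specs = default_zone_specs(4000)
        # nitrate reduction and ammonia oxidation genes decline with depth
        for fam in ("narG", "amoA", "nosZ"):
            assert specs["OAZ"].family_fractions[fam] > \
                specs["MZ"].family_fractions.get(fam, 0.0)
        # anammox hydrazine synthase peaks in the SMTZ and is absent in MZ
        assert specs["SMTZ"].family_fractions["hzsA"] > \
            specs["OAZ"].family_fractions["hzsA"]
        assert "hzsA" not in specs["MZ"].family_fractions
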