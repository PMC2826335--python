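"""Taxon-specific alleles, polyploid-origin markers and duplicated loci."""

import numpy as np
import pytest

from ssrwild import (
    Allele,
    ValidationError,
    classify_donor_amplification,
    duplicated_locus_markers,
    polyploid_origin_markers,
    section_specific_markers,
    specific_alleles,
)

from conftest import build_matrix


@pytest.fixture
def geno_matrix(tiny_taxonomy):
    # order: AH1 AH2 DUR1 IPA1 PIN1 PIN2 PUS1
    geno = {
        "AH1": {"M1": {320, 300, 900}, "C1": {150}},
        "AH2": {"M1": {320, 300}, "C1": {150}},
        "DUR1": {"M1": {320, 325}, "M2": {210}, "C1": {150}},
        "IPA1": {"M1": {300}, "M2": {210}, "C1": {150}},
        "PIN1": {"M2": {200}, "C1": {580}},
        "PIN2": {"M2": {200, 205}, "C1": {580}},
        "PUS1": {"C1": {150, 160}},
    }
    return build_matrix(geno, tiny_taxonomy.ids())


class TestSpecificAlleles:
    def test_species_specific_implies_section_specific(self, tiny_taxonomy,
                                                       geno_matrix):
        species = specific_alleles(geno_matrix, tiny_taxonomy, "species")
        section = specific_alleles(geno_matrix, tiny_taxonomy, "section")
        # (M2, 200) carried by both A. pintoi accessions only
        assert Allele("M2", 200) in species.alleles_of("A. pintoi")
        assert Allele("M2", 200) in section.alleles_of("Caulorrhizae")
        # every species-specific allele is section-specific for its section
        per_section = section.as_mapping()
        for taxon in species.summary.taxon:
            sec = tiny_taxonomy.section_of_species(taxon)
            assert species.alleles_of(taxon) <= per_section.get(sec, set())

    def test_cross_species_allele_is_section_specific_only(self, tiny_taxonomy,
                                                           geno_matrix):
        # (M2, 210) carried by A. duranensis and A. ipaensis (both Arachis)
        species = specific_alleles(geno_matrix, tiny_taxonomy, "species")
        section = specific_alleles(geno_matrix, tiny_taxonomy, "section")
        all_species_specific = set()
        for t in species.summary.taxon:
            all_species_specific |= species.alleles_of(t)
        assert Allele("M2", 210) not in all_species_specific
        assert Allele("M2", 210) in section.alleles_of("Arachis")

    def test_summary_counts_sum_to_total_and_pcts_half_up(self, tiny_taxonomy,
                                                          geno_matrix):
        report = specific_alleles(geno_matrix, tiny_taxonomy, "species")
        assert report.summary.n_specific.sum() == report.total
        for _, r in report.summary.iterrows():
            want = int(np.floor(100 * r.n_specific / report.total + 0.5))
            assert r.pct == want
        # sorted by descending count
        counts = list(report.summary.n_specific)
        assert counts == sorted(counts, reverse=True)

    def test_exclusion_restores_donor_specificity(self, tiny_taxonomy,
                                                  geno_matrix):
        # (M1, 320) is shared by DUR1 and the tetraploids; once tetraploids
        # are excluded it becomes specific to A. duranensis
        with_tets = specific_alleles(geno_matrix, tiny_taxonomy, "species")
        assert Allele("M1", 320) not in with_tets.alleles_of("A. duranensis")
        without = specific_alleles(
            geno_matrix, tiny_taxonomy, "species",
            exclude_accessions=("AH1", "AH2"),
        )
        assert Allele("M1", 320) in without.alleles_of("A. duranensis")

    def test_recovers_planted_private_alleles_exactly(self, default_dataset):
        from dataclasses import replace
        from ssrwild import SimulationConfig, simulate

        cfg, *_ = default_dataset
        cfg2 = replace(cfg, p_tetraploid_locus=0.0, seed=77)
        taxonomy, _, mat, _, truth = simulate(cfg2)
        tets = tuple(a.accession_id for a in taxonomy.tetraploids())
        report = specific_alleles(mat, taxonomy, "species",
                                  exclude_accessions=tets)
        detected = set()
        for t in report.summary.taxon:
            detected |= report.alleles_of(t)
        assert detected == truth.all_private()


class TestSectionSpecificMarkers:
    def test_confined_marker_detected(self, tiny_taxonomy, geno_matrix):
        amp = geno_matrix.to_amplification()
        # M1 amplifies only section-Arachis accessions
        assert section_specific_markers(amp, tiny_taxonomy) == ["M1"]

    def test_single_section_input_rejected(self, geno_matrix):
        from ssrwild import Accession, Taxonomy

        tax = Taxonomy(
            [Accession(a, "sp", "Arachis", "A", 20)
             for a in geno_matrix.accessions]
        )
        with pytest.raises(ValidationError, match=">= 2"):
            section_specific_markers(geno_matrix.to_amplification(), tax)


class TestPolyploidOrigin:
    def test_tetraploid_only_marker_detected(self, tiny_taxonomy):
        geno = {
            "AH1": {"M1": {500}, "M2": {200}},
            "AH2": {"M1": {500}},
            "DUR1": {"M2": {200}},
            "IPA1": {"M2": {210}},
            "PIN1": {"M2": {220}},
            "PIN2": {"M2": {220}},
            "PUS1": {"M2": {230}},
        }
        mat = build_matrix(geno, tiny_taxonomy.ids())
        amp = mat.to_amplification()
        assert polyploid_origin_markers(amp, tiny_taxonomy) == ["M1"]

    def test_marker_with_any_diploid_amplification_excluded(self,
                                                            tiny_taxonomy,
                                                            geno_matrix):
        amp = geno_matrix.to_amplification()
        assert polyploid_origin_markers(amp, tiny_taxonomy) == []

    def test_requires_tetraploids(self, geno_matrix):
        from ssrwild import Accession, Taxonomy

        tax = Taxonomy(
            [Accession(a, f"sp{i % 2}",
                       "Arachis" if i % 2 else "Caulorrhizae",
                       "A" if i % 2 else "unassigned", 20)
             for i, a in enumerate(geno_matrix.accessions)]
        )
        with pytest.raises(ValidationError, match="tetraploid"):
            polyploid_origin_markers(geno_matrix.to_amplification(), tax)


class TestDuplicatedLoci:
    def test_donor_plus_unique_fragment_signature(self, tiny_taxonomy,
                                                  geno_matrix):
        # AH1 at M1 carries 320 (from DUR1), 300 (from IPA1) and the 900 bp
        # fragment absent from every diploid
        got = duplicated_locus_markers(geno_matrix, tiny_taxonomy,
                                       "DUR1", "IPA1")
        assert got == [("M1", {Allele("M1", 900)})]

    def test_pure_donor_union_not_reported(self, tiny_taxonomy):
        geno = {
            "AH1": {"M1": {320, 300}},
            "AH2": {"M1": {320}},
            "DUR1": {"M1": {320}},
            "IPA1": {"M1": {300}},
            "PIN1": {"M1": {111}},
            "PIN2": {"M1": {111}},
            "PUS1": {"M1": {112}},
        }
        mat = build_matrix(geno, tiny_taxonomy.ids())
        assert duplicated_locus_markers(mat, tiny_taxonomy, "DUR1", "IPA1") == []

    def test_unknown_or_tetraploid_donor_rejected(self, tiny_taxonomy,
                                                  geno_matrix):
        with pytest.raises(ValidationError, match="NOPE"):
            duplicated_locus_markers(geno_matrix, tiny_taxonomy, "NOPE", "IPA1")
        with pytest.raises(ValidationError, match="not diploid"):
            duplicated_locus_markers(geno_matrix, tiny_taxonomy, "AH1", "IPA1")

    def test_simulated_duplicated_markers_recovered_exactly(self,
                                                            default_dataset):
        _, taxonomy, _, mat, _, truth = default_dataset
        got = duplicated_locus_markers(mat, taxonomy, truth.donor_A,
                                       truth.donor_B)
        assert {m for m, _ in got} == truth.duplicated_locus_markers
        extras = set()
        for _, e in got:
            extras |= e
        assert extras == truth.tetraploid_only_alleles


class TestDonorClassification:
    def test_three_classes(self, tiny_taxonomy, geno_matrix):
        amp = geno_matrix.to_amplification()
        got = classify_donor_amplification(
            amp, geno_matrix, "DUR1", "IPA1", ["AH1", "AH2"]
        )
        assert got["M1"] == "both_donors"  # 320 from A, 300 from B in AH1
        assert got["C1"] == "both_donors"
        assert got["M2"] == "neither"  # 210 never reaches a tetraploid

    def test_a_only_class(self, tiny_taxonomy):
        geno = {
            "AH1": {"M1": {210}},
            "AH2": {"M1": {210}},
            "DUR1": {"M1": {210}},
            "IPA1": {"M2": {300}},
            "PIN1": {"M2": {301}},
            "PIN2": {"M2": {301}},
            "PUS1": {"M2": {302}},
        }
        mat = build_matrix(geno, tiny_taxonomy.ids())
        got = classify_donor_amplification(
            mat.to_amplification(), mat, "DUR1", "IPA1", ["AH1", "AH2"]
        )
        assert got["M1"] == "A_only"

    def test_majority_class_under_full_retention(self):
        from dataclasses import replace
        from ssrwild import SimulationConfig, simulate

        cfg = SimulationConfig(seed=9, donor_retention=1.0,
                               p_tetraploid_locus=0.0)
        taxonomy, panel, mat, amp, truth = simulate(cfg)
        tets = [a.accession_id for a in taxonomy.tetraploids()]
        got = classify_donor_amplification(
            amp, mat, truth.donor_A, truth.donor_B, tets
        )
        from collections import Counter
        counts = Counter(got.values())
        assert counts.most_common(1)[0][0] == "both_donors"
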