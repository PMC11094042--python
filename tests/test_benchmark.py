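"""Join, subset, confidence filter, frequencies, and full benchmark rows."""

import pytest

from missbench.benchmark import (
    benchmark_protein_set,
    filter_by_confidence,
    join_scores_labels,
    mutation_frequencies,
    subset_residues,
    write_report_tsv,
)
from missbench.io import (
    ClinicalLabel,
    ClinicalVariant,
    ProteinMeta,
    ProteinSet,
    RegionAnnotation,
    ResidueConfidence,
    ScoreRecord,
)

B, P = ClinicalLabel.BENIGN, ClinicalLabel.PATHOGENIC


class TestJoin:
    def test_simple_match(self):
        joined, report = join_scores_labels(
            [ScoreRecord("P1", 10, "F", "C", 0.9)],
            [ClinicalVariant("P1", 10, "F", "C", P, 1)],
        )
        assert len(joined) == 1
        assert joined[0].score == 0.9 and joined[0].label is P
        assert report.n_unmatched_clinical == 0

    def test_ref_mismatch_rejected_and_counted(self):
        joined, report = join_scores_labels(
            [ScoreRecord("P1", 10, "F", "C", 0.9)],
            [ClinicalVariant("P1", 10, "L", "C", P, 1)],
        )
        assert joined == []
        assert report.n_ref_mismatch == 1

    def test_unmatched_clinical_counted(self):
        scores = [
            ScoreRecord("P1", 10, "F", "C", 0.9),
            ScoreRecord("P1", 11, "A", "T", 0.1),
        ]
        clinical = [
            ClinicalVariant("P1", 10, "F", "C", P, 1),
            ClinicalVariant("P1", 11, "A", "T", B, 1),
            ClinicalVariant("P1", 99, "W", "R", P, 1),
        ]
        joined, report = join_scores_labels(scores, clinical)
        assert len(joined) == 2
        assert report.n_unmatched_clinical == 1


REGIONS = [RegionAnnotation("P1", "30-50", "TM")]


def _items(positions, acc="P1"):
    return [ScoreRecord(acc, p, "A", "T", 0.5) for p in positions]


class TestSubsetResidues:
    def test_inclusive_boundaries(self):
        kept, _ = subset_residues(_items([29, 30, 50, 51]), REGIONS, "inside", "TM")
        assert [i.position for i in kept] == [30, 50]

    def test_outside_is_the_complement(self):
        kept, _ = subset_residues(_items([29, 30, 50, 51]), REGIONS, "outside", "TM")
        assert [i.position for i in kept] == [29, 51]

    def test_unannotated_accessions_dropped_in_both_modes(self):
        items = _items([40], acc="P2")
        for mode in ("inside", "outside"):
            kept, report = subset_residues(items, REGIONS, mode, "TM")
            assert kept == []
            assert report.n_dropped_unannotated == 1

    def test_inside_outside_partition_annotated_items(self):
        items = _items(range(1, 101))
        inside, _ = subset_residues(items, REGIONS, "inside", "TM")
        outside, _ = subset_residues(items, REGIONS, "outside", "TM")
        assert len(inside) + len(outside) == len(items)
        assert {i.position for i in inside} & {i.position for i in outside} == set()

    def test_region_type_filter(self):
        regions = REGIONS + [RegionAnnotation("P1", "60-70", "IBS")]
        kept, _ = subset_residues(_items([65]), regions, "inside", "TM")
        assert kept == []
        kept, _ = subset_residues(_items([65]), regions, "inside", "IBS")
        assert len(kept) == 1


class TestConfidenceFilter:
    CONF = {("P1", 1): 49.9, ("P1", 2): 50.0, ("P1", 3): 80.0}

    def test_strictly_below_cutoff_dropped(self):
        kept, report = filter_by_confidence(_items([1, 2, 3]), self.CONF, 50.0)
        assert [i.position for i in kept] == [2, 3]
        assert report.n_below_cutoff == 1

    def test_missing_confidence_counted(self):
        kept, report = filter_by_confidence(_items([1, 9]), self.CONF, 50.0)
        assert report.n_missing == 1

    def test_mixed_fixture_counts(self):
        conf = {("P1", p): (30.0 if p <= 4 else 90.0) for p in range(1, 11)}
        kept, _ = filter_by_confidence(_items(range(1, 11)), conf, 50.0)
        assert len(kept) == 6


class TestFrequencies:
    METAS = [ProteinMeta("P1", 100), ProteinMeta("P2", 150)]

    def test_empty_inputs_are_zero(self):
        freq = mutation_frequencies([], [], self.METAS)
        assert freq.f_cv_benign == freq.f_am_pathogenic == 0.0

    def test_clinical_count_over_summed_length(self):
        clinical = [
            ClinicalVariant("P1", p, "A", "T", B, 1) for p in range(1, 6)
        ]
        freq = mutation_frequencies(clinical, [], self.METAS)
        assert freq.f_cv_benign == pytest.approx(5 / 250)

    def test_six_snv_predictions_per_residue_half_and_half(self):
        # every residue: 3 benign-band + 3 pathogenic-band SNV predictions
        metas = [ProteinMeta("P1", 10)]
        scores = []
        for pos in range(1, 11):
            for alt, s in zip("TSP", (0.05, 0.1, 0.2)):
                scores.append(ScoreRecord("P1", pos, "A", alt, s))
            for alt, s in zip("VGD", (0.7, 0.8, 0.9)):
                scores.append(ScoreRecord("P1", pos, "A", alt, s))
        freq = mutation_frequencies([], scores, metas, snv_restrict=True)
        assert freq.f_am_benign == pytest.approx(3.0)
        assert freq.f_am_pathogenic == pytest.approx(3.0)

    def test_ambiguous_predictions_count_in_neither(self):
        scores = [ScoreRecord("P1", 1, "A", "T", 0.45)]
        freq = mutation_frequencies([], scores, [ProteinMeta("P1", 10)])
        assert freq.f_am_benign == freq.f_am_pathogenic == 0.0

    def test_snv_restriction_drops_unreachable(self):
        scores = [
            ScoreRecord("P1", 1, "F", "E", 0.9),  # not SNV-reachable
            ScoreRecord("P1", 2, "F", "C", 0.9),
        ]
        freq = mutation_frequencies([], scores, [ProteinMeta("P1", 10)],
                                    snv_restrict=True)
        assert freq.f_am_pathogenic == pytest.approx(1 / 10)

    def test_missing_length_names_the_accession(self):
        with pytest.raises(ValueError, match="P9"):
            mutation_frequencies(
                [ClinicalVariant("P9", 1, "A", "T", B, 1)], [], self.METAS
            )

    def test_doubling_lengths_halves_frequencies(self):
        clinical = [ClinicalVariant("P1", 1, "A", "T", P, 1)]
        scores = [ScoreRecord("P1", 1, "A", "T", 0.9)]
        f1 = mutation_frequencies(clinical, scores, [ProteinMeta("P1", 100)])
        f2 = mutation_frequencies(clinical, scores, [ProteinMeta("P1", 200)])
        assert f2.f_cv_pathogenic == pytest.approx(f1.f_cv_pathogenic / 2)
        assert f2.f_am_pathogenic == pytest.approx(f1.f_am_pathogenic / 2)


class TestBenchmarkProteinSet:
    def test_perfect_concordance_gives_unit_metrics(self, separated_cohort):
        b = separated_cohort
        report = benchmark_protein_set(b.protein_set, b.scores, b.clinical, b.metas)
        assert report.ppv == report.tpr == report.f1 == 1.0
        assert report.mcc == 1.0
        assert report.auc_roc == 1.0

    def test_empty_set_is_degenerate_not_an_exception(self, small_cohort):
        b = small_cohort
        empty = ProteinSet("empty", ("NOPE",))
        report = benchmark_protein_set(empty, b.scores, b.clinical, b.metas)
        assert report.n_mutations == 0
        assert report.degenerate

    def test_filters_never_increase_n_mutations(self, small_cohort):
        b = small_cohort
        base = benchmark_protein_set(b.protein_set, b.scores, b.clinical, b.metas)
        with_conf = benchmark_protein_set(
            b.protein_set, b.scores, b.clinical, b.metas,
            confidence=b.confidence, plddt_min=50.0,
        )
        tm_only = benchmark_protein_set(
            b.protein_set, b.scores, b.clinical, b.metas,
            regions=b.regions, region_type="TM", region_mode="inside",
        )
        assert with_conf.n_mutations <= base.n_mutations
        assert tm_only.n_mutations <= base.n_mutations

    def test_tm_and_nontm_partition_annotated_proteins(self, small_cohort):
        b = small_cohort
        inside = benchmark_protein_set(
            b.protein_set, b.scores, b.clinical, b.metas,
            regions=b.regions, region_type="TM", region_mode="inside",
        )
        outside = benchmark_protein_set(
            b.protein_set, b.scores, b.clinical, b.metas,
            regions=b.regions, region_type="TM", region_mode="outside",
        )
        annotated = {r.protein_acc for r in b.regions}
        joined_in_annotated = [
            c for c in b.clinical if c.protein_acc in annotated
        ]
        assert inside.n_mutations + outside.n_mutations == len(joined_in_annotated)

    def test_report_tsv_is_reproducible(self, small_cohort, tmp_path):
        b = small_cohort
        report = benchmark_protein_set(b.protein_set, b.scores, b.clinical, b.metas)
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report_tsv([report], p1)
        write_report_tsv(
            [benchmark_protein_set(b.protein_set, b.scores, b.clinical, b.metas)], p2
        )
        assert p1.read_bytes() == p2.read_bytes()
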