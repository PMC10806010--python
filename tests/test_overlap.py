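"""Paired-compartment occupancy classification and pooled summaries."""

import numpy as np
import pandas as pd
import pytest

from myotcr import diversity
from myotcr.model import Compartment
from myotcr.overlap import (
    OverlapClassification,
    classify_overlap,
    cohort_overlap_summary,
    scatter_table,
)
from myotcr.simulate import CohortConfig, generate_cohort

from conftest import make_sample


def paired(counts_m, counts_b, cdr3_m=None, cdr3_b=None):
    muscle = make_sample(counts_m, "S_M", "P01", Compartment.MUSCLE, cdr3s=cdr3_m)
    blood = make_sample(counts_b, "S_B", "P01", Compartment.BLOOD, cdr3s=cdr3_b)
    return muscle, blood


class TestClassifyOverlap:
    def test_identical_tables_all_shared(self):
        muscle, blood = paired([10, 20, 30], [10, 20, 30])
        cls = classify_overlap(muscle, blood)
        assert (cls.table["label"] == "shared").all()
        assert cls.n_dominant_muscle_restricted == 0

    def test_disjoint_tables_all_restricted(self):
        cdr3_m = ["CAAAF", "CCCCF", "CDDDF"]
        cdr3_b = ["CEEEF", "CFFFF", "CGGGF"]
        muscle, blood = paired([5, 5, 5], [5, 5, 5], cdr3_m, cdr3_b)
        cls = classify_overlap(muscle, blood)
        labels = cls.table["label"]
        assert labels.value_counts().to_dict() == {
            "muscle_restricted": 3, "blood_restricted": 3,
        }

    def test_subject_mismatch_rejected(self):
        muscle = make_sample([5], "S_M", "P01", Compartment.MUSCLE)
        blood = make_sample([5], "S_B", "P02", Compartment.BLOOD)
        with pytest.raises(ValueError, match="subject mismatch"):
            classify_overlap(muscle, blood)

    def test_unequal_depths_refused_unless_forced(self):
        muscle, blood = paired([10, 10], [10, 5])
        with pytest.raises(ValueError, match="unequal depths"):
            classify_overlap(muscle, blood)
        cls = classify_overlap(muscle, blood, force=True)
        assert len(cls.table) > 0

    def test_labels_symmetric_under_compartment_swap(self):
        cdr3_m = ["CAAAF", "CCCCF", "CDDDF"]
        cdr3_b = ["CAAAF", "CEEEF", "CFFFF"]
        muscle, blood = paired([60, 20, 20], [50, 30, 20], cdr3_m, cdr3_b)
        fwd = classify_overlap(muscle, blood)
        # swap the compartments by relabelling the same tables
        muscle2 = make_sample([50, 30, 20], "S_M", "P01", Compartment.MUSCLE, cdr3s=cdr3_b)
        blood2 = make_sample([60, 20, 20], "S_B", "P01", Compartment.BLOOD, cdr3s=cdr3_m)
        rev = classify_overlap(muscle2, blood2)
        swap = {"muscle_restricted": "blood_restricted",
                "blood_restricted": "muscle_restricted", "shared": "shared"}
        for key, lab in fwd.table["label"].items():
            assert rev.table.loc[key, "label"] == swap[lab]

    def test_min_umi_evidence_threshold(self):
        cdr3 = ["CAAAF", "CCCCF"]
        muscle, blood = paired([50, 50], [99, 1], cdr3, cdr3)
        loose = classify_overlap(muscle, blood, min_umi=1)
        strict = classify_overlap(muscle, blood, min_umi=2)
        assert (loose.table["label"] == "shared").all()
        assert (strict.table["label"] == "muscle_restricted").sum() == 1

    def test_cdr3_only_matching_ignores_v_gene(self):
        cdr3 = ["CAAAF"]
        muscle = make_sample([10], "S_M", "P01", Compartment.MUSCLE, cdr3s=cdr3,
                             v_genes=["TRBV20-1"])
        blood = make_sample([10], "S_B", "P01", Compartment.BLOOD, cdr3s=cdr3,
                            v_genes=["TRBV29-1"])
        full = classify_overlap(muscle, blood, key="full")
        loose = classify_overlap(muscle, blood, key="cdr3")
        assert (full.table["label"] != "shared").all()
        assert (loose.table["label"] == "shared").all()

    def test_restriction_monotone_under_blood_subsampling(self):
        samples, _, _ = generate_cohort(
            CohortConfig(n_patients=1, n_controls=0, clones_per_sample=400,
                         depth_reads=20_000), seed=5,
        )
        muscle = next(s for s in samples if s.compartment is Compartment.MUSCLE)
        blood = next(s for s in samples if s.compartment is Compartment.BLOOD)
        muscle_10k = diversity.subsample_reads(muscle, 10_000, seed=0)
        blood_10k = diversity.subsample_reads(blood, 10_000, seed=1)
        # deeper subsample of blood only: reads can vanish, never appear
        blood_5k = blood_10k.replace_counts(
            np.random.default_rng(2).multivariate_hypergeometric(blood_10k.counts(), 5000)
        )
        full = classify_overlap(muscle_10k, blood_10k)
        nested = classify_overlap(muscle_10k, blood_5k, force=True)
        restricted_full = set(full.table.index[full.table["label"] == "muscle_restricted"])
        restricted_nested = set(nested.table.index[nested.table["label"] == "muscle_restricted"])
        assert restricted_full <= restricted_nested


class TestCohortSummary:
    def _cls(self, subject, dominant, restricted, shared_dom=0):
        return OverlapClassification(
            subject_id=subject,
            table=pd.DataFrame(),
            n_dominant_muscle=dominant,
            n_dominant_muscle_restricted=restricted,
            n_dominant_shared_still_dominant_in_blood=shared_dom,
        )

    def test_pooled_counts_and_rounded_percentage(self):
        # 352 dominant muscle clones of which 97 restricted -> 28% at 0 dp
        per = [self._cls(f"P{i:02d}", 352 // 20 + (1 if i < 352 % 20 else 0),
                         97 // 20 + (1 if i < 97 % 20 else 0),
                         shared_dom=1 if i < 13 else 0)
               for i in range(20)]
        summary, per_subject = cohort_overlap_summary(per)
        row = summary.iloc[0]
        assert row["n_dominant_muscle"] == 352
        assert row["n_dominant_muscle_restricted"] == 97
        assert row["pct_restricted"] == pytest.approx(100 * 97 / 352)
        assert row["pct_restricted_rounded"] == 28
        assert row["n_subjects_with_shared_dominant_in_blood"] == 13

    def test_single_subject_without_restriction(self):
        summary, _ = cohort_overlap_summary([self._cls("P01", 10, 0)])
        assert summary.iloc[0]["pct_restricted"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort_overlap_summary([])


class TestScatterTable:
    def test_rows_cover_union_of_clone_keys(self):
        cdr3_m = ["CAAAF", "CCCCF", "CDDDF"]
        cdr3_b = ["CAAAF", "CEEEF", "CFFFF", "CGGGF"]
        muscle, blood = paired([40, 30, 30], [25, 25, 25, 25], cdr3_m, cdr3_b)
        cls = classify_overlap(muscle, blood)
        table = scatter_table(cls)
        assert len(table) == 6  # union: 3 + 4 with one shared

    def test_restricted_clone_has_zero_blood_frequency(self):
        cdr3_m = ["CAAAF", "CCCCF"]
        cdr3_b = ["CAAAF", "CEEEF"]
        muscle, blood = paired([80, 20], [50, 50], cdr3_m, cdr3_b)
        table = scatter_table(classify_overlap(muscle, blood))
        restricted = table[table["label"] == "muscle_restricted"]
        assert (restricted["frequency_pct_blood"] == 0).all()
        assert (restricted["frequency_pct_muscle"] > 0).all()

    def test_shared_clone_keeps_both_frequencies(self):
        cdr3 = ["CAAAF", "CCCCF"]
        muscle, blood = paired([2, 98], [1, 99], cdr3, cdr3)
        table = scatter_table(classify_overlap(muscle, blood))
        row = table.xs("CAAAF", level="cdr3_aa").iloc[0]
        assert row["frequency_pct_muscle"] == pytest.approx(2.0)
        assert row["frequency_pct_blood"] == pytest.approx(1.0)
        assert row["label"] == "shared"


class TestDetectionLimitMode:
    def test_soft_restriction_exceeds_hard_truth(self):
        config = CohortConfig(n_patients=4, n_controls=0, clones_per_sample=500,
                              depth_reads=15_000, detection_limit_mode=True)
        samples, _, truth = generate_cohort(config, seed=9)
        # in this mode no clone is truly absent from blood ...
        muscle_truth = truth.clones[truth.clones["origin"] == "muscle"]
        assert (muscle_truth["model_freq_blood"] > 0).all()
        # ... yet the measured restricted fraction among dominant clones stays
        # well above the hard-restriction truth of zero (detection limit)
        by_subject = {}
        for k, s in enumerate(samples):
            ss = diversity.subsample_reads(s, 10_000, seed=k)
            by_subject.setdefault(ss.subject_id, {})[ss.compartment.value] = ss
        cls = [classify_overlap(p["muscle"], p["blood"]) for p in by_subject.values()]
        summary, _ = cohort_overlap_summary(cls)
        assert summary.iloc[0]["pct_restricted"] > 10.0
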