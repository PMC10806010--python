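"""Compartment-occupancy classification of a subject's clones.

For each subject with paired muscle and blood samples (subsampled to the
same depth), every clone key in the union of the two repertoires is
labelled:

* ``muscle_restricted`` — found in muscle, not retraced in blood;
* ``shared`` — found in both compartments;
* ``blood_restricted`` — found in blood only.

"Found" means at least ``min_umi`` UMIs (default 1) at the analysis
depth. Dominance (frequency >= 0.5% by default) is evaluated per
compartment, and the cohort summary pools dominant muscle clones across
subjects to report the muscle-restricted percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import DEFAULT_DOMINANCE_PCT, clone_frequencies
from .model import Compartment, RepertoireSample

log = logging.getLogger(__name__)

LABELS = ["muscle_restricted", "shared", "blood_restricted"]


@dataclass
class OverlapClassification:
    """Per-clone occupancy labels and dominant-clone overlap counts."""

    subject_id: str
    table: pd.DataFrame = field(repr=False)  # one row per clone key in the union
    n_dominant_muscle: int = 0
    n_dominant_muscle_restricted: int = 0
    n_dominant_shared_still_dominant_in_blood: int = 0

    @property
    def frac_dominant_muscle_restricted(self) -> float:
        if self.n_dominant_muscle == 0:
            return float("nan")
        return self.n_dominant_muscle_restricted / self.n_dominant_muscle


def _key_frame(sample: RepertoireSample, key: str, dominance_pct: float) -> pd.DataFrame:
    freqs = clone_frequencies(sample, dominance_pct)
    if key == "cdr3":
        grouped = freqs.groupby("cdr3_aa", as_index=True).agg(
            umi_count=("umi_count", "sum"), frequency_pct=("frequency_pct", "sum")
        )
        grouped["is_dominant"] = grouped["frequency_pct"] >= dominance_pct
        return grouped
    if key == "full":
        out = freqs.set_index(["v_gene", "cdr3_aa", "j_gene"])
        return out[["umi_count", "frequency_pct", "is_dominant"]]
    raise ValueError(f"unknown matching key {key!r}")


def classify_overlap(
    muscle: RepertoireSample,
    blood: RepertoireSample,
    key: str = "full",
    min_umi: int = 1,
    dominance_pct: float = DEFAULT_DOMINANCE_PCT,
    force: bool = False,
) -> OverlapClassification:
    """Label every clone of a subject as muscle-restricted/shared/blood-restricted.

    ``key`` selects the retracing identity: ``"full"`` matches on
    (V gene, CDR3 aa, J gene); ``"cdr3"`` on the CDR3 amino-acid string
    alone. A clone counts as present in a compartment when it has at
    least ``min_umi`` UMIs there. The three labels partition the union of
    the subject's clone keys and are symmetric under swapping the
    compartments.
    """
    if muscle.subject_id != blood.subject_id:
        raise ValueError(
            f"subject mismatch: muscle={muscle.subject_id!r} blood={blood.subject_id!r}"
        )
    if muscle.compartment is not Compartment.MUSCLE or blood.compartment is not Compartment.BLOOD:
        raise ValueError("arguments must be (muscle sample, blood sample)")
    if muscle.total_reads != blood.total_reads:
        msg = (
            f"subject {muscle.subject_id}: unequal depths "
            f"(muscle {muscle.total_reads}, blood {blood.total_reads})"
        )
        if not force:
            raise ValueError(msg + "; subsample both to a common depth or pass force=True")
        log.warning("%s; proceeding under force=True", msg)

    m = _key_frame(muscle, key, dominance_pct)
    b = _key_frame(blood, key, dominance_pct)
    joined = m.join(b, how="outer", lsuffix="_muscle", rsuffix="_blood")
    cnt_m = joined["umi_count_muscle"].fillna(0).to_numpy()
    cnt_b = joined["umi_count_blood"].fillna(0).to_numpy()
    in_m = cnt_m >= min_umi
    in_b = cnt_b >= min_umi
    label = np.where(in_m & in_b, "shared", np.where(in_m, "muscle_restricted", "blood_restricted"))
    table = pd.DataFrame(
        {
            "umi_muscle": cnt_m.astype(np.int64),
            "umi_blood": cnt_b.astype(np.int64),
            "frequency_pct_muscle": joined["frequency_pct_muscle"].fillna(0.0),
            "frequency_pct_blood": joined["frequency_pct_blood"].fillna(0.0),
            "dominant_muscle": joined["is_dominant_muscle"].astype("boolean").fillna(False).astype(bool),
            "dominant_blood": joined["is_dominant_blood"].astype("boolean").fillna(False).astype(bool),
            "label": label,
        },
        index=joined.index,
    )
    dom_m = table["dominant_muscle"].to_numpy()
    restricted = table["label"].to_numpy() == "muscle_restricted"
    shared_dom_blood = dom_m & table["dominant_blood"].to_numpy()
    return OverlapClassification(
        subject_id=muscle.subject_id,
        table=table,
        n_dominant_muscle=int(dom_m.sum()),
        n_dominant_muscle_restricted=int((dom_m & restricted).sum()),
        n_dominant_shared_still_dominant_in_blood=int(shared_dom_blood.sum()),
    )


def cohort_overlap_summary(
    classifications: Sequence[OverlapClassification],
) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Pool dominant-muscle-clone counts across subjects.

    Returns ``(summary, per_subject)``: the one-row pooled summary
    (total dominant muscle clones, how many are muscle-restricted, the
    restricted percentage both full-precision and rounded to whole
    percent) and a per-subject table with the same counts plus an
    indicator of whether at least one muscle-dominant clone remains
    dominant in blood.
    """
    if not classifications:
        raise ValueError("no classifications to summarise")
    per_subject = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in classifications],
            "n_dominant_muscle": [c.n_dominant_muscle for c in classifications],
            "n_dominant_muscle_restricted": [
                c.n_dominant_muscle_restricted for c in classifications
            ],
            "has_shared_dominant_in_blood": [
                c.n_dominant_shared_still_dominant_in_blood > 0 for c in classifications
            ],
        }
    )
    total = int(per_subject["n_dominant_muscle"].sum())
    restricted = int(per_subject["n_dominant_muscle_restricted"].sum())
    pct = 100.0 * restricted / total if total else float("nan")
    summary = pd.DataFrame(
        [
            {
                "n_subjects": len(classifications),
                "n_dominant_muscle": total,
                "n_dominant_muscle_restricted": restricted,
                "pct_restricted": pct,
                "pct_restricted_rounded": int(round(pct)) if total else np.nan,
                "n_subjects_with_shared_dominant_in_blood": int(
                    per_subject["has_shared_dominant_in_blood"].sum()
                ),
            }
        ]
    )
    return summary, per_subject


def scatter_table(classification: OverlapClassification) -> pd.DataFrame:
    """Per-clone paired-frequency table for muscle-vs-blood scatter plots.

    One row per clone key in the union: muscle frequency (%), blood
    frequency (% — 0 when absent) and the occupancy label. The dominance
    guide value used downstream is attached as ``attrs['dominance_pct']``.
    """
    out = classification.table[
        ["frequency_pct_muscle", "frequency_pct_blood", "label"]
    ].copy()
    out.attrs["dominance_pct"] = DEFAULT_DOMINANCE_PCT
    return out
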