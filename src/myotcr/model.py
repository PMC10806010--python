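"""Core domain types for UMI-based TCR-beta clone tables.

A *clone* (clonotype) is identified within a sample by the triple
``(v_gene, cdr3_aa, j_gene)``; its abundance is the number of unique UMIs
observed for it, which is the unit of all frequency arithmetic downstream.
Samples come from one of two compartments, peripheral blood or muscle
tissue, and are paired per subject.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

#: The 20 standard amino acids (one-letter codes).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: Placeholder used when the J gene call is unknown.
UNKNOWN_J = ""

#: Columns of the canonical in-memory clone table.
CLONE_COLUMNS = ["v_gene", "cdr3_aa", "j_gene", "umi_count"]


class Compartment(str, enum.Enum):
    """Tissue compartment of a repertoire sample."""

    BLOOD = "blood"
    MUSCLE = "muscle"

    @classmethod
    def parse(cls, value: "str | Compartment") -> "Compartment":
        if isinstance(value, Compartment):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown compartment {value!r}; expected 'blood' or 'muscle'"
            ) from None


class SubjectGroup(str, enum.Enum):
    PATIENT = "patient"
    HEALTHY_CONTROL = "healthy_control"


class MyositisSubtype(str, enum.Enum):
    DM = "DM"
    IMNM = "IMNM"
    NM_OM = "NM_OM"
    ASYS = "ASyS"
    NONE = "none"


class AntibodyClass(str, enum.Enum):
    MYOSITIS_SPECIFIC = "myositis_specific"
    MYOSITIS_ASSOCIATED = "myositis_associated"
    SERONEGATIVE = "seronegative"
    NONE = "none"


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def validate_cdr3(cdr3: str, row: Optional[int] = None) -> str:
    """Check that a CDR3 string is non-empty and alphabet-restricted."""
    where = "" if row is None else f" (row {row})"
    if not cdr3:
        raise ValidationError(f"empty CDR3 amino-acid sequence{where}")
    bad = set(cdr3) - _AA_SET
    if bad:
        raise ValidationError(
            f"illegal amino-acid character(s) {sorted(bad)} in CDR3 "
            f"{cdr3!r}{where}; allowed alphabet is {AA_ALPHABET}"
        )
    return cdr3


@dataclass(frozen=True)
class CloneRecord:
    """One clonotype in one sample.

    ``umi_count`` is the number of unique UMIs supporting the clone — the
    molecule count used as "reads" throughout the analysis.
    """

    sample_id: str
    subject_id: str
    compartment: Compartment
    v_gene: str
    j_gene: str
    cdr3_aa: str
    umi_count: int

    def __post_init__(self) -> None:
        if self.umi_count < 1:
            raise ValidationError(
                f"umi_count must be >= 1, got {self.umi_count} for clone "
                f"{self.key} in sample {self.sample_id}"
            )
        validate_cdr3(self.cdr3_aa)

    @property
    def key(self) -> tuple:
        """Clone identity: (V gene, CDR3 aa, J gene) within a sample."""
        return (self.v_gene, self.cdr3_aa, self.j_gene)


@dataclass
class RepertoireSample:
    """All clones of one (subject, compartment), stored as a table.

    The table has columns ``v_gene, cdr3_aa, j_gene, umi_count`` with one
    row per clone key; duplicate keys are merged (counts summed) on
    construction, so ingest is idempotent and row-order invariant.
    """

    sample_id: str
    subject_id: str
    compartment: Compartment
    table: pd.DataFrame = field(repr=False)
    subsampled: bool = False
    subsample_seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.compartment = Compartment.parse(self.compartment)
        self.table = _normalize_clone_frame(self.table, self.sample_id)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, records: "list[CloneRecord]") -> "RepertoireSample":
        if not records:
            raise ValidationError("cannot build a sample from zero clone records")
        first = records[0]
        for r in records:
            if (r.sample_id, r.subject_id, r.compartment) != (
                first.sample_id,
                first.subject_id,
                first.compartment,
            ):
                raise ValidationError(
                    f"mixed sample identity in records: {r.sample_id} vs {first.sample_id}"
                )
        table = pd.DataFrame(
            {
                "v_gene": [r.v_gene for r in records],
                "cdr3_aa": [r.cdr3_aa for r in records],
                "j_gene": [r.j_gene for r in records],
                "umi_count": [r.umi_count for r in records],
            }
        )
        return cls(first.sample_id, first.subject_id, first.compartment, table)

    # -- views ----------------------------------------------------------------

    @property
    def total_reads(self) -> int:
        """Sum of unique-UMI counts over all clones."""
        return int(self.table["umi_count"].sum())

    @property
    def n_clones(self) -> int:
        return len(self.table)

    @property
    def clones(self) -> Iterator[CloneRecord]:
        for row in self.table.itertuples(index=False):
            yield CloneRecord(
                self.sample_id,
                self.subject_id,
                self.compartment,
                row.v_gene,
                row.cdr3_aa,
                row.j_gene,
                int(row.umi_count),
            )

    def counts(self) -> np.ndarray:
        return self.table["umi_count"].to_numpy(dtype=np.int64)

    def keys(self, cdr3_only: bool = False) -> pd.Index:
        """Clone identity keys, in table order."""
        if cdr3_only:
            return pd.Index(self.table["cdr3_aa"])
        return pd.MultiIndex.from_frame(self.table[["v_gene", "cdr3_aa", "j_gene"]])

    def replace_counts(
        self,
        counts: np.ndarray,
        subsampled: bool = False,
        subsample_seed: Optional[int] = None,
    ) -> "RepertoireSample":
        """New sample with the given per-clone counts; zero-count clones dropped."""
        table = self.table.assign(umi_count=np.asarray(counts, dtype=np.int64))
        table = table[table["umi_count"] > 0]
        return RepertoireSample(
            self.sample_id,
            self.subject_id,
            self.compartment,
            table,
            subsampled=subsampled,
            subsample_seed=subsample_seed,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RepertoireSample):
            return NotImplemented
        if (self.sample_id, self.subject_id, self.compartment) != (
            other.sample_id,
            other.subject_id,
            other.compartment,
        ):
            return False
        a = self.table.sort_values(["v_gene", "cdr3_aa", "j_gene"]).reset_index(drop=True)
        b = other.table.sort_values(["v_gene", "cdr3_aa", "j_gene"]).reset_index(drop=True)
        return a.equals(b)


def _normalize_clone_frame(table: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    missing = [c for c in CLONE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(
            f"clone table for sample {sample_id} missing column(s): {missing}"
        )
    table = table[CLONE_COLUMNS].copy()
    table["j_gene"] = table["j_gene"].fillna(UNKNOWN_J).astype(str)
    table["v_gene"] = table["v_gene"].astype(str)
    table["cdr3_aa"] = table["cdr3_aa"].astype(str)
    counts = pd.to_numeric(table["umi_count"], errors="raise")
    if (counts < 1).any():
        bad = int(np.argmax((counts < 1).to_numpy()))
        raise ValidationError(
            f"non-positive umi_count at clone row {bad} of sample {sample_id}"
        )
    table["umi_count"] = counts.astype(np.int64)
    for i, c in enumerate(table["cdr3_aa"]):
        validate_cdr3(c, row=i)
    # merge duplicate clone keys by summing counts (idempotent, order-invariant)
    table = (
        table.groupby(["v_gene", "cdr3_aa", "j_gene"], as_index=False, sort=True)[
            "umi_count"
        ]
        .sum()
        [CLONE_COLUMNS]
    )
    return table.reset_index(drop=True)


@dataclass(frozen=True)
class SubjectMeta:
    """Clinical metadata for one subject.

    ``ck_u_per_l`` is serum creatine kinase in U/L; ``mmt_score`` is the
    manual muscle testing strength score. Healthy controls carry neither.
    """

    subject_id: str
    group: SubjectGroup
    subtype: MyositisSubtype = MyositisSubtype.NONE
    antibody_class: AntibodyClass = AntibodyClass.NONE
    ck_u_per_l: Optional[float] = None
    mmt_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ck_u_per_l is not None and self.ck_u_per_l < 0:
            raise ValidationError(
                f"negative CK for subject {self.subject_id}: {self.ck_u_per_l}"
            )
        if (
            self.group is SubjectGroup.HEALTHY_CONTROL
            and self.subtype is not MyositisSubtype.NONE
        ):
            raise ValidationError(
                f"healthy control {self.subject_id} must have subtype 'none'"
            )
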