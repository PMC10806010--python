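"""Readers and writers for clone tables and subject metadata.

Clone tables are AIRR-rearrangement-style TSV: one row per clone per
sample, with columns ``sample_id, subject_id, compartment, v_call,
j_call, junction_aa, duplicate_count`` (``duplicate_count`` holds the
unique-UMI count). A *dialect* mapping lets arbitrary headers be mapped
onto these canonical names.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import (
    AntibodyClass,
    CloneRecord,
    Compartment,
    MyositisSubtype,
    RepertoireSample,
    SchemaError,
    SubjectGroup,
    SubjectMeta,
    UNKNOWN_J,
    ValidationError,
)

log = logging.getLogger(__name__)

#: canonical name -> AIRR column header
AIRR_COLUMNS: Mapping[str, str] = {
    "sample_id": "sample_id",
    "subject_id": "subject_id",
    "compartment": "compartment",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "cdr3_aa": "junction_aa",
    "umi_count": "duplicate_count",
}

_MANDATORY = ["sample_id", "subject_id", "compartment", "v_gene", "cdr3_aa", "umi_count"]

META_COLUMNS = ["subject_id", "group", "subtype", "antibody_class", "ck_u_per_l", "mmt_score"]


def read_clone_table(
    path: "str | Path",
    dialect: Optional[Mapping[str, str]] = None,
) -> "list[RepertoireSample]":
    """Read a clone-table TSV into one :class:`RepertoireSample` per sample id.

    Duplicate clone keys within a sample are merged by summing UMI counts,
    so the result is independent of row order.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Optional mapping from canonical column names (``sample_id``,
        ``subject_id``, ``compartment``, ``v_gene``, ``j_gene``,
        ``cdr3_aa``, ``umi_count``) to the headers actually present in the
        file. Defaults to AIRR conventions.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(AIRR_COLUMNS)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [colmap[c] for c in _MANDATORY if colmap[c] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "j_gene" not in df.columns:
        df["j_gene"] = UNKNOWN_J
    if df.empty:
        log.warning("%s: clone table has a header but no rows", path)
        return []
    try:
        df["umi_count"] = pd.to_numeric(df["umi_count"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric umi_count: {exc}") from None
    bad = df.index[df["umi_count"] < 1]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive umi_count at data row {int(bad[0]) + 1}"
        )
    samples = []
    for sample_id, chunk in df.groupby("sample_id", sort=True):
        subject = chunk["subject_id"].unique()
        if len(subject) > 1:
            raise ValidationError(
                f"{path}: sample {sample_id} maps to multiple subjects: {list(subject)}"
            )
        comp = chunk["compartment"].unique()
        if len(comp) > 1:
            raise ValidationError(
                f"{path}: sample {sample_id} maps to multiple compartments: {list(comp)}"
            )
        samples.append(
            RepertoireSample(
                sample_id=str(sample_id),
                subject_id=str(subject[0]),
                compartment=Compartment.parse(comp[0]),
                table=chunk[["v_gene", "cdr3_aa", "j_gene", "umi_count"]],
            )
        )
    return samples


def write_clone_table(
    samples: Sequence[RepertoireSample],
    path: "str | Path",
    dialect: Optional[Mapping[str, str]] = None,
) -> Path:
    """Write samples to TSV such that ``read_clone_table`` round-trips them."""
    path = Path(path)
    colmap = dict(AIRR_COLUMNS)
    if dialect:
        colmap.update(dialect)
    frames = []
    for s in samples:
        t = s.table.copy()
        t.insert(0, "compartment", s.compartment.value)
        t.insert(0, "subject_id", s.subject_id)
        t.insert(0, "sample_id", s.sample_id)
        frames.append(t)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(colmap))
    out = out.rename(columns=colmap)[[colmap[c] for c in colmap]]
    out.to_csv(path, sep="\t", index=False)
    return path


def read_subject_meta(path: "str | Path") -> "list[SubjectMeta]":
    """Read the subject metadata TSV (one row per subject)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            SubjectMeta(
                subject_id=d["subject_id"],
                group=SubjectGroup(d["group"]),
                subtype=MyositisSubtype(d.get("subtype") or "none"),
                antibody_class=AntibodyClass(d.get("antibody_class") or "none"),
                ck_u_per_l=_opt_float(d.get("ck_u_per_l")),
                mmt_score=_opt_float(d.get("mmt_score")),
            )
        )
    return records


def write_subject_meta(meta: Sequence[SubjectMeta], path: "str | Path") -> Path:
    path = Path(path)
    rows = [
        {
            "subject_id": m.subject_id,
            "group": m.group.value,
            "subtype": m.subtype.value,
            "antibody_class": m.antibody_class.value,
            "ck_u_per_l": "" if m.ck_u_per_l is None else m.ck_u_per_l,
            "mmt_score": "" if m.mmt_score is None else m.mmt_score,
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def meta_frame(meta: Sequence[SubjectMeta]) -> pd.DataFrame:
    """Subject metadata as a DataFrame indexed by subject_id."""
    df = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in meta],
            "group": [m.group.value for m in meta],
            "subtype": [m.subtype.value for m in meta],
            "antibody_class": [m.antibody_class.value for m in meta],
            "ck_u_per_l": [m.ck_u_per_l for m in meta],
            "mmt_score": [m.mmt_score for m in meta],
        }
    )
    return df.set_index("subject_id")


def _opt_float(value: Optional[str]) -> Optional[float]:
    if value is None or value == "":
        return None
    return float(value)
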