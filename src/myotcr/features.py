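"""CDR3 physicochemical features and V-gene usage.

Feature definitions (per unique clone, from the CDR3 amino-acid string):

* **length** — residue count.
* **net charge** — side-chain counting at pH 7: ``(#K + #R) - (#D + #E)
  + h * #H`` with a fractional histidine contribution ``h`` (default
  0.1). A Henderson–Hasselbalch mode computes side-chain charges from
  pKa values at a configurable pH instead.
* **hydrophobicity** — mean per-residue value on a hydropathy scale,
  Kyte–Doolittle by default (higher = more hydrophobic; bounded by the
  scale extremes, [-4.5, 4.5] for Kyte–Doolittle).

V-gene usage is the percentage of the repertoire attributed to each V
gene, either per distinct clone (default) or per UMI read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import AA_ALPHABET, RepertoireSample, validate_cdr3

log = logging.getLogger(__name__)

KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Eisenberg consensus hydrophobicity (higher = more hydrophobic)
EISENBERG: Mapping[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Hopp–Woods hydrophilicity, negated so that higher = more hydrophobic,
# keeping one sign convention across all scales.
HOPP_WOODS_NEGATED: Mapping[str, float] = {
    "A": 0.5, "R": -3.0, "N": -0.2, "D": -3.0, "C": 1.0,
    "Q": -0.2, "E": -3.0, "G": 0.0, "H": 0.5, "I": 1.8,
    "L": 1.8, "K": -3.0, "M": 1.3, "F": 2.5, "P": 0.0,
    "S": -0.3, "T": 0.4, "W": 3.4, "Y": 2.3, "V": 1.5,
}

SCALES: Mapping[str, Mapping[str, float]] = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
    "hopp-woods": HOPP_WOODS_NEGATED,
}

# side-chain pKa values for the Henderson–Hasselbalch charge mode
_PKA_POSITIVE = {"K": 10.5, "R": 12.5, "H": 6.0}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1}


@dataclass(frozen=True)
class CloneFeatures:
    cdr3_aa: str
    cdr3_length: int
    net_charge: float
    hydrophobicity: float


def net_charge(cdr3_aa: str, his_fraction: float = 0.1, ph: Optional[float] = None) -> float:
    """Approximate net side-chain charge of a CDR3 peptide.

    Default: integer counting ``(#K + #R) - (#D + #E) + his_fraction * #H``.
    If ``ph`` is given, per-residue Henderson–Hasselbalch charges are
    summed instead (K, R, H positive; D, E, C, Y negative; termini are
    ignored since the CDR3 sits inside the chain).
    """
    if ph is None:
        return (
            cdr3_aa.count("K")
            + cdr3_aa.count("R")
            - cdr3_aa.count("D")
            - cdr3_aa.count("E")
            + his_fraction * cdr3_aa.count("H")
        )
    charge = 0.0
    for aa in cdr3_aa:
        if aa in _PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (_PKA_NEGATIVE[aa] - ph))
    return charge


def hydrophobicity(cdr3_aa: str, scale: str = "kyte-doolittle") -> float:
    """Mean hydropathy of the CDR3 over the chosen scale."""
    values = SCALES[scale]
    return float(np.mean([values[aa] for aa in cdr3_aa]))


def compute_clone_features(
    cdr3_aa: str,
    scale: str = "kyte-doolittle",
    his_fraction: float = 0.1,
    ph: Optional[float] = None,
) -> CloneFeatures:
    """Length, net charge and mean hydrophobicity of one CDR3."""
    validate_cdr3(cdr3_aa)
    return CloneFeatures(
        cdr3_aa=cdr3_aa,
        cdr3_length=len(cdr3_aa),
        net_charge=net_charge(cdr3_aa, his_fraction=his_fraction, ph=ph),
        hydrophobicity=hydrophobicity(cdr3_aa, scale=scale),
    )


def feature_table(
    cdr3_list: Sequence[str],
    scale: str = "kyte-doolittle",
    his_fraction: float = 0.1,
    ph: Optional[float] = None,
) -> pd.DataFrame:
    """Vectorised per-clone feature table (one row per input CDR3)."""
    rows = [compute_clone_features(c, scale, his_fraction, ph) for c in cdr3_list]
    return pd.DataFrame([r.__dict__ for r in rows])


FEATURES = ["cdr3_length", "net_charge", "hydrophobicity"]


def feature_summary(
    features: pd.DataFrame,
    group_col: str,
    min_group_size: int = 2,
) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Per-group median/IQR of each feature plus pairwise comparisons.

    ``features`` must carry the feature columns and a grouping column
    (e.g. compartment or overlap label). Groups with fewer than
    ``min_group_size`` clones are excluded with a warning. Pairwise
    comparisons use two-sided Mann-Whitney tests with Bonferroni
    adjustment over the pairs within each feature.

    Returns ``(summary, comparisons)`` DataFrames.
    """
    from . import stats as _stats  # local import to avoid cycle

    groups = {}
    for name, chunk in features.groupby(group_col, sort=True):
        if len(chunk) < min_group_size:
            log.warning("group %r has %d < %d clones; excluded", name, len(chunk), min_group_size)
            continue
        groups[name] = chunk
    if len(groups) < 2:
        raise ValueError("need at least two usable groups")
    summary_rows = []
    for name, chunk in groups.items():
        for feat in FEATURES:
            x = chunk[feat].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summary_rows.append(
                {"group": name, "feature": feat, "n": len(x),
                 "median": med, "q1": q1, "q3": q3}
            )
    comp_frames = []
    for feat in FEATURES:
        by_group = {name: chunk[feat].to_numpy(dtype=float) for name, chunk in groups.items()}
        comp = _stats.compare_groups(by_group)
        comp_frames.append(comp.pairwise.assign(feature=feat))
    return pd.DataFrame(summary_rows), pd.concat(comp_frames, ignore_index=True)


def vgene_usage(
    table: "pd.DataFrame | RepertoireSample",
    weighting: str = "by_clone",
) -> pd.DataFrame:
    """V-gene usage as percentage of the repertoire, ranked.

    ``by_clone`` weights each distinct clone once; ``by_read`` weights by
    UMI count. Accepts a clone table (columns ``v_gene`` and, for
    ``by_read``, ``umi_count``) or a :class:`RepertoireSample`.
    """
    if isinstance(table, RepertoireSample):
        table = table.table
    v = table["v_gene"]
    if v.isna().all() or (v == "").all():
        raise ValueError("no V-gene annotations present")
    if weighting == "by_clone":
        counts = v.value_counts()
    elif weighting == "by_read":
        counts = table.groupby("v_gene")["umi_count"].sum().sort_values(ascending=False)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    pct = 100.0 * counts / counts.sum()
    out = pct.rename("frequency_pct").rename_axis("v_gene").reset_index()
    return out.sort_values(["frequency_pct", "v_gene"], ascending=[False, True]).reset_index(
        drop=True
    )
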