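"""Synthetic paired blood/muscle TCR-beta cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage can be exercised against planted truth:

* per patient, one muscle and one blood repertoire; controls give blood
  only. Clone generating frequencies follow a one-parameter power law
  over ranks (``p_i ∝ i^-s``) with a stronger skew in muscle than in
  blood, so muscle repertoires are more clonal by construction;
* a configurable fraction of muscle clones is *muscle-restricted*:
  excluded from the paired blood generating pool (or down-weighted below
  the detection limit in ``detection_limit_mode``);
* restricted clones draw longer CDR3s (shifted Poisson length) from a
  hydrophobicity-tilted residue alphabet, and their V genes favour
  TRBV20-1 while blood-private clones favour TRBV29-1;
* serum CK is a positive linear function of the muscle repertoire's
  generating-model Gini index plus Gaussian noise; the MMT strength
  score is a negative linear function of the same statistic;
* UMI counts are realised multinomially at a fixed read depth, so depth
  is conserved exactly and all sampling noise is explicit.

All randomness flows from a single seed through spawned per-subject
streams, so a subject's repertoire does not depend on cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import diversity
from .features import KYTE_DOOLITTLE
from .model import (
    AA_ALPHABET,
    AntibodyClass,
    Compartment,
    MyositisSubtype,
    RepertoireSample,
    SubjectGroup,
    SubjectMeta,
)

V_GENES = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV6-1", "TRBV7-2",
    "TRBV9", "TRBV10-3", "TRBV11-2", "TRBV12-3", "TRBV13", "TRBV15",
    "TRBV18", "TRBV19", "TRBV20-1", "TRBV25-1", "TRBV27", "TRBV28",
    "TRBV29-1", "TRBV30",
]
J_GENES = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]
MUSCLE_V = "TRBV20-1"
BLOOD_V = "TRBV29-1"

_LETTERS = np.frombuffer(AA_ALPHABET.encode("ascii"), dtype=np.uint8)
_KD = np.array([KYTE_DOOLITTLE[a] for a in AA_ALPHABET])


@dataclass
class CohortConfig:
    """Study-design and effect-size knobs of the synthetic cohort."""

    n_patients: int = 20
    n_controls: int = 10
    clones_per_sample: int = 2000
    depth_reads: int = 25_000
    # rank-frequency skew p_i ~ i^-s; jitter spreads the shape across subjects
    expansion_shape_blood: float = 0.6
    expansion_shape_muscle: float = 1.0
    muscle_shape_jitter: float = 0.15
    blood_shape_jitter: float = 0.05
    frac_muscle_restricted_dominant: float = 0.28
    cdr3_len_shift_restricted: int = 3
    hydrophobicity_shift_restricted: float = 0.5
    vbias_muscle: float = 3.0  # TRBV20-1 weight multiplier, restricted clones
    vbias_blood: float = 3.0  # TRBV29-1 weight multiplier, blood-private clones
    shared_blood_fraction: float = 0.30  # blood reads drawn from shared muscle clones
    detection_limit_mode: bool = False
    detection_limit_factor: float = 0.02
    ck_intercept: float = -3000.0
    ck_gini_slope: float = 8000.0
    ck_noise_sd: float = 800.0
    mmt_intercept: float = 100.0
    mmt_gini_slope: float = -40.0
    mmt_noise_sd: float = 6.0
    public_motif_patients: int = 0
    public_clone_freq: float = 0.02
    dominance_pct: float = 0.5
    cdr3_len_base: int = 8  # length = base + Poisson(mean_extra)
    cdr3_len_mean_extra: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_muscle_restricted_dominant", "shared_blood_fraction",
                     "detection_limit_factor", "public_clone_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("expansion_shape_blood", "expansion_shape_muscle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.depth_reads < self.clones_per_sample:
            raise ValueError(
                f"depth_reads ({self.depth_reads}) must be >= clones_per_sample "
                f"({self.clones_per_sample})"
            )
        if self.public_motif_patients > self.n_patients:
            raise ValueError("public_motif_patients exceeds n_patients")
        if self.mmt_gini_slope > 0:
            raise ValueError("mmt_gini_slope must be <= 0 (weaker muscle at higher clonality)")


@dataclass
class CohortTruth:
    """Ground-truth ledger: every planted label and generating frequency."""

    clones: pd.DataFrame = field(repr=False)
    subjects: pd.DataFrame = field(repr=False)
    config: CohortConfig = field(repr=False, default=None)


def power_law_freqs(n: int, shape: float) -> np.ndarray:
    """Normalised rank-frequency vector ``p_i ∝ i^-shape``."""
    p = np.arange(1, n + 1, dtype=float) ** (-shape)
    return p / p.sum()


def hydrophobic_tilt(shift: float) -> float:
    """Exponential-tilt parameter giving a mean Kyte-Doolittle shift.

    Residues are drawn with weight ``exp(t * KD(aa))``; this solves for
    ``t`` such that the mean KD value increases by ``shift`` relative to
    the uniform alphabet.
    """
    if shift == 0:
        return 0.0
    base_mean = _KD.mean()

    def gap(t: float) -> float:
        w = np.exp(t * _KD)
        return float((w * _KD).sum() / w.sum() - base_mean - shift)

    return brentq(gap, 0.0, 5.0)


def _tilted_weights(tilt: float) -> Optional[np.ndarray]:
    if tilt == 0:
        return None
    w = np.exp(tilt * _KD)
    return w / w.sum()


def _random_cdr3s(
    rng: np.random.Generator,
    n: int,
    mean_extra: float,
    base_len: int,
    weights: Optional[np.ndarray],
) -> "list[str]":
    """Random CDR3 strings 'C...F' with Poisson-distributed lengths.

    Interior residues are i.i.d. from the (possibly tilted) alphabet; no
    attempt is made at biologically valid V(D)J junctions.
    """
    lengths = base_len + rng.poisson(mean_extra, size=n)
    interior = lengths - 2
    total = int(interior.sum())
    codes = rng.choice(_LETTERS, size=total, p=weights)
    out = []
    pos = 0
    for m in interior:
        out.append("C" + bytes(codes[pos:pos + m]).decode("ascii") + "F")
        pos += m
    return out


def _vgene_weights(boost_gene: Optional[str], boost: float) -> np.ndarray:
    w = np.ones(len(V_GENES))
    if boost_gene is not None:
        w[V_GENES.index(boost_gene)] *= boost
    return w / w.sum()


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
) -> "tuple[list[RepertoireSample], list[SubjectMeta], CohortTruth]":
    """Generate the full synthetic cohort.

    Returns the repertoire samples (muscle+blood per patient, blood per
    control), subject metadata with clinical markers, and the truth
    ledger recording every planted label and generating frequency.
    Deterministic for a fixed config and seed (``seed`` overrides
    ``config.seed``).
    """
    config = config or CohortConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    n_subjects = config.n_patients + config.n_controls
    streams = root.spawn(n_subjects + 1)
    cohort_rng = np.random.default_rng(streams[n_subjects])

    tilt = hydrophobic_tilt(config.hydrophobicity_shift_restricted)
    tilted = _tilted_weights(tilt)
    v_neutral = _vgene_weights(None, 1.0)
    v_muscle = _vgene_weights(MUSCLE_V, config.vbias_muscle)
    v_blood = _vgene_weights(BLOOD_V, config.vbias_blood)

    motif = None
    if config.public_motif_patients > 0:
        motif = _random_cdr3s(cohort_rng, 1, config.cdr3_len_mean_extra,
                              config.cdr3_len_base, None)[0]

    samples: "list[RepertoireSample]" = []
    meta: "list[SubjectMeta]" = []
    clone_rows: "list[pd.DataFrame]" = []
    subject_rows: "list[dict]" = []

    for i in range(config.n_patients):
        subject_id = f"P{i + 1:02d}"
        rng = np.random.default_rng(streams[i])
        out = _generate_patient(subject_id, rng, config, tilted, v_neutral,
                                v_muscle, v_blood,
                                motif if i < config.public_motif_patients else None)
        patient_samples, clone_truth, gini_muscle = out
        samples.extend(patient_samples)
        clone_rows.append(clone_truth)
        ck = config.ck_intercept + config.ck_gini_slope * gini_muscle \
            + rng.normal(0.0, config.ck_noise_sd)
        mmt = config.mmt_intercept + config.mmt_gini_slope * gini_muscle \
            + rng.normal(0.0, config.mmt_noise_sd)
        meta.append(
            SubjectMeta(
                subject_id=subject_id,
                group=SubjectGroup.PATIENT,
                subtype=MyositisSubtype(
                    rng.choice(["DM", "IMNM", "NM_OM", "ASyS"],
                               p=[0.4, 0.25, 0.2, 0.15])
                ),
                antibody_class=AntibodyClass(
                    rng.choice(
                        ["myositis_specific", "myositis_associated", "seronegative"],
                        p=[0.5, 0.25, 0.25],
                    )
                ),
                ck_u_per_l=float(max(ck, 1.0)),
                mmt_score=float(mmt),
            )
        )
        subject_rows.append(
            {"subject_id": subject_id, "group": "patient",
             "analytic_gini_muscle": gini_muscle,
             "ck_u_per_l": meta[-1].ck_u_per_l, "mmt_score": meta[-1].mmt_score}
        )

    for i in range(config.n_controls):
        subject_id = f"HC{i + 1:02d}"
        rng = np.random.default_rng(streams[config.n_patients + i])
        s_b = config.expansion_shape_blood + config.blood_shape_jitter * rng.uniform(-1, 1)
        q = power_law_freqs(config.clones_per_sample, s_b)
        cdr3s = _random_cdr3s(rng, len(q), config.cdr3_len_mean_extra,
                              config.cdr3_len_base, None)
        v = [V_GENES[k] for k in rng.choice(len(V_GENES), size=len(q), p=v_blood)]
        j = [J_GENES[k] for k in rng.choice(len(J_GENES), size=len(q))]
        counts = rng.multinomial(config.depth_reads, q)
        table = pd.DataFrame(
            {"v_gene": v, "cdr3_aa": cdr3s, "j_gene": j, "umi_count": counts}
        )
        samples.append(
            RepertoireSample(f"{subject_id}_B", subject_id, Compartment.BLOOD,
                             table[table["umi_count"] > 0])
        )
        meta.append(SubjectMeta(subject_id=subject_id, group=SubjectGroup.HEALTHY_CONTROL))
        subject_rows.append(
            {"subject_id": subject_id, "group": "healthy_control",
             "analytic_gini_muscle": np.nan, "ck_u_per_l": np.nan, "mmt_score": np.nan}
        )

    truth = CohortTruth(
        clones=pd.concat(clone_rows, ignore_index=True),
        subjects=pd.DataFrame(subject_rows),
        config=config,
    )
    return samples, meta, truth


def _generate_patient(subject_id, rng, config, tilted, v_neutral, v_muscle, v_blood,
                      motif):
    """One patient: paired muscle and blood repertoires plus truth rows."""
    n = config.clones_per_sample
    s_m = config.expansion_shape_muscle + config.muscle_shape_jitter * rng.uniform(-1, 1)
    s_b = config.expansion_shape_blood + config.blood_shape_jitter * rng.uniform(-1, 1)
    p = power_law_freqs(n, s_m)
    restricted = rng.random(n) < config.frac_muscle_restricted_dominant
    public = np.zeros(n, dtype=bool)

    n_res = int(restricted.sum())
    cdr3 = np.empty(n, dtype=object)
    cdr3[~restricted] = _random_cdr3s(rng, n - n_res, config.cdr3_len_mean_extra,
                                      config.cdr3_len_base, None)
    cdr3[restricted] = _random_cdr3s(
        rng, n_res, config.cdr3_len_mean_extra + config.cdr3_len_shift_restricted,
        config.cdr3_len_base, tilted,
    )
    v = np.empty(n, dtype=object)
    v[~restricted] = [V_GENES[k] for k in
                      rng.choice(len(V_GENES), size=n - n_res, p=v_neutral)]
    v[restricted] = [V_GENES[k] for k in
                     rng.choice(len(V_GENES), size=n_res, p=v_muscle)]
    j = np.array([J_GENES[k] for k in rng.choice(len(J_GENES), size=n)], dtype=object)

    if motif is not None:
        # plant one dominant public clone within Hamming distance <= 1 of the motif
        seq = list(motif)
        if rng.random() < 0.8:
            pos = 1 + rng.integers(len(seq) - 2)
            seq[pos] = AA_ALPHABET[rng.integers(20)]
        p = np.concatenate([p * (1 - config.public_clone_freq), [config.public_clone_freq]])
        cdr3 = np.concatenate([cdr3, ["".join(seq)]])
        v = np.concatenate([v, [MUSCLE_V]])
        j = np.concatenate([j, [J_GENES[0]]])
        restricted = np.concatenate([restricted, [False]])
        public = np.concatenate([public, [True]])

    gini_muscle = diversity.gini_index(p)
    muscle_counts = rng.multinomial(config.depth_reads, p)
    muscle_table = pd.DataFrame(
        {"v_gene": v, "cdr3_aa": cdr3, "j_gene": j, "umi_count": muscle_counts}
    )

    # blood pool: private clones plus the non-restricted (shared) muscle clones
    q = power_law_freqs(n, s_b)
    cdr3_b = np.array(
        _random_cdr3s(rng, n, config.cdr3_len_mean_extra, config.cdr3_len_base, None),
        dtype=object,
    )
    v_b = np.array([V_GENES[k] for k in rng.choice(len(V_GENES), size=n, p=v_blood)],
                   dtype=object)
    j_b = np.array([J_GENES[k] for k in rng.choice(len(J_GENES), size=n)], dtype=object)

    shared_mask = ~restricted
    shared_w = p[shared_mask]
    if config.detection_limit_mode:
        shared_mask = np.ones_like(restricted)
        shared_w = np.where(restricted, p * config.detection_limit_factor, p)[shared_mask]
    shared_w = shared_w / shared_w.sum()
    gamma = config.shared_blood_fraction
    blood_w = np.concatenate([(1 - gamma) * q, gamma * shared_w])
    blood_w = blood_w / blood_w.sum()
    blood_counts = rng.multinomial(config.depth_reads, blood_w)
    blood_table = pd.DataFrame(
        {
            "v_gene": np.concatenate([v_b, v[shared_mask]]),
            "cdr3_aa": np.concatenate([cdr3_b, cdr3[shared_mask]]),
            "j_gene": np.concatenate([j_b, j[shared_mask]]),
            "umi_count": blood_counts,
        }
    )

    muscle = RepertoireSample(f"{subject_id}_M", subject_id, Compartment.MUSCLE,
                              muscle_table[muscle_table["umi_count"] > 0])
    blood = RepertoireSample(f"{subject_id}_B", subject_id, Compartment.BLOOD,
                             blood_table[blood_table["umi_count"] > 0])

    model_freq_blood = np.zeros(len(p))
    model_freq_blood[shared_mask if not config.detection_limit_mode else slice(None)] = (
        gamma * shared_w / blood_w.sum()
    )
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "v_gene": v,
            "cdr3_aa": cdr3,
            "j_gene": j,
            "origin": "muscle",
            "restricted": restricted,
            "public": public,
            "model_freq_muscle": p,
            "model_freq_blood": model_freq_blood,
            "dominant_model": p >= config.dominance_pct / 100.0,
        }
    )
    blood_truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "v_gene": v_b,
            "cdr3_aa": cdr3_b,
            "j_gene": j_b,
            "origin": "blood_private",
            "restricted": False,
            "public": False,
            "model_freq_muscle": 0.0,
            "model_freq_blood": (1 - gamma) * q,
            "dominant_model": False,
        }
    )
    return [muscle, blood], pd.concat([truth, blood_truth], ignore_index=True), gini_muscle


def analytic_target_r(config: Optional[CohortConfig] = None, covariate: str = "ck") -> float:
    """Population Pearson r between the muscle-model Gini and a marker.

    The marker is linear in the generating-model Gini with Gaussian
    noise, and the Gini is a deterministic function of the muscle skew
    shape, itself uniform around its default. The population r is
    ``b*sd(G) / sqrt(b^2 var(G) + sigma^2)``, with ``var(G)`` evaluated
    numerically over the shape distribution.
    """
    config = config or CohortConfig()
    s_grid = np.linspace(
        config.expansion_shape_muscle - config.muscle_shape_jitter,
        config.expansion_shape_muscle + config.muscle_shape_jitter,
        201,
    )
    g = np.array([diversity.gini_index(power_law_freqs(config.clones_per_sample, s))
                  for s in s_grid])
    var_g = float(np.var(g))
    if covariate == "ck":
        b, sd = config.ck_gini_slope, config.ck_noise_sd
    elif covariate == "mmt":
        b, sd = config.mmt_gini_slope, config.mmt_noise_sd
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    return b * np.sqrt(var_g) / np.sqrt(b * b * var_g + sd * sd)


def analytic_profile(freqs: np.ndarray) -> "dict[str, float]":
    """Gini/Shannon/Simpson of an infinite-depth generating frequency vector."""
    return {
        "gini": diversity.gini_index(freqs),
        "shannon": diversity.shannon_entropy(freqs),
        "simpson": diversity.simpson_index(freqs),
    }


def truth_recovery_report(
    truth: CohortTruth,
    classifications: Sequence,
    profiles: Optional[pd.DataFrame] = None,
) -> "dict[str, float]":
    """Score pipeline outputs against the planted truth.

    Restriction labels: sensitivity and specificity of the measured
    muscle-restricted/shared calls (over dominant muscle clones observed
    in the subsampled muscle repertoires) against the planted restriction
    flags. Diversity: mean bias of each measured muscle metric relative
    to the analytic value of the generating frequency vector.
    """
    known = {c.subject_id for c in classifications}
    truth_subjects = set(truth.clones.loc[truth.clones["origin"] == "muscle", "subject_id"])
    missing = {c for c in known if c not in truth_subjects}
    if missing:
        raise ValueError(f"classifications for unknown subjects: {sorted(missing)}")
    tp = fn = tn = fp = 0
    for cls in classifications:
        t = truth.clones
        t = t[(t["subject_id"] == cls.subject_id) & (t["origin"] == "muscle")]
        t = t.set_index(["v_gene", "cdr3_aa", "j_gene"])
        measured = cls.table[cls.table["dominant_muscle"]]
        labels = measured["label"]
        planted = t.loc[t.index.intersection(measured.index), "restricted"]
        for key, is_restricted in planted.items():
            lab = labels.loc[key]
            if is_restricted:
                tp += lab == "muscle_restricted"
                fn += lab != "muscle_restricted"
            else:
                tn += lab == "shared"
                fp += lab != "shared"
    report = {
        "restriction_sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "restriction_specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "n_dominant_truth_restricted": tp + fn,
        "n_dominant_truth_shared": tn + fp,
    }
    if profiles is not None:
        biases = {"gini": [], "shannon": [], "simpson": []}
        grouped = truth.clones[truth.clones["origin"] == "muscle"].groupby("subject_id")
        for _, row in profiles[profiles["compartment"] == "muscle"].iterrows():
            model = grouped.get_group(row["subject_id"])["model_freq_muscle"].to_numpy()
            ana = analytic_profile(model)
            for m in biases:
                biases[m].append(row[m] - ana[m])
        for m, vals in biases.items():
            report[f"{m}_bias_muscle"] = float(np.mean(vals)) if vals else float("nan")
    return report


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
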