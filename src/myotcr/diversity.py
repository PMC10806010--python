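"""Fixed-depth subsampling and clonality/diversity statistics.

All samples are normalised to a common sequencing depth (default 10,000
UMI reads) by sampling reads without replacement, then clone frequencies
are expressed as percentages of the subsampled total. Three statistics
summarise the frequency distribution:

* **Gini index** — inequality of clone frequencies; 0 when all clones
  are equally abundant, approaching 1 when a single clone carries all
  reads. A measure of overall clonal expansion.
* **Shannon entropy** — ``H = -sum f_i ln f_i`` (nats); diversity with
  emphasis on the high-frequency part of the repertoire.
* **Simpson index** (Gini–Simpson form) — ``D = 1 - sum f_i^2``; the
  probability that two random reads come from different clones, more
  sensitive to the low-frequency tail. Larger = more diverse for both.

Clones at or above the dominance cutoff (default 0.5% of reads) are
*dominant*; the *impact* of a clone (or clone set) is its (cumulative)
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import RepertoireSample

log = logging.getLogger(__name__)

DEFAULT_DEPTH = 10_000
DEFAULT_DOMINANCE_PCT = 0.5


class SubsampleDepthError(ValueError):
    """Sample has fewer reads than the requested subsampling depth."""


@dataclass(frozen=True)
class DiversityProfile:
    """Per-sample diversity/clonality summary."""

    sample_id: str
    subject_id: str
    compartment: str
    gini: float
    shannon: float
    simpson: float
    n_clones_observed: int
    n_dominant: int
    dominant_impact_pct: float


def subsample_reads(
    sample: RepertoireSample,
    depth: int = DEFAULT_DEPTH,
    seed: Optional[int] = None,
    keep_all_if_shallow: bool = False,
) -> RepertoireSample:
    """Randomly select ``depth`` reads from a sample, without replacement.

    Individual UMI reads are sampled, which makes the per-clone subsampled
    counts a multivariate-hypergeometric draw over clones. Clones drawn to
    zero are removed. Deterministic for a fixed ``seed``.

    Raises
    ------
    SubsampleDepthError
        If the sample holds fewer than ``depth`` reads and
        ``keep_all_if_shallow`` is off. With the fallback on, the sample
        is returned unchanged (flagged, logged) instead.
    """
    if sample.subsampled:
        raise ValueError(f"sample {sample.sample_id} is already subsampled")
    total = sample.total_reads
    if total < depth:
        if keep_all_if_shallow:
            log.warning(
                "sample %s has %d < %d reads; keeping all reads (no subsampling)",
                sample.sample_id,
                total,
                depth,
            )
            return sample.replace_counts(sample.counts(), subsampled=True, subsample_seed=seed)
        raise SubsampleDepthError(
            f"sample {sample.sample_id}: {total} reads < requested depth {depth}"
        )
    if total == depth:
        return sample.replace_counts(sample.counts(), subsampled=True, subsample_seed=seed)
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(sample.counts(), depth)
    return sample.replace_counts(new_counts, subsampled=True, subsample_seed=seed)


def clone_frequencies(
    sample: RepertoireSample,
    dominance_pct: float = DEFAULT_DOMINANCE_PCT,
) -> pd.DataFrame:
    """Per-clone frequency (% of total UMIs) and dominance flag.

    Returns the sample's clone table with added columns ``frequency_pct``
    (summing to 100) and ``is_dominant`` (frequency >= ``dominance_pct``).
    """
    total = sample.total_reads
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id} has no reads")
    out = sample.table.copy()
    out["frequency_pct"] = out["umi_count"].to_numpy(dtype=float) * (100.0 / total)
    out["is_dominant"] = out["frequency_pct"] >= dominance_pct
    return out


def _proportions(frequencies: np.ndarray) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("need a non-empty 1-d vector of frequencies")
    if (f < 0).any():
        raise ValueError("frequencies must be nonnegative")
    total = f.sum()
    if total <= 0:
        raise ValueError("frequencies sum to zero")
    return f / total


def gini_index(frequencies: np.ndarray, normalized: bool = False) -> float:
    """Gini index of a clone-frequency (or count) vector.

    Mean-absolute-difference form ``G = sum_ij |f_i - f_j| / (2 n sum f)``,
    computed via the sorted-vector identity in O(n log n). Scale-invariant;
    ranges over [0, 1 - 1/n]. With ``normalized=True`` the value is
    multiplied by n/(n-1) so that one clone holding everything scores
    exactly 1 at finite n.
    """
    p = np.sort(_proportions(frequencies))
    n = p.size
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    g = float(2.0 * np.sum(i * p) / n - (n + 1) / n)
    if normalized:
        g *= n / (n - 1)
    # clamp tiny negative rounding residue at perfect evenness
    return 0.0 if abs(g) < 1e-15 else g


def shannon_entropy(frequencies: np.ndarray, base: Optional[float] = None) -> float:
    """Shannon entropy ``-sum f ln f`` of clone proportions (nats by default)."""
    p = _proportions(frequencies)
    p = p[p > 0]
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        h /= float(np.log(base))
    return max(h, 0.0)


def simpson_index(frequencies: np.ndarray, variant: str = "gini_simpson") -> float:
    """Simpson diversity of clone proportions.

    ``gini_simpson`` (default): ``1 - sum f^2``, in [0, 1), larger = more
    diverse. ``inverse``: ``1 / sum f^2``.
    """
    p = _proportions(frequencies)
    s = float(np.sum(p * p))
    if variant == "gini_simpson":
        return 1.0 - s
    if variant == "inverse":
        return 1.0 / s
    raise ValueError(f"unknown Simpson variant {variant!r}")


def diversity_profile(
    sample: RepertoireSample,
    dominance_pct: float = DEFAULT_DOMINANCE_PCT,
) -> DiversityProfile:
    """Bundle Gini/Shannon/Simpson with dominance counts for one sample."""
    freqs = clone_frequencies(sample, dominance_pct)
    f = freqs["frequency_pct"].to_numpy()
    dom = freqs["is_dominant"].to_numpy()
    return DiversityProfile(
        sample_id=sample.sample_id,
        subject_id=sample.subject_id,
        compartment=sample.compartment.value,
        gini=gini_index(f),
        shannon=shannon_entropy(f),
        simpson=simpson_index(f),
        n_clones_observed=len(freqs),
        n_dominant=int(dom.sum()),
        dominant_impact_pct=float(f[dom].sum()),
    )


def profile_frame(profiles: "list[DiversityProfile]") -> pd.DataFrame:
    """Stack per-sample profiles into the per-sample metrics table."""
    return pd.DataFrame([p.__dict__ for p in profiles])
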