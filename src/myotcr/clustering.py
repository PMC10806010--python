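"""Grouping of related clones by CDR3 amino-acid Hamming distance.

Related clones are found by computing all pairwise Hamming distances
between CDR3 amino-acid sequences, estimating a density over the
distance distribution — which is typically bimodal: a low mode of
genuinely related sequences and a high mode of unrelated ones — and
cutting at the valley between the two modes. The cut is floored at 3
amino acids. Clones closer than the threshold are joined by an edge and
clusters are the connected components of the resulting graph.

Unequal-length CDR3 pairs have no Hamming distance; by default they get
infinite distance and never share an edge (an edit-distance mode is
available via ``unequal="levenshtein"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

THRESHOLD_FLOOR = 3
GRID_STEP = 0.01
#: a valley must dip to below this fraction of the lower flanking peak for
#: the distance distribution to count as genuinely bimodal
MAX_VALLEY_DEPTH_RATIO = 0.8


def hamming_matrix(cdr3_list: Sequence[str], unequal: str = "inf") -> np.ndarray:
    """Pairwise distance matrix over CDR3 amino-acid sequences.

    Equal-length pairs get the Hamming distance (count of mismatching
    positions). Unequal-length pairs get ``inf`` under the default policy,
    or the Levenshtein edit distance with ``unequal="levenshtein"``.
    """
    n = len(cdr3_list)
    if n == 0:
        raise ValueError("empty sequence list")
    lengths = np.array([len(s) for s in cdr3_list])
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    # vectorised per equal-length block
    for length in np.unique(lengths):
        idx = np.flatnonzero(lengths == length)
        if idx.size < 2:
            continue
        arr = np.frombuffer(
            "".join(cdr3_list[i] for i in idx).encode("ascii"), dtype=np.uint8
        ).reshape(idx.size, length)
        block = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        d[np.ix_(idx, idx)] = block
    if unequal == "levenshtein":
        import edlib

        for i in range(n):
            for j in range(i + 1, n):
                if lengths[i] != lengths[j]:
                    ed = edlib.align(cdr3_list[i], cdr3_list[j], task="distance")
                    d[i, j] = d[j, i] = ed["editDistance"]
    elif unequal != "inf":
        raise ValueError(f"unknown unequal-length policy {unequal!r}")
    return d


@dataclass(frozen=True)
class ThresholdEstimate:
    """Dynamic clustering threshold derived from the distance density."""

    sample_id: str
    threshold: int
    mode: str  # bimodal_valley | floor_applied | unimodal_fallback
    valley_position: Optional[float] = None
    grid: np.ndarray = field(default=None, repr=False, compare=False)
    density: np.ndarray = field(default=None, repr=False, compare=False)


def _finite_upper_triangle(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(m.shape[0], 1)
    d = m[iu]
    return d[np.isfinite(d)]


def dynamic_threshold(
    matrix: np.ndarray,
    sample_id: str = "",
    bandwidth: Optional[float] = None,
    floor: int = THRESHOLD_FLOOR,
    grid_step: float = GRID_STEP,
) -> ThresholdEstimate:
    """Estimate the per-sample clustering threshold from a distance matrix.

    A Gaussian kernel density (Silverman bandwidth unless overridden) is
    evaluated on a fine grid over the finite pairwise distances. The two
    highest local maxima are located; the grid position of the density
    minimum strictly between them is the valley, rounded half-up to an
    integer and floored at ``floor``. With fewer than two local maxima the
    distribution is treated as unimodal and the floor is returned.

    A valley only counts when it dips to below
    ``MAX_VALLEY_DEPTH_RATIO`` of the lower flanking peak: CDR3 pools mix
    several sequence lengths, whose per-length distance modes produce
    shallow ripples in the density that are not the related/unrelated
    bimodality this threshold looks for. Shallow-valley distributions are
    treated as unimodal.
    """
    d = _finite_upper_triangle(matrix)
    if d.size == 0:
        raise ValueError("no finite pairwise distances; nothing to threshold")
    if d.size < 2 or np.ptp(d) == 0:
        return ThresholdEstimate(sample_id, floor, "unimodal_fallback")
    kde = gaussian_kde(d, bw_method=bandwidth if bandwidth is not None else "silverman")
    grid = np.arange(0.0, d.max() + grid_step, grid_step)
    density = kde(grid)
    maxima = argrelextrema(density, np.greater_equal, order=1)[0]
    # drop plateau duplicates and grid endpoints
    maxima = maxima[(maxima > 0) & (maxima < len(grid) - 1)]
    maxima = maxima[np.concatenate(([True], np.diff(maxima) > 1))]
    if maxima.size < 2:
        return ThresholdEstimate(sample_id, floor, "unimodal_fallback", None, grid, density)
    top2 = np.sort(maxima[np.argsort(density[maxima])[-2:]])
    lo, hi = int(top2[0]), int(top2[1])
    if hi - lo < 2:
        return ThresholdEstimate(sample_id, floor, "unimodal_fallback", None, grid, density)
    inner = slice(lo + 1, hi)
    valley_density = float(density[inner].min())
    if valley_density > MAX_VALLEY_DEPTH_RATIO * min(density[lo], density[hi]):
        return ThresholdEstimate(sample_id, floor, "unimodal_fallback", None, grid, density)
    valley = float(grid[inner][np.argmin(density[inner])])
    rounded = int(np.floor(valley + 0.5))  # round half-up
    if rounded >= floor:
        return ThresholdEstimate(sample_id, rounded, "bimodal_valley", valley, grid, density)
    return ThresholdEstimate(sample_id, floor, "floor_applied", valley, grid, density)


@dataclass
class ClusterResult:
    """Partition of clones into single-linkage clusters at a threshold."""

    labels: np.ndarray  # cluster id per input sequence
    threshold: int
    edge_rule: str
    edges: pd.DataFrame  # columns: i, j, distance

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def members(self) -> "dict[int, list[int]]":
        out: "dict[int, list[int]]" = {}
        for i, c in enumerate(self.labels):
            out.setdefault(int(c), []).append(i)
        return out


def cluster_clones(
    matrix: np.ndarray,
    threshold: int,
    edge_rule: str = "lt",
) -> ClusterResult:
    """Group clones whose distance is below the threshold.

    An edge joins every pair with finite distance ``< threshold``
    (``edge_rule="le"`` switches to ``<=``); clusters are the connected
    components, i.e. single-linkage groups, so relatedness is transitive.
    Cluster ids are assigned in order of each cluster's smallest member
    index, making the labelling invariant to input order semantics.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if edge_rule == "lt":
        adj = m < threshold
    elif edge_rule == "le":
        adj = m <= threshold
    else:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    np.fill_diagonal(adj, False)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    labels = np.empty(n, dtype=np.int64)
    comps = sorted(nx.connected_components(g), key=min)
    for cid, comp in enumerate(comps):
        for node in comp:
            labels[node] = cid
    edges = pd.DataFrame({"i": ii, "j": jj, "distance": m[ii, jj]})
    return ClusterResult(labels=labels, threshold=threshold, edge_rule=edge_rule, edges=edges)


def cross_patient_sharing(
    cdr3_list: Sequence[str],
    subject_ids: Sequence[str],
    threshold: Optional[int] = None,
    edge_rule: str = "lt",
) -> "tuple[pd.DataFrame, pd.DataFrame, ClusterResult]":
    """Cluster pooled dominant muscle clones and summarise patient sharing.

    Pools clones across patients, computes one cohort-level dynamic
    threshold (unless given), clusters, and reports per-cluster member and
    patient counts plus the edge list for network rendering.

    Returns ``(cluster_table, edge_table, result)`` where ``cluster_table``
    has one row per cluster (size, n_patients, patient ids) and
    ``edge_table`` one row per graph edge with the sequences joined.
    """
    if len(cdr3_list) != len(subject_ids):
        raise ValueError("cdr3_list and subject_ids must align")
    matrix = hamming_matrix(cdr3_list)
    if threshold is None:
        est = dynamic_threshold(matrix, sample_id="pooled")
        threshold = est.threshold
    result = cluster_clones(matrix, threshold, edge_rule=edge_rule)
    subj = np.asarray(subject_ids, dtype=object)
    rows = []
    for cid, idx in result.members().items():
        patients = sorted(set(subj[idx]))
        rows.append(
            {
                "cluster_id": cid,
                "size": len(idx),
                "n_patients": len(patients),
                "patient_ids": ",".join(patients),
                "cdr3s": ",".join(cdr3_list[i] for i in idx),
            }
        )
    clusters = pd.DataFrame(rows).sort_values("cluster_id").reset_index(drop=True)
    edges = result.edges.assign(
        cdr3_i=[cdr3_list[i] for i in result.edges["i"]],
        cdr3_j=[cdr3_list[j] for j in result.edges["j"]],
        subject_i=[subj[i] for i in result.edges["i"]],
        subject_j=[subj[j] for j in result.edges["j"]],
    )
    return clusters, edges, result
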