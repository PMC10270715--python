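"""Construction of weighted structural networks from raw connectome matrices.

A raw connectome pairs a symmetric streamline-count matrix with a co-indexed
matrix of mean radial diffusivity (RD, mm^2/s) per reconstructed connection.
Edges recovered with fewer than ``ns_thr`` streamlines are considered
unreliable and excluded; surviving edges are weighted with the inverse mean
RD (so weight carries units of s/mm^2, higher = putatively better myelinated
/ denser axonal connection).  Because the count threshold is arbitrary, it is
calibrated against target cohort-mean sparsities and the analysis is swept
over a descending range of targets.

"Sparsity" here follows the connectomics usage of the source analyses: the
fraction of possible edges *retained* after thresholding (i.e. connection
density), averaged over participants.  It therefore falls as the threshold
rises.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawConnectome",
    "WeightedNetwork",
    "SweepPlan",
    "read_connectome",
    "build_weighted",
    "network_sparsity",
    "calibrate_threshold",
    "plan_sweep",
    "detect_isolated",
    "DEFAULT_SPARSITY_TARGETS",
]

#: Default sweep: cohort-mean sparsity targets 0.85 down to 0.25 in steps of 0.05.
DEFAULT_SPARSITY_TARGETS: tuple[float, ...] = tuple(
    np.round(np.arange(0.85, 0.249, -0.05), 2)
)

_RD_SYM_RTOL = 1e-12  # relative tolerance for float noise in RD symmetry


def _check_square_symmetric(a: np.ndarray, what: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} matrix must be square, got shape {a.shape}")
    if a.shape[0] < 2:
        raise ValueError(f"{what} matrix must have at least 2 nodes")


@dataclasses.dataclass
class RawConnectome:
    """One participant's streamline-count and mean-RD matrices on one atlas.

    Invariants enforced on construction: both matrices square and co-indexed,
    counts non-negative integers with exact symmetry and zero diagonal, and RD
    finite-positive exactly where the count is positive.  RD asymmetry within
    a tiny relative tolerance (float noise from upstream writers) is
    symmetrized by averaging; anything larger is rejected.
    """

    participant_id: str
    atlas_name: str
    node_labels: tuple[str, ...]
    counts: np.ndarray
    mean_rd: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        rd = np.asarray(self.mean_rd, dtype=float)
        _check_square_symmetric(counts, "counts")
        _check_square_symmetric(rd, "mean RD")
        n = counts.shape[0]
        if len(self.node_labels) != n or rd.shape[0] != n:
            raise ValueError("node labels and matrices must be co-indexed")
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("streamline counts must be integers")
            counts = as_int
        if (counts < 0).any():
            raise ValueError("streamline counts must be non-negative")
        if np.diagonal(counts).any():
            raise ValueError("counts diagonal must be zero (no self-connections)")
        if not np.array_equal(counts, counts.T):
            raise ValueError("counts matrix must be exactly symmetric")
        scale = np.abs(rd) + np.abs(rd.T)
        asym = np.abs(rd - rd.T)
        if np.any(asym > _RD_SYM_RTOL * np.maximum(scale, np.finfo(float).tiny)):
            raise ValueError("mean RD matrix asymmetric beyond tolerance")
        rd = 0.5 * (rd + rd.T)
        np.fill_diagonal(rd, 0.0)
        connected = counts > 0
        if not np.all(np.isfinite(rd[connected]) & (rd[connected] > 0)):
            raise ValueError(
                f"{self.participant_id}: RD must be finite and positive "
                "wherever the streamline count is positive"
            )
        if np.any(rd[~connected] != 0):
            raise ValueError(
                f"{self.participant_id}: RD defined where streamline count is zero"
            )
        self.counts = counts
        self.mean_rd = rd
        self.node_labels = tuple(self.node_labels)

    @property
    def n_nodes(self) -> int:
        return self.counts.shape[0]


@dataclasses.dataclass(frozen=True)
class WeightedNetwork:
    """Thresholded network with edge weight = 1 / mean RD (0 = absent edge)."""

    node_labels: tuple[str, ...]
    weights: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        _check_square_symmetric(w, "weights")
        if (w < 0).any() or not np.allclose(w, w.T, rtol=0, atol=0):
            raise ValueError("weights must be symmetric and non-negative")
        if np.diagonal(w).any():
            raise ValueError("weights diagonal must be zero")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclasses.dataclass(frozen=True)
class SweepPlan:
    """Calibrated count thresholds for a descending ladder of sparsity targets."""

    target_sparsities: tuple[float, ...]
    calibrated_thresholds: Mapping[float, int]

    def __post_init__(self) -> None:
        thr = [self.calibrated_thresholds[t] for t in self.target_sparsities]
        if any(b < a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be non-decreasing as targets fall")


def _read_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return frame


def read_connectome(
    counts_file: str | Path,
    rd_file: str | Path,
    participant_id: str | None = None,
    atlas_name: str = "",
) -> RawConnectome:
    """Read a labelled count/RD TSV pair into a validated :class:`RawConnectome`.

    Labels must match between the two files in the same order; permutations are
    an error, never silently reordered.
    """
    counts = _read_matrix(counts_file)
    rd = _read_matrix(rd_file)
    if list(counts.index) != list(rd.index):
        raise ValueError(
            f"node labels differ between {counts_file} and {rd_file} "
            "(same set in a different order is rejected, not reordered)"
        )
    if participant_id is None:
        participant_id = Path(counts_file).name.replace("_counts.tsv", "")
    return RawConnectome(
        participant_id=participant_id,
        atlas_name=atlas_name,
        node_labels=tuple(counts.index),
        counts=counts.to_numpy(),
        mean_rd=rd.to_numpy(dtype=float),
    )


def build_weighted(raw: RawConnectome, ns_thr: int) -> WeightedNetwork:
    """Apply the streamline-count threshold and weight edges by 1/RD.

    An edge is retained iff its count is positive and at least ``ns_thr``
    ("fewer than ``ns_thr`` streamlines" excluded); thresholds 0 and 1 are
    therefore equivalent.  The retained edge set depends only on the counts,
    never on the RD values.
    """
    if ns_thr < 0:
        raise ValueError("ns_thr must be non-negative")
    keep = raw.counts >= max(int(ns_thr), 1)
    weights = np.zeros_like(raw.mean_rd)
    weights[keep] = 1.0 / raw.mean_rd[keep]
    return WeightedNetwork(raw.node_labels, weights, int(ns_thr))


def network_sparsity(net: WeightedNetwork) -> float:
    """Fraction of possible edges present (connection density)."""
    n = net.n_nodes
    iu = np.triu_indices(n, 1)
    return float(np.count_nonzero(net.weights[iu]) / (n * (n - 1) / 2))


def _pooled_survival(cohort: Sequence[RawConnectome]) -> tuple[np.ndarray, int]:
    """Pooled count histogram survival S[t] = #edges with count >= t, t=0..max+1."""
    n = cohort[0].n_nodes
    iu = np.triu_indices(n, 1)
    pooled = np.concatenate([c.counts[iu] for c in cohort])
    pooled = pooled[pooled > 0]
    if pooled.size == 0:
        return np.zeros(2, dtype=np.int64), len(iu[0])
    hist = np.bincount(pooled)
    surv = np.concatenate([np.cumsum(hist[::-1])[::-1], [0]])
    surv[0] = surv[1]  # count>=0 edges and count>=1 edges coincide (0 = non-edge)
    return surv, len(iu[0])


def calibrate_threshold(cohort: Sequence[RawConnectome], target: float) -> int:
    """Smallest integer threshold whose cohort-mean sparsity is <= ``target``.

    The mean is taken over per-participant sparsities (all participants share
    the atlas, so this equals a pooled edge count over the cohort).  Returns 0
    when the unthresholded cohort is already at or below the target.
    """
    if not 0 < target <= 1:
        raise ValueError("target sparsity must be in (0, 1]")
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if len({c.n_nodes for c in cohort}) != 1:
        raise ValueError("cohort mixes atlas dimensions")
    surv, m_pairs = _pooled_survival(cohort)
    budget = target * len(cohort) * m_pairs
    below = np.flatnonzero(surv <= budget)
    return int(below[0])


def plan_sweep(
    cohort: Sequence[RawConnectome],
    targets: Iterable[float] = DEFAULT_SPARSITY_TARGETS,
) -> SweepPlan:
    """Calibrate one shared threshold per sparsity target, 0.85 down to 0.25."""
    targets = tuple(float(t) for t in targets)
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate sparsity targets")
    if any(b >= a for a, b in zip(targets, targets[1:])):
        raise ValueError("sparsity targets must be strictly decreasing")
    thresholds = {t: calibrate_threshold(cohort, t) for t in targets}
    return SweepPlan(targets, thresholds)


def detect_isolated(net: WeightedNetwork, node_subset: Iterable[str]) -> set[str]:
    """Members of ``node_subset`` with no retained edge to another member."""
    subset = list(node_subset)
    index = {lab: i for i, lab in enumerate(net.node_labels)}
    unknown = [lab for lab in subset if lab not in index]
    if unknown:
        raise KeyError(f"unknown node labels: {unknown}")
    idx = np.array([index[lab] for lab in subset], dtype=int)
    block = net.weights[np.ix_(idx, idx)]
    isolated = block.sum(axis=1) == 0
    return {lab for lab, iso in zip(subset, isolated) if iso}
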