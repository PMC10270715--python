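"""Node-level and subnetwork-mean graph metrics for weighted networks.

Three metrics are computed per node: degree (count of retained edges —
independent of the edge weighting), strength (sum of incident 1/RD weights)
and the weighted clustering coefficient.  The weighted clustering follows
the Onnela geometric-mean convention on max-normalized weights, the form
used by the Brain Connectivity Toolbox for undirected weighted graphs:

    c_i = (2 / (k_i (k_i - 1))) * sum_{j<h} (w'_ij w'_ih w'_jh)^(1/3),
    w' = w / max(w),   c_i = 0 when k_i < 2.

All core functions operate on stacked weight arrays of shape (..., n, n),
so a whole cohort's subnetworks can be processed in one vectorized call.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import SubnetworkSpec, extract_subnetwork
from .build import WeightedNetwork

__all__ = [
    "degrees",
    "strengths",
    "clustering_coefficients",
    "node_degree",
    "node_strength",
    "node_clustering",
    "subnetwork_means",
    "MetricTable",
    "compute_metric_table",
    "ScreenResult",
    "collinearity_screen",
    "METRIC_NAMES",
    "METRIC_PRIORITY",
]

METRIC_NAMES = ("degree", "strength", "clustering")
#: Retention priority for the collinearity screen (first kept preferentially).
METRIC_PRIORITY = ("degree", "clustering", "strength")


def degrees(weights: np.ndarray) -> np.ndarray:
    """Edge counts per node; shape (..., n). Weight values are irrelevant."""
    w = np.asarray(weights)
    return np.count_nonzero(w, axis=-1)


def strengths(weights: np.ndarray) -> np.ndarray:
    """Sum of incident edge weights per node; shape (..., n)."""
    return np.asarray(weights, dtype=float).sum(axis=-1)


def clustering_coefficients(weights: np.ndarray, variant: str = "onnela") -> np.ndarray:
    """Weighted clustering per node; shape (..., n); values in [0, 1].

    ``variant="onnela"`` (default): geometric-mean triangle intensity on
    max-normalized weights.  ``variant="binary"`` ignores the weight values.
    A graph with no edges has an undefined weight maximum; its nodes are all
    assigned 0.
    """
    w = np.asarray(weights, dtype=float)
    if variant == "binary":
        w = (w > 0).astype(float)
        mx = np.ones(w.shape[:-2])
    elif variant == "onnela":
        mx = w.max(axis=(-2, -1))
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    k = np.count_nonzero(w, axis=-1)
    safe_mx = np.where(mx > 0, mx, 1.0)
    what = np.cbrt(w / safe_mx[..., None, None])
    cyc3 = np.einsum("...ij,...jh,...hi->...i", what, what, what)
    denom = k * (k - 1)
    return np.where(denom > 0, cyc3 / np.where(denom > 0, denom, 1), 0.0)


def _as_series(values: np.ndarray, net: WeightedNetwork, name: str) -> pd.Series:
    return pd.Series(values, index=list(net.node_labels), name=name)


def node_degree(net: WeightedNetwork) -> pd.Series:
    return _as_series(degrees(net.weights), net, "degree")


def node_strength(net: WeightedNetwork) -> pd.Series:
    return _as_series(strengths(net.weights), net, "strength")


def node_clustering(net: WeightedNetwork, variant: str = "onnela") -> pd.Series:
    return _as_series(clustering_coefficients(net.weights, variant), net, "clustering")


def subnetwork_means(
    vectors: Mapping[str, pd.Series], include_isolated: bool = True
) -> dict[str, float]:
    """Arithmetic means of node metric vectors over the subnetwork's nodes.

    Isolated nodes remain members and contribute their zeros unless
    ``include_isolated=False``, in which case nodes with zero degree are left
    out of every mean (degree vector required to identify them).
    """
    vectors = dict(vectors)
    index = None
    for v in vectors.values():
        if index is None:
            index = v.index
        elif not index.equals(v.index):
            raise ValueError("metric vectors must share one node set")
    if index is None or len(index) == 0:
        raise ValueError("empty node set")
    mask = np.ones(len(index), dtype=bool)
    if not include_isolated:
        if "degree" not in vectors:
            raise ValueError("excluding isolated nodes requires a degree vector")
        mask = vectors["degree"].to_numpy() > 0
        if not mask.any():
            mask[:] = True  # fully isolated subnetwork: report the zeros
    return {f"mean_{k}": float(v.to_numpy()[mask].mean()) for k, v in vectors.items()}


@dataclasses.dataclass
class MetricTable:
    """Per participant x subnetwork x threshold metric means and node vectors.

    ``means`` columns: participant, subnetwork, threshold, mean_degree,
    mean_clustering, mean_strength.  ``nodes`` is tidy:
    participant, subnetwork, threshold, metric, node, value.
    """

    means: pd.DataFrame
    nodes: pd.DataFrame

    def cell(self, metric: str, subnetwork: str) -> pd.Series:
        """Mean-metric values for one (metric, subnetwork), indexed by participant."""
        sub = self.means[self.means["subnetwork"] == subnetwork]
        return sub.set_index("participant")[f"mean_{metric}"]


def compute_metric_table(
    nets: Mapping[str, WeightedNetwork],
    subnets: Mapping[str, SubnetworkSpec],
    include_isolated: bool = True,
    clustering_variant: str = "onnela",
) -> MetricTable:
    """Metrics for every participant on every induced subnetwork.

    All networks must share node labels and threshold (one sweep point).
    Metrics are computed on the induced subgraphs, so degree counts only
    intra-subnetwork edges.
    """
    nets = dict(nets)
    if not nets:
        raise ValueError("no networks supplied")
    first = next(iter(nets.values()))
    labels = first.node_labels
    threshold = first.threshold_used
    for pid, net in nets.items():
        if net.node_labels != labels or net.threshold_used != threshold:
            raise ValueError(f"network {pid!r} differs in labels or threshold")
    pids = list(nets)
    stacked = np.stack([nets[p].weights for p in pids])
    pos = {lab: i for i, lab in enumerate(labels)}
    mean_rows, node_rows = [], []
    for sname, spec in subnets.items():
        idx = np.array([pos[m] for m in spec.members], dtype=int)
        sub = stacked[:, idx][:, :, idx]
        vals = {
            "degree": degrees(sub).astype(float),
            "strength": strengths(sub),
            "clustering": clustering_coefficients(sub, clustering_variant),
        }
        keep = np.ones(vals["degree"].shape, dtype=bool)
        if not include_isolated:
            keep = vals["degree"] > 0
            keep[~keep.any(axis=1)] = True
        denom = keep.sum(axis=1)
        for i, pid in enumerate(pids):
            row = {"participant": pid, "subnetwork": sname, "threshold": threshold}
            for mname in METRIC_NAMES:
                row[f"mean_{mname}"] = float(vals[mname][i][keep[i]].sum() / denom[i])
            mean_rows.append(row)
        for mname in METRIC_NAMES:
            flat = vals[mname]
            node_rows.append(
                pd.DataFrame(
                    {
                        "participant": np.repeat(pids, len(idx)),
                        "subnetwork": sname,
                        "threshold": threshold,
                        "metric": mname,
                        "node": np.tile(spec.members, len(pids)),
                        "value": flat.ravel(),
                    }
                )
            )
    means = pd.DataFrame(mean_rows)[
        ["participant", "subnetwork", "threshold",
         "mean_degree", "mean_clustering", "mean_strength"]
    ]
    return MetricTable(means=means, nodes=pd.concat(node_rows, ignore_index=True))


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    correlations: pd.DataFrame  # (subnetwork, threshold) x metric-pair |r|
    flags: tuple[str, ...] = ()


def collinearity_screen(
    table: MetricTable | pd.DataFrame, cutoff: float = 0.85
) -> ScreenResult:
    """Drop metrics nearly collinear with a retained, higher-priority metric.

    Within each (subnetwork, threshold) cell the Pearson correlations among
    the three mean metrics are computed across participants.  Walking the
    fixed priority degree > clustering > strength, a metric is dropped when
    its |r| against some retained metric exceeds ``cutoff`` in the majority
    of cells; a zero-variance cell casts the same vote and is flagged.
    """
    means = table.means if isinstance(table, MetricTable) else table
    if means["participant"].nunique() < 3:
        raise ValueError("collinearity screen needs at least 3 participants")
    cols = {m: f"mean_{m}" for m in METRIC_PRIORITY}
    records, flags = [], []
    groups = list(means.groupby(["subnetwork", "threshold"], sort=True))
    for (sname, thr), grp in groups:
        for a, b in itertools.combinations(METRIC_PRIORITY, 2):
            a, b = sorted((a, b))
            xa, xb = grp[cols[a]].to_numpy(), grp[cols[b]].to_numpy()
            if xa.std() == 0 or xb.std() == 0:
                r = np.nan
                flags.append(f"{sname}@{thr}: zero variance in {a if xa.std() == 0 else b}")
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            records.append(
                {"subnetwork": sname, "threshold": thr,
                 "metric_a": a, "metric_b": b, "abs_r": abs(r) if np.isfinite(r) else np.nan}
            )
    corr = pd.DataFrame(records)
    retained: list[str] = []
    dropped: list[str] = []
    n_cells = len(groups)
    for metric in METRIC_PRIORITY:
        votes = 0
        for kept in retained:
            a, b = sorted([metric, kept])
            sel = corr[(corr["metric_a"] == a) & (corr["metric_b"] == b)]["abs_r"]
            votes = max(votes, int(((sel > cutoff) | sel.isna()).sum()))
        if retained and votes > n_cells / 2:
            dropped.append(metric)
        else:
            retained.append(metric)
    return ScreenResult(tuple(retained), tuple(dropped), corr, tuple(flags))
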