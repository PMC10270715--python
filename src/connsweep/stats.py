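"""Association statistics: schizotypy vs network metrics.

The statistical recipe mirrors the published analysis: partial Pearson
correlations between the schizotypy total and each subnetwork-mean metric,
correcting for age and sex; single-pass outlier exclusion of data points
whose Cook's distance (from the OLS of the metric on intercept + schizotypy
+ age + sex) exceeds four times the mean Cook's distance; Benjamini–Hochberg
FDR over the family of all retained metrics x all subnetworks at each
threshold; persistence classification across the threshold sweep; and an
uncorrected node-level driver analysis for the persistent pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import SubnetworkSpec
from .build import WeightedNetwork, detect_isolated
from .metrics import MetricTable

__all__ = [
    "demographic_screen",
    "partial_corr",
    "cooks_distance",
    "ExclusionRecord",
    "exclude_outliers",
    "fdr_bh",
    "CorrelationResult",
    "run_association",
    "results_to_frame",
    "summarize_persistence",
    "node_driver_analysis",
]


def demographic_screen(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among schizotypy total, age and sex.

    Sex enters as its 0/1 code, making the sex correlations point-biserial.
    Intended to verify that the covariates are not correlated with the score.
    """
    if len(cohort) < 4:
        raise ValueError("demographic screen needs at least 4 participants")
    rows = []
    for a, b in (("spq_total", "age"), ("spq_total", "sex"), ("age", "sex")):
        x = cohort[a].to_numpy(dtype=float)
        y = cohort[b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"zero variance in {a if x.std() == 0 else b}")
        r, p = sps.pearsonr(x, y)
        rows.append({"var_a": a, "var_b": b, "r": float(r), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)


def _covariate_matrix(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariate rows must match observation count")
    return c


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized against [1, covariates] by least squares;
    the Pearson correlation of the residuals is returned with a two-sided p
    value from the t transform on n - 2 - k degrees of freedom (k covariates).
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    c = _covariate_matrix(covariates, n)
    k = c.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    res = np.column_stack([x, y]) - design @ coef
    rx, ry = res[:, 0], res[:, 1]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    # relative floor: residuals at rounding level of the input scale are zero
    tol_x = 1e-10 * max(np.abs(x).max(), 1e-300) * np.sqrt(n)
    tol_y = 1e-10 * max(np.abs(y).max(), 1e-300) * np.sqrt(n)
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p


def cooks_distance(response: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Cook's influence D_i for an OLS fit of ``response`` on ``design``.

    D_i = e_i^2 h_ii / (p s^2 (1 - h_ii)^2) with hat diagonal h, p design
    columns and residual mean square s^2.  Exact leverage points (h_ii = 1)
    are flagged with +inf.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", q, q)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ coef
    s2 = (e @ e) / (n - p)
    if s2 == 0:
        return np.where(h >= 1 - 1e-10, np.inf, 0.0)
    d = np.empty(n)
    leverage = h >= 1 - 1e-10
    d[leverage] = np.inf
    ok = ~leverage
    d[ok] = (e[ok] ** 2 / (p * s2)) * h[ok] / (1.0 - h[ok]) ** 2
    return d


@dataclasses.dataclass(frozen=True)
class ExclusionRecord:
    excluded: tuple[int, ...]  # positional indices
    cooks: np.ndarray
    cutoff: float
    annotations: dict = dataclasses.field(default_factory=dict)


def exclude_outliers(
    values: np.ndarray,
    schizotypy: np.ndarray,
    covariates: np.ndarray | None,
    multiplier: float = 4.0,
) -> tuple[np.ndarray, ExclusionRecord]:
    """Single-pass exclusion of points with Cook's D above ``multiplier`` x mean.

    The regression is the association model itself: metric on intercept +
    schizotypy + covariates.  The mean is taken over finite distances, so an
    exact leverage point (infinite D) is excluded whenever the cutoff is
    finite.  Returns (kept positional indices, record).
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(schizotypy, dtype=float)
    n = y.size
    c = _covariate_matrix(covariates, n)
    design = np.column_stack([np.ones(n), x, c])
    d = cooks_distance(y, design)
    finite = np.isfinite(d)
    cutoff = multiplier * d[finite].mean() if finite.any() else np.inf
    excluded = np.flatnonzero(d > cutoff)
    kept = np.setdiff1d(np.arange(n), excluded)
    if kept.size <= c.shape[1] + 3:
        raise ValueError(
            f"outlier exclusion would leave only {kept.size} points"
        )
    return kept, ExclusionRecord(tuple(int(i) for i in excluded), d, float(cutoff))


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclasses.dataclass
class CorrelationResult:
    """One metric x subnetwork x threshold partial-correlation test."""

    metric_name: str
    subnetwork: str
    threshold: int
    n_used: int
    r_partial: float
    p_value: float
    q_value: float
    excluded_ids: tuple[str, ...]
    cooks_distances: dict[str, float]
    sparsity_target: float | None = None
    degenerate: bool = False
    annotations: dict = dataclasses.field(default_factory=dict)


def _cohort_frame(cohort) -> pd.DataFrame:
    frame = cohort.copy()
    if "id" in frame.columns:
        frame = frame.set_index("id")
    for col in ("spq_total", "age", "sex"):
        if col not in frame.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    return frame


def run_association(
    table: MetricTable,
    cohort: pd.DataFrame,
    metrics: Sequence[str] = ("degree", "clustering"),
    subnetworks: Sequence[str] | None = None,
    cooks_multiplier: float = 4.0,
    fdr_alpha: float = 0.05,
    sparsity_target: float | None = None,
    nets: Mapping[str, WeightedNetwork] | None = None,
    subnets: Mapping[str, SubnetworkSpec] | None = None,
) -> list[CorrelationResult]:
    """Outlier exclusion + partial correlation + BH-FDR for one sweep point.

    The FDR family is all ``metrics`` x all subnetworks at this threshold
    (default 2 x 4 = 8 tests).  Degenerate cells (zero variance) are reported
    as NaN records, never silently dropped, and do not enter the BH family.
    When the thresholded networks are supplied, excluded participants are
    annotated with their isolated subnetwork nodes and with whether their
    metric value is a >3 SD degree-distribution outlier.
    """
    frame = _cohort_frame(cohort)
    if subnetworks is None:
        subnetworks = list(dict.fromkeys(table.means["subnetwork"]))
    threshold = int(table.means["threshold"].iloc[0])
    x = frame["spq_total"].to_numpy(dtype=float)
    cov = frame[["age", "sex"]].to_numpy(dtype=float)
    ids = np.array(frame.index.astype(str))

    results: list[CorrelationResult] = []
    for sname in subnetworks:
        for metric in metrics:
            y = table.cell(metric, sname).reindex(frame.index)
            if y.isna().any():
                raise ValueError(f"metric table missing participants for {sname}/{metric}")
            yv = y.to_numpy(dtype=float)
            base = dict(
                metric_name=metric,
                subnetwork=sname,
                threshold=threshold,
                sparsity_target=sparsity_target,
            )
            try:
                kept, record = exclude_outliers(yv, x, cov, cooks_multiplier)
                r, p = partial_corr(x[kept], yv[kept], cov[kept])
            except ValueError as err:
                results.append(
                    CorrelationResult(
                        **base,
                        n_used=0,
                        r_partial=np.nan,
                        p_value=np.nan,
                        q_value=np.nan,
                        excluded_ids=(),
                        cooks_distances={},
                        degenerate=True,
                        annotations={"error": str(err)},
                    )
                )
                continue
            excluded_ids = tuple(ids[list(record.excluded)])
            annotations: dict = {}
            for pos, pid in zip(record.excluded, excluded_ids):
                note = {}
                if nets is not None and subnets is not None and pid in nets:
                    note["isolated_nodes"] = sorted(
                        detect_isolated(nets[pid], subnets[sname].members)
                    )
                spread = yv.std()
                if spread > 0:
                    note["metric_z"] = float((yv[pos] - yv.mean()) / spread)
                annotations[pid] = note
            results.append(
                CorrelationResult(
                    **base,
                    n_used=int(kept.size),
                    r_partial=r,
                    p_value=p,
                    q_value=np.nan,
                    excluded_ids=excluded_ids,
                    cooks_distances=dict(zip(ids, record.cooks.tolist())),
                    annotations=annotations,
                )
            )
    valid = [res for res in results if not res.degenerate]
    if valid:
        q = fdr_bh([res.p_value for res in valid])
        for res, qi in zip(valid, q):
            res.q_value = float(qi)
    return results


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    rows = [
        {
            "metric": r.metric_name,
            "subnetwork": r.subnetwork,
            "threshold": r.threshold,
            "sparsity_target": r.sparsity_target,
            "n_used": r.n_used,
            "r": r.r_partial,
            "p": r.p_value,
            "q": r.q_value,
            "excluded_ids": ";".join(r.excluded_ids),
            "degenerate": r.degenerate,
        }
        for r in results
    ]
    return pd.DataFrame(rows).sort_values(
        ["subnetwork", "metric", "threshold"], kind="mergesort", ignore_index=True
    )


def summarize_persistence(
    results: Sequence[CorrelationResult],
    persistence_fraction: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each metric x subnetwork pair across the sweep.

    robust: FDR-significant (q < alpha) at >= ``persistence_fraction`` of sweep
    points; nominal: p < alpha at >= that fraction without meeting robust;
    none otherwise.  Degenerate points count as non-significant.  Both
    fractions are always reported so the classification is auditable.
    """
    frame = pd.DataFrame(
        {
            "metric": [r.metric_name for r in results],
            "subnetwork": [r.subnetwork for r in results],
            "point": [
                r.sparsity_target if r.sparsity_target is not None else r.threshold
                for r in results
            ],
            "sig_q": [(not r.degenerate) and r.q_value < alpha for r in results],
            "sig_p": [(not r.degenerate) and r.p_value < alpha for r in results],
        }
    )
    rows = []
    for (metric, sname), grp in frame.groupby(["metric", "subnetwork"], sort=True):
        n_points = grp["point"].nunique()
        if n_points < 2:
            raise ValueError("persistence needs results from at least 2 sweep points")
        frac_q = grp["sig_q"].mean()
        frac_p = grp["sig_p"].mean()
        if frac_q >= persistence_fraction:
            cls = "robust"
        elif frac_p >= persistence_fraction:
            cls = "nominal"
        else:
            cls = "none"
        rows.append(
            {
                "metric": metric,
                "subnetwork": sname,
                "n_points": n_points,
                "frac_fdr_significant": float(frac_q),
                "frac_nominal_significant": float(frac_p),
                "persistence_class": cls,
            }
        )
    return pd.DataFrame(rows)


def node_driver_analysis(
    table: MetricTable,
    cohort: pd.DataFrame,
    subnet_results: Sequence[CorrelationResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Node-level partial correlations for flagged metric x subnetwork pairs.

    Each node of a flagged subnetwork is tested with the same covariates and
    the exclusion set established at the subnetwork level; a node drives the
    subnetwork correlation when its uncorrected p value is below ``alpha``.
    """
    frame = _cohort_frame(cohort)
    rows = []
    for res in subnet_results:
        nodes = table.nodes[
            (table.nodes["metric"] == res.metric_name)
            & (table.nodes["subnetwork"] == res.subnetwork)
        ]
        if nodes.empty:
            raise ValueError(
                f"no node vectors for {res.subnetwork}/{res.metric_name}"
            )
        wide = nodes.pivot(index="participant", columns="node", values="value")
        wide = wide.reindex(frame.index)
        keep = ~frame.index.astype(str).isin(res.excluded_ids)
        x = frame.loc[keep, "spq_total"].to_numpy(dtype=float)
        cov = frame.loc[keep, ["age", "sex"]].to_numpy(dtype=float)
        for node in nodes["node"].unique():
            yv = wide.loc[keep, node].to_numpy(dtype=float)
            try:
                r, p = partial_corr(x, yv, cov)
                degenerate = False
            except ValueError:
                r, p, degenerate = np.nan, np.nan, True
            rows.append(
                {
                    "subnetwork": res.subnetwork,
                    "metric": res.metric_name,
                    "threshold": res.threshold,
                    "node": node,
                    "r_partial": r,
                    "p_value": p,
                    "is_driver": bool((not degenerate) and p < alpha),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["subnetwork", "metric", "node"], kind="mergesort", ignore_index=True
    )
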