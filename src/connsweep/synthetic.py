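"""Synthetic schizotypy cohorts with a known planted connectivity effect.

No raw cohort accompanies the published analysis, so every downstream stage
is exercised against simulated data with a recoverable ground truth.  The
generator emulates three things:

* SPQ-like schizotypy totals — sums of nine subscale scores, each subscale a
  binomial over its 0/1 items, so every total lies in [0, 74];
* demographics (age, sex) drawn independently of the score;
* per-participant connectomes — symmetric streamline-count matrices
  (negative-binomial counts on Bernoulli edges) and co-indexed mean radial
  diffusivity matrices (truncated normal, mm^2/s), where a configurable
  effect shifts edge probability (``beta_edge``, logit per SD of schizotypy)
  and/or RD (``beta_weight``, mm^2/s per SD; negative = stronger 1/RD weight)
  on all edges incident to a chosen set of target nodes.

``beta_weight = beta_edge = 0`` is the exact global null.  A single integer
seed governs every draw through one documented stream-splitting scheme
(`numpy.random.SeedSequence(seed).spawn`: child 0 = participants, child 1 =
connectomes), so identical configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import load_atlas
from .build import RawConnectome

__all__ = [
    "InstrumentError",
    "SubscaleSpec",
    "SPQ_SUBSCALES",
    "Participant",
    "ConnectomeTemplate",
    "EffectSpec",
    "SynthConfig",
    "max_schizotypy_total",
    "gen_participants",
    "gen_template",
    "gen_connectomes",
    "effect_for_partial_r",
    "participants_to_frame",
    "write_cohort",
]


class InstrumentError(ValueError):
    """Raised when a strict nine-subscale instrument is mis-specified."""


@dataclasses.dataclass(frozen=True)
class SubscaleSpec:
    name: str
    n_items: int

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValueError("subscale item count must be positive")


#: The nine SPQ subscales with their published item counts (sum = 74).
SPQ_SUBSCALES: tuple[SubscaleSpec, ...] = (
    SubscaleSpec("ideas_of_reference", 9),
    SubscaleSpec("excessive_social_anxiety", 8),
    SubscaleSpec("odd_beliefs_magical_thinking", 7),
    SubscaleSpec("unusual_perceptual_experiences", 9),
    SubscaleSpec("no_close_friends", 9),
    SubscaleSpec("odd_eccentric_behaviour", 7),
    SubscaleSpec("constricted_affect", 8),
    SubscaleSpec("odd_speech", 9),
    SubscaleSpec("suspiciousness", 8),
)


def max_schizotypy_total(subscales: Sequence[SubscaleSpec] = SPQ_SUBSCALES) -> int:
    """Maximum attainable total score (74 for the default instrument)."""
    return sum(s.n_items for s in subscales)


@dataclasses.dataclass(frozen=True)
class Participant:
    id: str
    subscale_scores: tuple[int, ...]
    schizotypy_total: int
    age: float
    sex: int  # 0 = male, 1 = female

    def __post_init__(self) -> None:
        if self.schizotypy_total != sum(self.subscale_scores):
            raise ValueError("schizotypy total must equal the subscale sum")
        if any(s < 0 for s in self.subscale_scores):
            raise ValueError("subscale scores must be non-negative")
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0 (male) or 1 (female)")


@dataclasses.dataclass(frozen=True)
class ConnectomeTemplate:
    """Statistical stand-in for tractogram-derived matrices on one atlas."""

    atlas_name: str
    n_nodes: int
    edge_prob: np.ndarray
    count_mean: np.ndarray
    rd_mean: float = 0.6e-3  # mm^2/s
    rd_sd: float = 0.05e-3
    count_dispersion: float = 8.0

    def __post_init__(self) -> None:
        for name in ("edge_prob", "count_mean"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"{name} must be {self.n_nodes}x{self.n_nodes}")
            if not np.array_equal(a, a.T) or np.diagonal(a).any():
                raise ValueError(f"{name} must be symmetric with zero diagonal")
            object.__setattr__(self, name, a)
        if np.any(self.edge_prob < 0) or np.any(self.edge_prob > 1):
            raise ValueError("edge_prob entries must lie in [0, 1]")
        off = ~np.eye(self.n_nodes, dtype=bool)
        if np.any(self.count_mean[off] <= 0):
            raise ValueError("count_mean must be positive off the diagonal")
        if self.rd_mean <= 0 or self.rd_sd <= 0 or self.count_dispersion <= 0:
            raise ValueError("rd_mean, rd_sd and count_dispersion must be positive")


@dataclasses.dataclass(frozen=True)
class EffectSpec:
    """Planted schizotypy effect on edges incident to the target nodes."""

    target_nodes: frozenset[str] = frozenset()
    beta_weight: float = 0.0  # RD shift (mm^2/s) per SD of schizotypy
    beta_edge: float = 0.0  # logit edge-probability shift per SD of schizotypy

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_nodes", frozenset(self.target_nodes))


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    n_participants: int
    seed: int
    template: ConnectomeTemplate
    effect: EffectSpec = EffectSpec()
    age_range: tuple[float, float] = (18.0, 55.0)
    female_fraction: float = 0.657
    subscale_response_prob: float = 0.168
    subscales: tuple[SubscaleSpec, ...] = SPQ_SUBSCALES
    strict_instrument: bool = True

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")
        if not 0 <= self.subscale_response_prob <= 1:
            raise ValueError("subscale_response_prob must lie in [0, 1]")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError("age_range must be (min, max)")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(2)
    return {
        "participants": np.random.default_rng(children[0]),
        "connectomes": np.random.default_rng(children[1]),
    }


def gen_participants(config: SynthConfig) -> list[Participant]:
    """Draw the cohort: per-item binomial subscales, uniform age, Bernoulli sex.

    Score, age and sex are mutually independent by construction.
    """
    if config.strict_instrument and len(config.subscales) != 9:
        raise InstrumentError(
            f"strict instrument requires nine subscales, got {len(config.subscales)}"
        )
    rng = _streams(config.seed)["participants"]
    n = config.n_participants
    n_items = np.array([s.n_items for s in config.subscales])
    scores = rng.binomial(n_items, config.subscale_response_prob, size=(n, len(n_items)))
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sexes = (rng.random(n) < config.female_fraction).astype(int)
    return [
        Participant(
            id=f"sub-{i + 1:04d}",
            subscale_scores=tuple(int(s) for s in scores[i]),
            schizotypy_total=int(scores[i].sum()),
            age=float(ages[i]),
            sex=int(sexes[i]),
        )
        for i in range(n)
    ]


def gen_template(
    atlas_name: str,
    n_nodes: int,
    density: float,
    seed: int,
    count_scale: float = 40.0,
    count_sigma: float = 0.6,
    rd_mean: float = 0.6e-3,
    rd_sd: float = 0.05e-3,
    count_dispersion: float = 8.0,
) -> ConnectomeTemplate:
    """Template with uniform edge probability ``density`` and log-normally
    heterogeneous expected streamline counts (so count thresholds are graded)."""
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edge_prob = np.full((n_nodes, n_nodes), float(density))
    np.fill_diagonal(edge_prob, 0.0)
    raw = rng.lognormal(mean=np.log(count_scale), sigma=count_sigma, size=(n_nodes, n_nodes))
    count_mean = np.maximum(np.triu(raw, 1) + np.triu(raw, 1).T, 2.0)
    np.fill_diagonal(count_mean, 0.0)
    return ConnectomeTemplate(
        atlas_name=atlas_name,
        n_nodes=n_nodes,
        edge_prob=edge_prob,
        count_mean=count_mean,
        rd_mean=rd_mean,
        rd_sd=rd_sd,
        count_dispersion=count_dispersion,
    )


def _standardized_totals(participants: Sequence[Participant]) -> np.ndarray:
    totals = np.array([p.schizotypy_total for p in participants], dtype=float)
    sd = totals.std()
    if sd == 0:
        return np.zeros_like(totals)
    return (totals - totals.mean()) / sd


def gen_connectomes(
    participants: Sequence[Participant], config: SynthConfig
) -> list[RawConnectome]:
    """Draw one count/RD matrix pair per participant.

    Edge existence is Bernoulli with the template probability, logit-shifted by
    ``beta_edge * z`` on target-incident edges (z = within-cohort standardized
    schizotypy total).  Counts on existing edges are 1 + negative binomial
    (gamma–Poisson mixture) with the template mean; RD is normal around
    ``rd_mean + beta_weight * z`` on target-incident edges, truncated strictly
    positive, and defined exactly where the count is positive.
    """
    tpl = config.template
    registry = load_atlas(tpl.atlas_name)
    if registry.n_nodes != tpl.n_nodes:
        raise ValueError(
            f"template has {tpl.n_nodes} nodes but atlas "
            f"{tpl.atlas_name!r} registers {registry.n_nodes}"
        )
    labels = registry.node_labels
    unknown = config.effect.target_nodes - set(labels)
    if unknown:
        raise ValueError(f"effect target nodes not in atlas: {sorted(unknown)}")
    rng = _streams(config.seed)["connectomes"]
    n = len(participants)
    n_nodes = tpl.n_nodes
    iu = np.triu_indices(n_nodes, 1)
    m = iu[0].size
    target_idx = registry.index_of(sorted(config.effect.target_nodes))
    is_target = np.zeros(n_nodes, dtype=bool)
    is_target[target_idx] = True
    incident = is_target[iu[0]] | is_target[iu[1]]

    z = _standardized_totals(participants)
    p0 = tpl.edge_prob[iu]
    with np.errstate(divide="ignore"):
        logit0 = np.log(p0) - np.log1p(-p0)  # +-inf at p0 in {0, 1} stays put
    shift = np.where(incident, config.effect.beta_edge, 0.0)
    logit = logit0[None, :] + shift[None, :] * z[:, None]
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(-logit))
    prob = np.where(np.isinf(logit0)[None, :].repeat(n, 0), p0[None, :].repeat(n, 0), prob)

    exists = rng.random((n, m)) < prob
    # negative-binomial counts via gamma-Poisson; +1 so an existing edge never has count 0
    mu = np.maximum(tpl.count_mean[iu] - 1.0, 1e-9)
    k = tpl.count_dispersion
    lam = rng.gamma(shape=k, scale=mu[None, :] / k, size=(n, m))
    counts = 1 + rng.poisson(lam)

    rd_mu = tpl.rd_mean + np.where(incident, config.effect.beta_weight, 0.0)[None, :] * z[:, None]
    rd = rng.normal(rd_mu, tpl.rd_sd)
    for _ in range(100):  # truncate strictly positive by redrawing
        bad = rd <= 0
        if not bad.any():
            break
        rd[bad] = rng.normal(rd_mu[bad], tpl.rd_sd)
    else:
        raise RuntimeError("RD truncation failed; rd_sd too large relative to rd_mean")

    counts = np.where(exists, counts, 0)
    rd = np.where(exists, rd, 0.0)

    out = []
    for i, part in enumerate(participants):
        cmat = np.zeros((n_nodes, n_nodes), dtype=np.int64)
        rmat = np.zeros((n_nodes, n_nodes))
        cmat[iu] = counts[i]
        rmat[iu] = rd[i]
        cmat += cmat.T
        rmat += rmat.T
        out.append(
            RawConnectome(
                participant_id=part.id,
                atlas_name=tpl.atlas_name,
                node_labels=labels,
                counts=cmat,
                mean_rd=rmat,
            )
        )
    return out


def effect_for_partial_r(
    template: ConnectomeTemplate,
    members: Sequence[str],
    target_nodes: Sequence[str],
    target_r: float,
    beta_weight: float = 0.0,
) -> EffectSpec:
    """Closed-form ``beta_edge`` giving a chosen true partial correlation.

    Linearizes the logistic edge model around the template probabilities: with
    affected intra-subnetwork pairs A (those incident to a target node) and all
    intra-subnetwork pairs E, the correlation between the standardized score z
    and the subnetwork mean degree is approximately

        r = beta * c / sqrt(v + (beta * c)^2),   c = sum_A p(1-p),  v = sum_E p(1-p)

    solved for beta.  The approximation is accurate for the unthresholded
    network (count thresholding attenuates it); derived before any data are
    seen, purely from the template.
    """
    registry = load_atlas(template.atlas_name)
    members = list(members)
    targets = set(target_nodes)
    if not targets <= set(members):
        raise ValueError("target nodes must belong to the subnetwork members")
    idx = registry.index_of(members)
    is_target = np.isin(members, sorted(targets))
    p = template.edge_prob[np.ix_(idx, idx)]
    pq = p * (1 - p)
    tri = np.triu_indices(len(members), 1)
    affected = is_target[tri[0]] | is_target[tri[1]]
    c = pq[tri][affected].sum()
    v = pq[tri].sum()
    if c == 0:
        raise ValueError("no variable affected edges; cannot plant the effect")
    beta = target_r * np.sqrt(v) / (c * np.sqrt(1 - target_r**2))
    return EffectSpec(frozenset(targets), beta_weight=beta_weight, beta_edge=float(beta))


def participants_to_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    """Cohort table with columns ``id,spq_total,sub1..sub9,age,sex``."""
    n_sub = len(participants[0].subscale_scores) if participants else 9
    rows = {
        "id": [p.id for p in participants],
        "spq_total": [p.schizotypy_total for p in participants],
    }
    for j in range(n_sub):
        rows[f"sub{j + 1}"] = [p.subscale_scores[j] for p in participants]
    rows["age"] = [p.age for p in participants]
    rows["sex"] = [p.sex for p in participants]
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: SynthConfig | None) -> dict | None:
    if config is None:
        return None
    tpl = config.template
    return {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "age_range": list(config.age_range),
        "female_fraction": config.female_fraction,
        "subscale_response_prob": config.subscale_response_prob,
        "subscales": [[s.name, s.n_items] for s in config.subscales],
        "template": {
            "atlas_name": tpl.atlas_name,
            "n_nodes": tpl.n_nodes,
            "rd_mean": tpl.rd_mean,
            "rd_sd": tpl.rd_sd,
            "count_dispersion": tpl.count_dispersion,
            "edge_prob_sha256": hashlib.sha256(tpl.edge_prob.tobytes()).hexdigest(),
            "count_mean_sha256": hashlib.sha256(tpl.count_mean.tobytes()).hexdigest(),
        },
        "effect": {
            "target_nodes": sorted(config.effect.target_nodes),
            "beta_weight": config.effect.beta_weight,
            "beta_edge": config.effect.beta_edge,
        },
    }


def write_cohort(
    participants: Sequence[Participant],
    connectomes: Sequence[RawConnectome],
    directory: str | Path,
    config: SynthConfig | None = None,
) -> dict:
    """Write cohort table, per-participant matrix TSV pairs and a JSON manifest.

    Matrix files carry node labels as header row and column and round-trip
    exactly through :func:`connsweep.build.read_connectome` (floats written
    with 17 significant digits).  Returns the manifest dict.
    """
    if len(participants) != len(connectomes):
        raise ValueError("participants and connectomes differ in length")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort_path = directory / "cohort.csv"
    participants_to_frame(participants).to_csv(cohort_path, index=False)
    files = {"cohort.csv": _sha256(cohort_path)}
    for part, conn in zip(participants, connectomes):
        if part.id != conn.participant_id:
            raise ValueError("participant order mismatch with connectomes")
        labels = list(conn.node_labels)
        cpath = directory / f"{part.id}_counts.tsv"
        rpath = directory / f"{part.id}_rd.tsv"
        pd.DataFrame(conn.counts, index=labels, columns=labels).to_csv(cpath, sep="\t")
        pd.DataFrame(conn.mean_rd, index=labels, columns=labels).to_csv(
            rpath, sep="\t", float_format="%.17g"
        )
        files[cpath.name] = _sha256(cpath)
        files[rpath.name] = _sha256(rpath)
    manifest = {
        "n_participants": len(participants),
        "atlas_name": connectomes[0].atlas_name if connectomes else None,
        "seed": config.seed if config is not None else None,
        "config": _config_echo(config),
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
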