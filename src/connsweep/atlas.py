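"""Atlas node registries and resting-state subnetwork definitions.

Two published parcellations are shipped as packaged label lists: the AAL
atlas (90 cerebral areas) and the Desikan–Killiany atlas (84 areas, of which
82 are cerebral and 2 cerebellar), plus a 20-node toy registry used by the
simulation studies.  Four systems are analysed — auditory, sensorimotor,
visual and default mode.  Their default node memberships are reconstructions
(see ``data/subnetworks_default.yaml``) and can be overridden by user config.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .build import WeightedNetwork

__all__ = [
    "AtlasRegistry",
    "SubnetworkSpec",
    "SUBNETWORK_NAMES",
    "load_atlas",
    "load_subnetworks",
    "extract_subnetwork",
]

SUBNETWORK_NAMES = ("default_mode", "sensorimotor", "visual", "auditory")

_BUILTIN_FILES = {
    "aal": "aal.tsv",
    "desikan_killiany": "desikan_killiany.tsv",
    "toy20": "toy20.tsv",
}
_BUILTIN_COUNTS = {"aal": (90, 90), "desikan_killiany": (84, 82), "toy20": (20, 20)}


@dataclasses.dataclass(frozen=True)
class AtlasRegistry:
    """Immutable ordered node registry with cerebrum/cerebellum division."""

    name: str
    node_labels: tuple[str, ...]
    cerebrum_labels: frozenset[str]
    cerebellum_labels: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.node_labels)) != len(self.node_labels):
            raise ValueError(f"atlas {self.name!r}: duplicate node labels")
        known = self.cerebrum_labels | self.cerebellum_labels
        if known != set(self.node_labels):
            raise ValueError(f"atlas {self.name!r}: division does not cover labels")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.node_labels)}
        return np.array([pos[lab] for lab in labels], dtype=int)


@dataclasses.dataclass(frozen=True)
class SubnetworkSpec:
    """Named system with its member node labels (kept in atlas order)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"subnetwork {self.name!r} needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"subnetwork {self.name!r}: duplicate members")


def _parse_registry(name: str, text: str) -> AtlasRegistry:
    labels, cerebrum, cerebellum = [], [], []
    for line in text.strip().splitlines():
        parts = line.rstrip("\n").split("\t")
        label = parts[0].strip()
        division = parts[1].strip() if len(parts) > 1 else "cerebrum"
        labels.append(label)
        (cerebellum if division == "cerebellum" else cerebrum).append(label)
    return AtlasRegistry(name, tuple(labels), frozenset(cerebrum), frozenset(cerebellum))


def load_atlas(name_or_path: str | Path) -> AtlasRegistry:
    """Load a built-in registry ("aal", "desikan_killiany", "toy20") or a TSV file.

    Custom files hold one node per line: ``label<TAB>division`` with division
    ``cerebrum`` (default) or ``cerebellum``.
    """
    key = str(name_or_path)
    if key in _BUILTIN_FILES:
        text = (
            resources.files("connsweep") / "data" / _BUILTIN_FILES[key]
        ).read_text()
        reg = _parse_registry(key, text)
        n_total, n_cerebral = _BUILTIN_COUNTS[key]
        assert reg.n_nodes == n_total and len(reg.cerebrum_labels) == n_cerebral
        return reg
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(f"unknown atlas {name_or_path!r}")
    return _parse_registry(path.stem, path.read_text())


def _default_subnetwork_config() -> dict:
    text = (resources.files("connsweep") / "data" / "subnetworks_default.yaml").read_text()
    return yaml.safe_load(text)


def load_subnetworks(
    atlas: AtlasRegistry,
    config: str | Path | Mapping[str, Iterable[str]] | None = None,
) -> dict[str, SubnetworkSpec]:
    """Resolve the four system definitions against an atlas.

    ``config`` may be a mapping ``subnetwork -> [labels]``, a YAML/JSON path of
    that shape, or None for the packaged defaults of the atlas.  Every member
    must exist in the atlas; the four canonical system names are required.
    """
    if config is None:
        defaults = _default_subnetwork_config()
        if atlas.name not in defaults:
            raise ValueError(
                f"no default subnetworks for atlas {atlas.name!r}; pass a config"
            )
        mapping = defaults[atlas.name]
    elif isinstance(config, (str, Path)):
        text = Path(config).read_text()
        mapping = (
            json.loads(text)
            if str(config).endswith(".json")
            else yaml.safe_load(text)
        )
        if atlas.name in mapping and isinstance(mapping[atlas.name], Mapping):
            mapping = mapping[atlas.name]
    else:
        mapping = config
    if set(mapping) != set(SUBNETWORK_NAMES):
        raise ValueError(
            f"subnetwork config must define exactly {SUBNETWORK_NAMES}, "
            f"got {sorted(mapping)}"
        )
    atlas_order = {lab: i for i, lab in enumerate(atlas.node_labels)}
    specs: dict[str, SubnetworkSpec] = {}
    for name in SUBNETWORK_NAMES:
        members = list(mapping[name])
        if not members:
            raise ValueError(f"subnetwork {name!r} is empty")
        unknown = [m for m in members if m not in atlas_order]
        if unknown:
            raise ValueError(
                f"subnetwork {name!r}: labels not in atlas {atlas.name!r}: {unknown}"
            )
        members = tuple(sorted(members, key=atlas_order.__getitem__))
        specs[name] = SubnetworkSpec(name, members)
    return specs


def extract_subnetwork(net: WeightedNetwork, spec: SubnetworkSpec) -> WeightedNetwork:
    """Induced subgraph on the spec's members; weights preserved bit-exactly."""
    index = {lab: i for i, lab in enumerate(net.node_labels)}
    missing = [m for m in spec.members if m not in index]
    if missing:
        raise KeyError(f"subnetwork {spec.name!r}: members missing from network: {missing}")
    idx = np.array([index[m] for m in spec.members], dtype=int)
    return WeightedNetwork(
        spec.members, net.weights[np.ix_(idx, idx)], net.threshold_used
    )
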