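"""Domain model for non-adherence trees (NATs).

A non-adherence tree is a fault tree whose top event is discontinuation of a
medication regimen (NA) and whose basic events are non-adherence factors
(NAFs) such as side effects or forgetfulness.  Intermediate nodes group
factors — in the bundled case study, into the five WHO adherence dimensions —
and are connected by Boolean gates (AND, OR, PAND).

Each basic node carries a leaf *rate model* describing its daily hazard:

``constant``
    a fixed per-day rate (the pooled WNAR of a factor);
``linear_decay``
    a rate that drops by a fixed fraction of its initial value per elapsed
    day, floored at zero (e.g. a knowledge gap that closes over the regimen);
``repairable``
    an up/down subsystem with an exponential time to failure and a fixed
    repair duration (medicine supply systems);
``age_stratified``
    per-age-band constant rates mixed by cohort weights.

Trees are read from and written to a small YAML/JSON schema; see
:func:`load_tree` / :func:`write_tree`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Union

import yaml

from .errors import TreeStructureError, TreeValidationError

__all__ = [
    "GateKind",
    "ConstantRate",
    "LinearDecayRate",
    "RepairableRate",
    "AgeBand",
    "AgeStratifiedRate",
    "RateModel",
    "NafNode",
    "NonAdherenceTree",
    "effective_rate",
    "load_tree",
    "write_tree",
]


class GateKind(str, Enum):
    """Boolean gate connecting a node to its children.

    AND and OR are symmetric in their children.  PAND (priority-AND) fires
    only when all children occur in the listed order, so child order is
    significant for PAND nodes only.
    """

    AND = "AND"
    OR = "OR"
    PAND = "PAND"


# --------------------------------------------------------------------------
# Leaf rate models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantRate:
    """Fixed hazard, in events per day."""

    rate: float
    form = "constant"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"constant rate must be >= 0, got {self.rate}")

    def scaled(self, factor: float) -> "ConstantRate":
        return ConstantRate(self.rate * factor)

    def to_dict(self) -> dict:
        return {"form": self.form, "rate": self.rate}


@dataclass(frozen=True)
class LinearDecayRate:
    """Hazard that decays linearly with elapsed whole days.

    On day ``d`` (counting from 0 at regimen start) the rate is
    ``initial_rate * (1 - decay_fraction_per_day * d)``, floored at zero.
    """

    initial_rate: float
    decay_fraction_per_day: float
    form = "linear_decay"

    def __post_init__(self) -> None:
        if self.initial_rate < 0:
            raise ValueError(f"initial_rate must be >= 0, got {self.initial_rate}")
        if not 0 <= self.decay_fraction_per_day <= 1:
            raise ValueError(
                "decay_fraction_per_day must be in [0, 1], "
                f"got {self.decay_fraction_per_day}"
            )

    def scaled(self, factor: float) -> "LinearDecayRate":
        return replace(self, initial_rate=self.initial_rate * factor)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "initial_rate": self.initial_rate,
            "decay_fraction_per_day": self.decay_fraction_per_day,
        }


@dataclass(frozen=True)
class RepairableRate:
    """Up/down subsystem: exponential failures, fixed repair duration.

    ``failure_rate`` is per day; ``mean_repair_time`` is in hours.  A
    repairable leaf does not reduce to a single hazard — the simulator
    tracks its availability explicitly.
    """

    failure_rate: float
    mean_repair_time: float  # hours
    form = "repairable"

    def __post_init__(self) -> None:
        if self.failure_rate < 0:
            raise ValueError(f"failure_rate must be >= 0, got {self.failure_rate}")
        if self.mean_repair_time <= 0:
            raise ValueError(
                f"mean_repair_time must be > 0 hours, got {self.mean_repair_time}"
            )

    def scaled(self, factor: float) -> "RepairableRate":
        return replace(self, failure_rate=self.failure_rate * factor)

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "failure_rate": self.failure_rate,
            "mean_repair_time": self.mean_repair_time,
        }


@dataclass(frozen=True)
class AgeBand:
    """One age band of a stratified rate: label, per-day rate, cohort weight."""

    label: str
    rate: float
    weight: float


@dataclass(frozen=True)
class AgeStratifiedRate:
    """Per-age-band constant hazards mixed by cohort weights.

    Weights must be non-negative and sum to 1 (within 1e-9).  The default
    cohort mix in the bundled fixtures is equal thirds.
    """

    bands: tuple[AgeBand, ...]
    form = "age_stratified"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("age_stratified requires at least one band")
        for b in self.bands:
            if b.rate < 0:
                raise ValueError(f"band {b.label!r} rate must be >= 0, got {b.rate}")
            if b.weight < 0:
                raise ValueError(f"band {b.label!r} weight must be >= 0, got {b.weight}")
        total = sum(b.weight for b in self.bands)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"band weights must sum to 1, got {total}")

    @property
    def mean_rate(self) -> float:
        """Population-averaged hazard, Σ weight_b × rate_b."""
        return sum(b.weight * b.rate for b in self.bands)

    def scaled(self, factor: float) -> "AgeStratifiedRate":
        return AgeStratifiedRate(
            tuple(replace(b, rate=b.rate * factor) for b in self.bands)
        )

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "bands": [
                {"label": b.label, "rate": b.rate, "weight": b.weight}
                for b in self.bands
            ],
        }


RateModel = Union[ConstantRate, LinearDecayRate, RepairableRate, AgeStratifiedRate]

_RATE_FORMS = {
    "constant": ConstantRate,
    "linear_decay": LinearDecayRate,
    "repairable": RepairableRate,
    "age_stratified": AgeStratifiedRate,
}


def rate_model_from_dict(spec: Mapping, node_id: str = "?") -> RateModel:
    """Build a rate model from its mapping form (the ``rate:`` YAML block)."""
    if "form" not in spec:
        raise TreeValidationError(f"node {node_id!r}: rate model is missing 'form'")
    form = spec["form"]
    params = {k: v for k, v in spec.items() if k != "form"}
    try:
        if form == "constant":
            return ConstantRate(rate=float(params.pop("rate")))
        if form == "linear_decay":
            return LinearDecayRate(
                initial_rate=float(params.pop("initial_rate")),
                decay_fraction_per_day=float(params.pop("decay_fraction_per_day")),
            )
        if form == "repairable":
            return RepairableRate(
                failure_rate=float(params.pop("failure_rate")),
                mean_repair_time=float(params.pop("mean_repair_time")),
            )
        if form == "age_stratified":
            bands = tuple(
                AgeBand(str(b["label"]), float(b["rate"]), float(b["weight"]))
                for b in params.pop("bands")
            )
            return AgeStratifiedRate(bands=bands)
    except (KeyError, TypeError, ValueError) as exc:
        raise TreeValidationError(f"node {node_id!r}: invalid rate model: {exc}") from exc
    raise TreeValidationError(f"node {node_id!r}: unknown rate form {form!r}")


def effective_rate(model: RateModel, day: float) -> float:
    """Hazard (per day) of a leaf rate model on elapsed day ``day``.

    ``day`` counts whole elapsed days from 0 at regimen start; day ``d``
    covers the interval [d, d+1), so dosing on Day 1 uses ``day=0``.

    Constant models return their rate; linear-decay models their floored
    decayed rate; age-stratified models the population-averaged hazard.
    Repairable models do **not** reduce to a single hazard (their effect
    depends on joint downtime windows, handled by the simulator's
    availability process): calling this on one returns the raw failure rate
    and emits a :class:`UserWarning`.
    """
    if day < 0:
        raise ValueError(f"day must be >= 0, got {day}")
    if isinstance(model, ConstantRate):
        return model.rate
    if isinstance(model, LinearDecayRate):
        return max(0.0, model.initial_rate * (1.0 - model.decay_fraction_per_day * day))
    if isinstance(model, AgeStratifiedRate):
        return model.mean_rate
    if isinstance(model, RepairableRate):
        warnings.warn(
            "effective_rate on a repairable model returns its raw failure rate; "
            "availability effects are only captured by the simulator",
            UserWarning,
            stacklevel=2,
        )
        return model.failure_rate
    raise TypeError(f"unknown rate model {model!r}")


# --------------------------------------------------------------------------
# Nodes and trees
# --------------------------------------------------------------------------

_NODE_KINDS = ("basic", "intermediate", "top")


@dataclass(frozen=True)
class NafNode:
    """One node of a non-adherence tree.

    Basic nodes are undecomposable factors: they have a rate model, no gate
    and no children.  Intermediate and top nodes have a gate and at least
    one child, and no rate model.
    """

    id: str
    label: str = ""
    kind: str = "basic"
    gate: GateKind | None = None
    children: tuple[str, ...] = ()
    rate_model: RateModel | None = None

    def __post_init__(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise TreeValidationError(f"node id must be a non-empty string, got {self.id!r}")
        if self.kind not in _NODE_KINDS:
            raise TreeValidationError(
                f"node {self.id!r}: kind must be one of {_NODE_KINDS}, got {self.kind!r}"
            )
        if self.kind == "basic":
            if self.children:
                raise TreeValidationError(f"basic node {self.id!r} must not have children")
            if self.gate is not None:
                raise TreeValidationError(f"basic node {self.id!r} must not have a gate")
            if self.rate_model is None:
                raise TreeValidationError(f"basic node {self.id!r} is missing a rate model")
        else:
            if not self.children:
                raise TreeValidationError(
                    f"{self.kind} node {self.id!r} must have at least one child"
                )
            if self.gate is None:
                raise TreeValidationError(f"{self.kind} node {self.id!r} is missing a gate")
            if self.rate_model is not None:
                raise TreeValidationError(
                    f"{self.kind} node {self.id!r} must not carry a rate model"
                )

    @property
    def is_basic(self) -> bool:
        return self.kind == "basic"


@dataclass(frozen=True)
class NonAdherenceTree:
    """A validated non-adherence tree.

    ``nodes`` maps id → node; ``top_id`` names the unique top event.  The
    id graph must be a proper tree: every non-top node has exactly one
    parent, all nodes are reachable from the top, and the basic nodes are
    exactly the leaves.
    """

    nodes: Mapping[str, NafNode]
    top_id: str
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", dict(self.nodes))
        self._validate()

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        for node_id, node in self.nodes.items():
            if node.id != node_id:
                raise TreeStructureError(
                    f"node map key {node_id!r} does not match node id {node.id!r}"
                )
        if self.top_id not in self.nodes:
            raise TreeStructureError(f"top id {self.top_id!r} is not a node")
        tops = [n.id for n in self.nodes.values() if n.kind == "top"]
        if tops != [self.top_id]:
            raise TreeStructureError(
                f"exactly one node must have kind='top' and match top_id; found {tops}"
            )

        parents: dict[str, str] = {}
        for node in self.nodes.values():
            if len(set(node.children)) != len(node.children):
                raise TreeStructureError(f"node {node.id!r} lists a child twice")
            for child in node.children:
                if child not in self.nodes:
                    raise TreeStructureError(
                        f"node {node.id!r} references missing child {child!r}"
                    )
                if child in parents:
                    raise TreeStructureError(
                        f"node {child!r} has multiple parents "
                        f"({parents[child]!r} and {node.id!r}); shared events are unsupported"
                    )
                parents[child] = node.id
        if self.top_id in parents:
            raise TreeStructureError(f"top node {self.top_id!r} must not have a parent")

        # reachability from the top; any shortfall means orphans or a cycle
        seen: set[str] = set()
        stack = [self.top_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise TreeStructureError(f"cycle detected at node {nid!r}")
            seen.add(nid)
            stack.extend(self.nodes[nid].children)
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise TreeStructureError(f"nodes unreachable from top: {orphans}")

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: str) -> NafNode:
        return self.nodes[node_id]

    @property
    def top(self) -> NafNode:
        return self.nodes[self.top_id]

    def basic_ids(self) -> tuple[str, ...]:
        """Ids of all basic (leaf) nodes, in depth-first order from the top."""
        out: list[str] = []

        def walk(nid: str) -> None:
            node = self.nodes[nid]
            if node.is_basic:
                out.append(nid)
            for c in node.children:
                walk(c)

        walk(self.top_id)
        return tuple(out)

    def parent_of(self, node_id: str) -> str | None:
        for node in self.nodes.values():
            if node_id in node.children:
                return node.id
        return None

    def dimension_of(self, basic_id: str) -> str:
        """The child-of-top ancestor grouping a basic factor.

        For the case-study tree this is the WHO adherence dimension; a basic
        node hanging directly under the top is its own dimension.
        """
        nid = basic_id
        while True:
            parent = self.parent_of(nid)
            if parent is None:
                return nid
            if parent == self.top_id:
                return nid
            nid = parent

    def iter_basic(self) -> Iterator[NafNode]:
        for nid in self.basic_ids():
            yield self.nodes[nid]

    def with_rate_models(self, updates: Mapping[str, RateModel]) -> "NonAdherenceTree":
        """A copy of the tree with the given basic nodes' rate models replaced."""
        new_nodes = dict(self.nodes)
        for nid, model in updates.items():
            node = self.nodes.get(nid)
            if node is None or not node.is_basic:
                raise KeyError(f"{nid!r} is not a basic node of this tree")
            new_nodes[nid] = replace(node, rate_model=model)
        return NonAdherenceTree(
            nodes=new_nodes, top_id=self.top_id, name=self.name,
            description=self.description,
        )


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def tree_from_dict(data: Mapping) -> NonAdherenceTree:
    """Build and validate a tree from the parsed YAML/JSON mapping."""
    if not isinstance(data, Mapping):
        raise TreeValidationError("tree document must be a mapping")
    for key in ("top", "nodes"):
        if key not in data:
            raise TreeValidationError(f"tree document is missing {key!r}")
    nodes: dict[str, NafNode] = {}
    for raw in data["nodes"]:
        nid = raw.get("id")
        if not nid:
            raise TreeValidationError("a node entry is missing 'id'")
        if nid in nodes:
            raise TreeStructureError(f"duplicate node id {nid!r}")
        gate = raw.get("gate")
        if gate is not None:
            try:
                gate = GateKind(gate)
            except ValueError as exc:
                raise TreeValidationError(f"node {nid!r}: unknown gate {gate!r}") from exc
        rate = raw.get("rate")
        nodes[nid] = NafNode(
            id=nid,
            label=raw.get("label", ""),
            kind=raw.get("kind", "basic"),
            gate=gate,
            children=tuple(raw.get("children", ()) or ()),
            rate_model=rate_model_from_dict(rate, nid) if rate is not None else None,
        )
    return NonAdherenceTree(
        nodes=nodes,
        top_id=data["top"],
        name=data.get("name", ""),
        description=data.get("description", ""),
    )


def tree_to_dict(tree: NonAdherenceTree) -> dict:
    """Mapping form of a tree, with keys in canonical writer order."""
    doc: dict = {"name": tree.name}
    if tree.description:
        doc["description"] = tree.description
    doc["top"] = tree.top_id
    doc["nodes"] = []
    for node in tree.nodes.values():
        entry: dict = {"id": node.id, "label": node.label, "kind": node.kind}
        if node.gate is not None:
            entry["gate"] = node.gate.value
        if node.children:
            entry["children"] = list(node.children)
        if node.rate_model is not None:
            entry["rate"] = node.rate_model.to_dict()
        doc["nodes"].append(entry)
    return doc


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("yaml", "json"):
            raise ValueError(f"format must be 'yaml' or 'json', got {format!r}")
        return format
    return "json" if path.suffix.lower() == ".json" else "yaml"


def load_tree(path: str | Path, format: str | None = None) -> NonAdherenceTree:
    """Read and validate a tree from a YAML or JSON file.

    The format is inferred from the suffix unless given explicitly (JSON for
    ``.json``, YAML otherwise; JSON is an isomorphic dialect of the YAML
    schema).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    with open(path) as fh:
        data = json.load(fh) if fmt == "json" else yaml.safe_load(fh)
    return tree_from_dict(data)


def write_tree(tree: NonAdherenceTree, path: str | Path, format: str | None = None) -> None:
    """Write a tree to YAML or JSON; ``load_tree`` round-trips it node-for-node."""
    path = Path(path)
    fmt = _infer_format(path, format)
    doc = tree_to_dict(tree)
    with open(path, "w") as fh:
        if fmt == "json":
            json.dump(doc, fh, indent=2)
            fh.write("\n")
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)
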