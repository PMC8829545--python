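"""Declarative hierarchical gating.

A gate tree is a list of named nodes, each with a parent and a
conjunction of atoms over single markers on the transformed scale. A
cell is inside a gate iff it is inside the parent gate and satisfies
every atom. Two atom forms exist:

* threshold atoms — ``CD3+`` / ``CD3-`` (optionally ``CD3 + 1.9`` with
  an explicit cut); ``+`` means value >= threshold, ``-`` means value <
  threshold, so a +/- pair on one marker partitions the parent exactly;
* interval atoms — ``CD56 in [1.4, 3.75)`` with a closed lower and open
  upper bound, used for bright/dim/negative strata on one channel;
  boundary values land in the higher stratum.

Thresholds live in the gate config, not the code: manual cytometry
gates are dataset-specific, so the shipped defaults only suit the
synthetic cohorts (midpoints between archetype levels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import EventTable

__all__ = [
    "GateAtom",
    "GateNode",
    "GateTree",
    "SubsetAssignment",
    "evaluate_gate_tree",
    "subset_frequencies",
    "mean_signal_intensity",
    "load_gate_tree",
]

ROOT = "root"


@dataclass(frozen=True)
class GateAtom:
    """One marker condition: sign atom (+/- vs threshold) or interval."""

    marker: str
    kind: str  # "+", "-", or "interval"
    threshold: float = float("nan")
    lower: float = float("-inf")
    upper: float = float("inf")

    def __post_init__(self) -> None:
        if self.kind in ("+", "-"):
            if not np.isfinite(self.threshold):
                raise ValueError(f"atom on {self.marker!r}: threshold must be finite")
        elif self.kind == "interval":
            if not self.lower < self.upper:
                raise ValueError(
                    f"atom on {self.marker!r}: interval lower bound must be < upper"
                )
        else:
            raise ValueError(f"unknown atom kind {self.kind!r}")

    def evaluate(self, table: EventTable) -> np.ndarray:
        x = table.marker_values(self.marker)
        if self.kind == "+":
            return x >= self.threshold
        if self.kind == "-":
            return x < self.threshold
        return (x >= self.lower) & (x < self.upper)

    def __str__(self) -> str:
        if self.kind == "interval":
            return f"{self.marker} in [{self.lower}, {self.upper})"
        return f"{self.marker} {self.kind} {self.threshold:g}"


@dataclass
class GateNode:
    name: str
    parent: str  # ROOT for top-level gates
    atoms: list[GateAtom] = field(default_factory=list)


@dataclass
class GateTree:
    """Ordered gate nodes plus declared sibling partition groups."""

    nodes: list[GateNode]
    partitions: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = {ROOT}
        for node in self.nodes:
            if node.name in seen:
                raise ValueError(f"duplicate gate name {node.name!r}")
            if node.parent not in seen:
                raise ValueError(
                    f"gate {node.name!r}: parent {node.parent!r} not defined "
                    f"before child (missing or cyclic)"
                )
            seen.add(node.name)

    def node(self, name: str) -> GateNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"unknown gate {name!r}")

    def markers_used(self) -> set[str]:
        return {a.marker for n in self.nodes for a in n.atoms}

    def descends_from(self, child: str, ancestor: str) -> bool:
        if ancestor == ROOT:
            return True
        cur = child
        while cur != ROOT:
            if cur == ancestor:
                return True
            cur = self.node(cur).parent
        return False


@dataclass
class SubsetAssignment:
    """Boolean gate membership per cell, for every gate in the tree."""

    tree: GateTree
    membership: dict[str, np.ndarray]

    def __getitem__(self, gate: str) -> np.ndarray:
        if gate == ROOT:
            n = len(next(iter(self.membership.values())))
            return np.ones(n, dtype=bool)
        if gate not in self.membership:
            raise KeyError(f"unknown gate {gate!r}")
        return self.membership[gate]

    def terminal_labels(self) -> list[frozenset]:
        """Per cell, the set of gates it is in that have no member child."""
        children: dict[str, list[str]] = {}
        for node in self.tree.nodes:
            children.setdefault(node.parent, []).append(node.name)
        n = len(next(iter(self.membership.values())))
        labels: list[set] = [set() for _ in range(n)]
        for name, mask in self.membership.items():
            kids = children.get(name, [])
            if kids:
                in_child = np.zeros(n, dtype=bool)
                for k in kids:
                    in_child |= self.membership[k]
                terminal = mask & ~in_child
            else:
                terminal = mask
            for i in np.flatnonzero(terminal):
                labels[i].add(name)
        return [frozenset(s) for s in labels]

    def check_hierarchy(self) -> None:
        """Assert child membership implies parent membership (every cell)."""
        for node in self.tree.nodes:
            if node.parent == ROOT:
                continue
            bad = self.membership[node.name] & ~self.membership[node.parent]
            if bad.any():
                raise AssertionError(
                    f"hierarchy violated: {bad.sum()} cells in {node.name!r} "
                    f"but not in parent {node.parent!r}"
                )

    def check_partitions(self) -> None:
        """Assert declared sibling groups are exclusive (and exhaustive)."""
        for part in self.tree.partitions:
            gates = part["gates"]
            parents = {self.tree.node(g).parent for g in gates}
            if len(parents) != 1:
                raise AssertionError(f"partition {gates} spans multiple parents")
            parent = parents.pop()
            stack = np.vstack([self.membership[g] for g in gates])
            counts = stack.sum(axis=0)
            in_parent = self[parent]
            if (counts[in_parent] > 1).any():
                raise AssertionError(f"partition {gates} is not mutually exclusive")
            if part.get("exhaustive") and (counts[in_parent] < 1).any():
                raise AssertionError(
                    f"partition {gates} does not exhaust parent {parent!r}"
                )


def evaluate_gate_tree(table: EventTable, tree: GateTree) -> SubsetAssignment:
    """Evaluate every gate of the tree over the table. Deterministic."""
    missing = sorted(tree.markers_used() - set(table.markers))
    if missing:
        raise ValueError(f"gate tree references markers absent from table: {missing}")
    membership: dict[str, np.ndarray] = {}
    for node in tree.nodes:
        mask = (
            np.ones(table.n_cells, dtype=bool)
            if node.parent == ROOT
            else membership[node.parent].copy()
        )
        for atom in node.atoms:
            mask &= atom.evaluate(table)
        membership[node.name] = mask
    return SubsetAssignment(tree=tree, membership=membership)


def subset_frequencies(
    assign: SubsetAssignment,
    table: EventTable,
    numerator: str,
    denominator: str = ROOT,
) -> pd.DataFrame:
    """Per subject x compartment percentage of denominator cells in numerator.

    An empty denominator for a subject/compartment yields a missing
    value, not zero. The numerator must descend from the denominator (or
    the denominator is the root population).
    """
    if not assign.tree.descends_from(numerator, denominator):
        raise ValueError(
            f"numerator {numerator!r} does not descend from denominator {denominator!r}"
        )
    num = assign[numerator]
    den = assign[denominator]
    df = pd.DataFrame({
        "subject_id": table.subject_id,
        "group": table.group,
        "compartment": table.compartment,
        "num": num,
        "den": den,
    })
    agg = df.groupby(["subject_id", "group", "compartment"], sort=False).agg(
        n_numerator=("num", "sum"), n_denominator=("den", "sum")
    ).reset_index()
    agg["percentage"] = np.where(
        agg["n_denominator"] > 0,
        100.0 * agg["n_numerator"] / agg["n_denominator"].replace(0, np.nan),
        np.nan,
    )
    agg.insert(3, "numerator", numerator)
    agg.insert(4, "denominator", denominator)
    return agg


def mean_signal_intensity(
    table: EventTable,
    assign: SubsetAssignment,
    gate: str,
    marker: str,
) -> pd.DataFrame:
    """Per subject x compartment mean of one marker over cells in a gate.

    The MSI convention of cytometry figure panels: an arithmetic mean of
    the transformed intensities; empty gates give missing values.
    """
    mask = assign[gate]
    x = table.marker_values(marker)  # raises KeyError for unknown marker
    df = pd.DataFrame({
        "subject_id": table.subject_id,
        "group": table.group,
        "compartment": table.compartment,
        "in_gate": mask,
        "value": np.where(mask, x, np.nan),
    })
    agg = df.groupby(["subject_id", "group", "compartment"], sort=False).agg(
        n_cells=("in_gate", "sum"), msi=("value", "mean")
    ).reset_index()
    agg.loc[agg["n_cells"] == 0, "msi"] = np.nan
    agg.insert(3, "gate", gate)
    agg.insert(4, "marker", marker)
    return agg


# ---------------------------------------------------------------------------
# config parsing

_SIGN_RE = re.compile(r"^\s*(\S+?)\s*([+-])\s*([-+0-9.eE]+)?\s*$")
_INTERVAL_RE = re.compile(
    r"^\s*(\S+)\s+in\s+\[\s*([^,\s]+)\s*,\s*([^)\s]+)\s*\)\s*$"
)


def parse_atom(text: str, thresholds: dict[str, float] | None = None,
               default_threshold: float = 1.9) -> GateAtom:
    """Parse ``marker op threshold`` / ``marker in [lo, hi)`` atom strings."""
    thresholds = thresholds or {}
    m = _INTERVAL_RE.match(text)
    if m:
        marker, lo, hi = m.groups()
        return GateAtom(marker=marker, kind="interval",
                        lower=float(lo), upper=float(hi))
    m = _SIGN_RE.match(text)
    if m:
        marker, sign, thr = m.groups()
        threshold = float(thr) if thr is not None else float(
            thresholds.get(marker, default_threshold)
        )
        return GateAtom(marker=marker, kind=sign, threshold=threshold)
    raise ValueError(f"cannot parse gate atom {text!r}")


def gate_tree_from_dict(cfg: dict) -> GateTree:
    thresholds = {
        k: float(v) for k, v in (cfg.get("thresholds") or {}).items() if k != "default"
    }
    default_thr = float((cfg.get("thresholds") or {}).get("default", 1.9))
    nodes = [
        GateNode(
            name=g["name"],
            parent=g.get("parent", ROOT),
            atoms=[parse_atom(a, thresholds, default_thr) for a in g.get("atoms", [])],
        )
        for g in cfg["gates"]
    ]
    return GateTree(nodes=nodes, partitions=list(cfg.get("partitions", [])))


def load_gate_tree(path: str | Path) -> GateTree:
    with open(path) as fh:
        return gate_tree_from_dict(yaml.safe_load(fh))
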