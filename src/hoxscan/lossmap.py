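"""Dollo-parsimony gene-loss reconstruction on a rooted species tree.

Under Dollo parsimony each orthology group is gained exactly once — on the
edge above the last common ancestor of all species that retain it — and
every absence inside that clade is explained by losses. The minimal loss
set is the set of maximal all-absent subtrees within the gain clade, which
a single post-order pass finds in linear time. Polytomies are supported;
losses on polytomy children count per child edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd


@dataclass
class EventSet:
    """Single-gain / minimal-loss scenario for one orthology group."""

    group: str
    gain_edge: str | None  # child-node label of the gain edge, or None
    loss_edges: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def _leaf_states(
    tree: dendropy.Tree, presence: Mapping[str, int]
) -> dict[dendropy.Node, int]:
    states = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in presence:
            raise ValueError(f"leaf {label!r} missing from presence matrix")
        states[leaf] = int(presence[label])
    return states


def dollo_reconstruct(
    tree: dendropy.Tree, presence: Mapping[str, int], group: str = ""
) -> EventSet:
    """Reconstruct the single gain and minimal losses for one group.

    ``presence`` maps every leaf label to 0/1. With no present leaf the
    character was never gained (gain_edge None, no losses).
    """
    leaf_state = _leaf_states(tree, presence)
    # post-order: number of present leaves below each node
    n_present: dict[dendropy.Node, int] = {}
    n_leaves: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            n_present[node] = leaf_state[node]
            n_leaves[node] = 1
        else:
            n_present[node] = sum(n_present[c] for c in node.child_nodes())
            n_leaves[node] = sum(n_leaves[c] for c in node.child_nodes())
    total_present = n_present[tree.seed_node]
    if total_present == 0:
        return EventSet(group=group, gain_edge=None)
    # gain above the LCA of present leaves: deepest node covering them all
    gain = tree.seed_node
    while True:
        carriers = [c for c in gain.child_nodes() if n_present[c] > 0]
        if len(carriers) == 1 and n_present[carriers[0]] == total_present:
            gain = carriers[0]
        else:
            break
    # losses: maximal all-absent subtrees inside the gain clade
    losses: set[str] = set()
    stack = [gain]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if n_present[child] == 0:
                losses.add(child.label)
            elif n_present[child] < n_leaves[child]:
                stack.append(child)
    return EventSet(group=group, gain_edge=gain.label, loss_edges=frozenset(losses))


def replay_events(tree: dendropy.Tree, events: EventSet) -> dict[str, int]:
    """Leaf states implied by playing the gain then the losses down the tree."""
    states: dict[str, int] = {}

    def walk(node: dendropy.Node, state: int) -> None:
        if events.gain_edge is not None and node.label == events.gain_edge:
            state = 1
        if node.label in events.loss_edges:
            state = 0
        if node.is_leaf():
            states[node.taxon.label] = state
        for child in node.child_nodes():
            walk(child, state)

    walk(tree.seed_node, 0)
    return states


def fitch_changes(tree: dendropy.Tree, presence: Mapping[str, int]) -> int:
    """Fitch small-parsimony change count for comparison with Dollo.

    Allows independent gains; returned count mixes gains and losses.
    """
    leaf_state = _leaf_states(tree, presence)
    changes = 0
    sets: dict[dendropy.Node, frozenset[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({leaf_state[node]})
            continue
        child_sets = [sets[c] for c in node.child_nodes()]
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[node] = inter
        else:
            # generalised Fitch for polytomies: most frequent states
            tally: dict[int, int] = {}
            for cs in child_sets:
                for s in cs:
                    tally[s] = tally.get(s, 0) + 1
            top = max(tally.values())
            sets[node] = frozenset(s for s, n in tally.items() if n == top)
            changes += len(child_sets) - top
    return changes


def summarize_events(
    tree: dendropy.Tree, matrix: pd.DataFrame
) -> tuple[pd.DataFrame, list[EventSet]]:
    """One Dollo reconstruction per group, merged into a per-branch table.

    ``matrix``: species (index) x group (columns) 0/1 DataFrame. Returns a
    (branch, group, event) table — independent losses of one group on
    disjoint branches are distinct rows — plus the per-group event sets.
    """
    rows = []
    event_sets = []
    for grp in matrix.columns:
        presence = {str(sp): int(matrix.loc[sp, grp]) for sp in matrix.index}
        ev = dollo_reconstruct(tree, presence, group=str(grp))
        event_sets.append(ev)
        if ev.gain_edge is not None:
            rows.append({"branch": ev.gain_edge, "group": str(grp), "event": "gain"})
        for edge in sorted(ev.loss_edges):
            rows.append({"branch": edge, "group": str(grp), "event": "loss"})
    table = pd.DataFrame(rows, columns=["branch", "group", "event"])
    return table, event_sets
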