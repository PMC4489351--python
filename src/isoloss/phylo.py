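"""Dollo mapping of isoform losses on a rooted species tree.

Under Dollo parsimony the isoform is gained once (present at the root)
and can only be lost; the minimum event set therefore consists of the
maximal clades whose leaves are all lost-or-unknown and which contain
at least one lost leaf. Unknown leaves are wildcards: they may sit
inside a lost clade without forcing an extra event, and never anchor
one. Events whose supporting taxa carry incompatible lesions are then
split: two lost leaves stay in one event only if they share at least
one homologous lesion (same type, overlapping alignment span, and for
indels an identical length). This is the computable proxy for judging
mutation events "obviously independent".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy

from .calling import State
from .features import Lesion, LesionReport, lesions_homologous


@dataclass
class LossEvent:
    anchor: str  # label of the branch's child node (or joined leaf names)
    supporting_leaves: tuple[str, ...]
    shared_lesion: Lesion | None = None
    flags: list[str] = field(default_factory=list)


def _leaf_label(leaf: dendropy.Node) -> str:
    if leaf.taxon is not None:
        return leaf.taxon.label
    return leaf.label or ""


def _node_anchor_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return _leaf_label(node)
    if node.label:
        return node.label
    leaves = sorted(_leaf_label(l) for l in node.leaf_iter())
    return "stem(" + "+".join(leaves) + ")"


def _mrca_within(node: dendropy.Node, targets: set[str]) -> dendropy.Node:
    """Descend from ``node`` to the smallest clade containing all targets."""
    current = node
    while True:
        for child in current.child_nodes():
            below = {_leaf_label(l) for l in child.leaf_iter()}
            if targets <= below:
                current = child
                break
        else:
            return current


def _as_state(value) -> State:
    return value if isinstance(value, State) else State(value)


def dollo_events(
    tree: dendropy.Tree, calls: dict[str, State | str]
) -> list[LossEvent]:
    """Minimum loss events for a presence/absence character map.

    Each event is anchored, among the tying minimum placements, at the
    branch closest to the leaves: the stem of the MRCA of its lost
    supporting leaves (losses map in terminal lineages).
    """
    states = {sp: _as_state(st) for sp, st in calls.items()}
    lossable: dict[int, bool] = {}
    lost_below: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            st = states.get(label, State.UNKNOWN)
            lossable[id(node)] = st in (State.LOST, State.UNKNOWN)
            lost_below[id(node)] = [label] if st is State.LOST else []
        else:
            children = node.child_nodes()
            lossable[id(node)] = all(lossable[id(c)] for c in children)
            lost_below[id(node)] = [x for c in children for x in lost_below[id(c)]]

    events: list[LossEvent] = []
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if not (lossable[id(node)] and lost_below[id(node)]):
            continue
        parent = node.parent_node
        if parent is not None and lossable[id(parent)]:
            continue  # not maximal
        lost = set(lost_below[id(node)])
        anchor_node = _mrca_within(node, lost)
        flags = []
        if node is root:
            flags.append("all leaves lost: contradicts presence at root")
        events.append(
            LossEvent(
                anchor=_node_anchor_label(anchor_node),
                supporting_leaves=tuple(sorted(lost)),
                flags=flags,
            )
        )
    events.sort(key=lambda e: e.supporting_leaves)
    return events


def _common_lesion(members: list[str], reports: dict[str, LesionReport]) -> Lesion | None:
    """A lesion of the first member homologous to one in every other."""
    first = reports[members[0]].lesions
    for lesion in first:
        if all(
            any(lesions_homologous(lesion, other) for other in reports[m].lesions)
            for m in members[1:]
        ):
            return lesion
    return None


def split_by_lesion(
    tree: dendropy.Tree,
    events: list[LossEvent],
    reports: dict[str, LesionReport],
) -> list[LossEvent]:
    """Partition each event's leaves into lesion-compatible sub-events.

    Leaves are grouped by the transitive closure of pairwise lesion
    homology; each group becomes its own event anchored at the stem of
    its leaf set. A lost leaf without a report is kept as its own event
    (with a warning). Never decreases the event count.
    """
    label_to_node = {
        _leaf_label(l): l for l in tree.leaf_node_iter()
    }
    out: list[LossEvent] = []
    for event in events:
        members = [l for l in event.supporting_leaves if l in reports]
        orphans = [l for l in event.supporting_leaves if l not in reports]
        for leaf in orphans:
            warnings.warn(f"no lesion report for lost leaf {leaf}; kept as its own event")
            out.append(LossEvent(anchor=leaf, supporting_leaves=(leaf,), flags=["no report"]))
        if not members:
            continue
        # union-find over lesion homology
        parent = {m: m for m in members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if find(a) == find(b):
                    continue
                if any(
                    lesions_homologous(la, lb)
                    for la in reports[a].lesions
                    for lb in reports[b].lesions
                ):
                    parent[find(b)] = find(a)

        groups: dict[str, list[str]] = {}
        for m in members:
            groups.setdefault(find(m), []).append(m)

        for group in sorted(groups.values()):
            group = sorted(group)
            if len(group) == 1:
                node = label_to_node[group[0]]
                anchor = _leaf_label(node)
            else:
                mrca = _mrca_within(tree.seed_node, set(group))
                anchor = _node_anchor_label(mrca)
            out.append(
                LossEvent(
                    anchor=anchor,
                    supporting_leaves=tuple(group),
                    shared_lesion=_common_lesion(group, reports),
                    flags=list(event.flags),
                )
            )
    # flag shared derived lesions inconsistent with the tree (homoplasy):
    # homologous-looking lesions in two separate events are counted as
    # independent but marked, never used to re-estimate the tree.
    for i, a in enumerate(out):
        for b in out[i + 1 :]:
            if a.shared_lesion is None and len(a.supporting_leaves) > 1:
                continue
            la = (
                [a.shared_lesion]
                if a.shared_lesion is not None
                else reports.get(a.supporting_leaves[0], None).lesions
                if a.supporting_leaves[0] in reports
                else []
            )
            lb = (
                [b.shared_lesion]
                if b.shared_lesion is not None
                else reports.get(b.supporting_leaves[0], None).lesions
                if b.supporting_leaves[0] in reports
                else []
            )
            if any(lesions_homologous(x, y) for x in la for y in lb):
                if "homoplasy" not in a.flags:
                    a.flags.append("homoplasy")
                if "homoplasy" not in b.flags:
                    b.flags.append("homoplasy")
    out.sort(key=lambda e: e.supporting_leaves)
    return out


def count_independent_losses(
    tree: dendropy.Tree,
    calls: dict[str, State | str],
    reports: dict[str, LesionReport] | None = None,
) -> tuple[int, list[LossEvent]]:
    """Lesion-aware independent loss count (plain Dollo if no reports)."""
    events = dollo_events(tree, calls)
    if reports is not None:
        events = split_by_lesion(tree, events, reports)
    return len(events), events


def read_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick", preserve_underscores=True)
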