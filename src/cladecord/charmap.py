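"""Parsimony mapping of plastome structural characters onto a fixed tree.

Characters are binary (present/absent) with an explicit *uncertain* state
that imposes no constraint (a gray cell: the feature may still be present).
Gene-content characters are mapped under Dollo parsimony (a single ancestral
presence, any number of independent losses), the general minimal-change
count under Fitch (Sankoff) parsimony; comparing the two separates clean
loss histories from characters that would require reversals.

Intron characters (position and cis/trans splicing status) are modelled as
separate binary characters rather than multistate ones, so a trans-splicing
gain is an independent mark on the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .taxa import TaxonSet
from .trees import Tree

__all__ = [
    "CharacterMatrix",
    "EventMap",
    "read_character_table",
    "fitch_events",
    "dollo_events",
    "synapomorphy_report",
]

PRESENT, ABSENT, UNCERTAIN = "present", "absent", "uncertain"

_STATE_TOKENS = {
    "1": PRESENT,
    "0": ABSENT,
    "?": UNCERTAIN,
    "present": PRESENT,
    "absent": ABSENT,
    "uncertain": UNCERTAIN,
}

_META_ROWS = {"!position": "position", "!splicing": "splicing"}


@dataclass
class CharacterMatrix:
    """Taxa x binary structural characters with optional intron metadata."""

    taxa: TaxonSet
    characters: list[str]
    states: dict[tuple[str, str], str]  # (taxon, character) -> state
    intron_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("character ids must be unique")
        for taxon in self.taxa:
            for ch in self.characters:
                s = self.states.get((taxon, ch))
                if s not in (PRESENT, ABSENT, UNCERTAIN):
                    raise ValueError(
                        f"missing or invalid state for ({taxon!r}, {ch!r}): {s!r}"
                    )

    def state(self, taxon: str, character: str) -> str:
        return self.states[(taxon, character)]

    def column(self, character: str) -> dict[str, str]:
        if character not in self.characters:
            raise KeyError(f"unknown character {character!r}")
        return {t: self.states[(t, character)] for t in self.taxa}


def read_character_table(path: str | Path, universe: TaxonSet | None = None) -> CharacterMatrix:
    """Read a taxon x character CSV into a :class:`CharacterMatrix`.

    The header row carries character ids; each row starts with a taxon
    label; cells are ``1/0/?`` or ``present/absent/uncertain``. Optional
    metadata rows whose first field is ``!position`` or ``!splicing``
    attach intron position / cis-trans annotations per character.
    """
    df = pd.read_csv(path, dtype=str).fillna("?")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: character table needs a taxon column plus characters")
    characters = [str(c) for c in df.columns[1:]]
    if len(set(characters)) != len(characters):
        raise ValueError(f"{path}: duplicate character ids in header")
    states: dict[tuple[str, str], str] = {}
    intron_meta: dict[str, dict[str, str]] = {}
    taxa_rows: list[str] = []
    for _, row in df.iterrows():
        key = str(row.iloc[0]).strip()
        if key in _META_ROWS:
            meta_key = _META_ROWS[key]
            for ch, val in zip(characters, row.iloc[1:]):
                val = str(val).strip()
                if val and val != "?":
                    intron_meta.setdefault(ch, {})[meta_key] = val
            continue
        taxa_rows.append(key)
        for ch, val in zip(characters, row.iloc[1:]):
            tok = str(val).strip().lower()
            if tok not in _STATE_TOKENS:
                raise ValueError(
                    f"{path}: unknown state token {val!r} at taxon {key!r}, "
                    f"character {ch!r}"
                )
            states[(key, ch)] = _STATE_TOKENS[tok]
    if universe is None:
        universe = TaxonSet(taxa_rows)
    else:
        stray = [t for t in taxa_rows if t not in universe]
        if stray:
            raise ValueError(f"{path}: taxa not in universe: {stray}")
    return CharacterMatrix(universe, characters, states, intron_meta)


@dataclass
class EventMap:
    """A minimal event placement for one character on one tree.

    ``event_edges`` lists ``(clade_tips, transition)`` pairs, where
    ``clade_tips`` are the (state-known) tips below the edge carrying the
    event and ``transition`` is ``"present->absent"`` or
    ``"absent->present"``. ``ambiguous`` is set when more than one minimal
    reconstruction exists; the reported one prefers the parent's state on
    ties (delayed transformation), which places events on the stem edges of
    maximal clades."""

    character: str
    root_state: str
    min_events: int
    event_edges: list[tuple[tuple[str, ...], str]]
    ambiguous: bool
    uninformative: bool = False


def _pruned_dendropy(tree: Tree, keep: set[str]):
    dtree = tree.dendropy_tree.clone(depth=1)
    taxa_to_keep = [lf.taxon for lf in dtree.leaf_node_iter() if lf.taxon.label in keep]
    dtree.retain_taxa(taxa_to_keep)
    return dtree


def fitch_events(
    tree: Tree,
    cm: CharacterMatrix,
    character: str,
    root_state: str | None = None,
) -> EventMap:
    """Minimal-change (Fitch/Sankoff) mapping of a binary character.

    Uncertain tips are treated as missing and pruned before the dynamic
    program. ``root_state`` optionally constrains the root (e.g. the
    ancestral-presence assumption); unconstrained, the count is invariant
    to rooting. ``ambiguous`` is computed by counting minimal
    reconstructions exactly."""
    col = cm.column(character)
    known = {t for t, s in col.items() if s != UNCERTAIN and t in set(tree.leaf_labels)}
    if len(known) < 1 or len({col[t] for t in known}) <= 1 and (
        root_state is None or not known or col[next(iter(known))] == root_state
    ):
        # constant (or empty) character: zero events
        state = col[next(iter(known))] if known else (root_state or PRESENT)
        return EventMap(
            character, root_state or state, 0, [], False, uninformative=not known
        )

    if len(known) == 1:
        (tip,) = known
        s = col[tip]
        if root_state is not None and s != root_state:
            return EventMap(
                character, root_state, 1, [((tip,), f"{root_state}->{s}")], False
            )
        return EventMap(character, root_state or s, 0, [], False)

    dtree = _pruned_dendropy(tree, known)
    states = (PRESENT, ABSENT)
    INF = math.inf

    cost: dict = {}
    ways: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            s = col[node.taxon.label]
            cost[node] = {t: (0 if t == s else INF) for t in states}
            ways[node] = {t: (1 if t == s else 0) for t in states}
        else:
            cost[node] = {}
            ways[node] = {}
            for s in states:
                total, nways = 0, 1
                for ch in node.child_nodes():
                    best, w = INF, 0
                    for t in states:
                        c = cost[ch][t] + (0 if t == s else 1)
                        if c < best:
                            best, w = c, ways[ch][t]
                        elif c == best:
                            w += ways[ch][t]
                    total += best
                    nways *= w
                cost[node][s] = total
                ways[node][s] = nways

    root = dtree.seed_node
    if root_state is not None:
        min_cost = cost[root][root_state]
        n_opt = ways[root][root_state]
        chosen_root = root_state
    else:
        min_cost = min(cost[root].values())
        n_opt = sum(ways[root][s] for s in states if cost[root][s] == min_cost)
        # deterministic tie-break: prefer presence at the root
        chosen_root = next(s for s in states if cost[root][s] == min_cost)
    if not math.isfinite(min_cost):
        raise ValueError(
            f"character {character!r}: no reconstruction satisfies the "
            f"root-state constraint {root_state!r}"
        )

    # top-down refinement, preferring the parent's state on ties (DELTRAN)
    assign = {root: chosen_root}
    events: list[tuple[tuple[str, ...], str]] = []
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        parent_state = assign[node.parent_node]
        best = min(cost[node][t] + (0 if t == parent_state else 1) for t in states)
        candidates = [
            t for t in states if cost[node][t] + (0 if t == parent_state else 1) == best
        ]
        chosen = parent_state if parent_state in candidates else candidates[0]
        assign[node] = chosen
        if chosen != parent_state:
            tips = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
            events.append((tips, f"{parent_state}->{chosen}"))

    return EventMap(
        character=character,
        root_state=chosen_root,
        min_events=int(min_cost),
        event_edges=events,
        ambiguous=n_opt > 1,
    )


def dollo_events(tree: Tree, cm: CharacterMatrix, character: str) -> EventMap:
    """Loss-only (Dollo) mapping: the character is present at the root and
    gains are forbidden below it, so the minimum is the number of maximal
    clades whose (state-known) tips are all absent. The minimal placement
    is unique: one loss on each such clade's stem edge."""
    col = cm.column(character)
    known = {t for t, s in col.items() if s != UNCERTAIN and t in set(tree.leaf_labels)}
    absent_tips = {t for t in known if col[t] == ABSENT}
    if not known:
        return EventMap(character, PRESENT, 0, [], False, uninformative=True)
    if not absent_tips:
        return EventMap(character, PRESENT, 0, [], False)

    dtree = _pruned_dendropy(tree, known)
    all_absent: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            all_absent[node] = col[node.taxon.label] == ABSENT
        else:
            all_absent[node] = all(all_absent[c] for c in node.child_nodes())
    events: list[tuple[tuple[str, ...], str]] = []
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue  # root constrained present
        if all_absent[node] and not all_absent.get(node.parent_node, False):
            tips = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
            events.append((tips, f"{PRESENT}->{ABSENT}"))
    if all_absent.get(dtree.seed_node, False):
        # every known tip absent: one loss per root-child lineage
        events = []
        for node in dtree.seed_node.child_nodes():
            tips = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
            events.append((tips, f"{PRESENT}->{ABSENT}"))
    return EventMap(character, PRESENT, len(events), events, ambiguous=False)


def synapomorphy_report(
    tree: Tree,
    cm: CharacterMatrix,
    root_states: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Map every character under both Fitch and Dollo parsimony.

    ``root_states`` overrides the default ancestral-presence assumption per
    character (e.g. a trans-splicing character is ancestrally absent). The
    ``unique`` flag marks characters explained by a single event without
    reversals or parallel changes."""
    root_states = dict(root_states or {})
    rows = []
    for ch in cm.characters:
        root = root_states.get(ch, PRESENT)
        fit = fitch_events(tree, cm, ch, root_state=root)
        dol = dollo_events(tree, cm, ch)
        clades = "|".join(",".join(tips) for tips, _ in fit.event_edges)
        rows.append(
            {
                "character": ch,
                "root_state": root,
                "fitch_events": fit.min_events,
                "dollo_events": dol.min_events,
                "event_clades": clades,
                "ambiguous": fit.ambiguous,
                "unique": fit.min_events == 1,
                "uninformative": fit.uninformative,
                "intron_position": cm.intron_meta.get(ch, {}).get("position", ""),
                "splicing": cm.intron_meta.get(ch, {}).get("splicing", ""),
            }
        )
    return pd.DataFrame(rows)
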