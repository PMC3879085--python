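"""Generic typed traversal over the structure hierarchy.

A single API visits all objects of a chosen level (model, chain, residue
or atom) contained directly or transitively in any hierarchy node: a
generalization of map / fold / length from flat lists to the nested
Structure -> Model -> Chain -> Residue -> Atom containers.  The level to
visit is an explicit :class:`TraversalKind` argument — the run-time
analogue of selecting a container instance by element type.

Visits always happen in document order (models in stored order, then
chains within each model, residues within each chain, atoms within each
residue).  A node asked to traverse its own kind yields itself, so every
operation is also defined on a bare Atom or Chain ("singleton" rule).

Mapping operations return a new root and never mutate their input;
unchanged sub-trees may be shared structurally.
"""

from __future__ import annotations

import enum
from dataclasses import replace
from typing import Any, Callable, Iterator, Tuple, TypeVar, Union

from .model import Atom, Chain, Model, Residue, Structure

__all__ = [
    "TraversalKind",
    "FoldDirection",
    "TraversalError",
    "iter_nodes",
    "count",
    "map_over",
    "fold_over",
    "map_with_state",
]

TraversalRoot = Union[Structure, Model, Chain, Residue, Atom]
Node = TypeVar("Node", Model, Chain, Residue, Atom)
Acc = TypeVar("Acc")
State = TypeVar("State")


class TraversalKind(enum.Enum):
    """Which hierarchy level a traversal visits."""

    MODEL = 1
    CHAIN = 2
    RESIDUE = 3
    ATOM = 4


class FoldDirection(enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class TraversalError(RuntimeError):
    """The visited function failed; carries the node's position."""


_NODE_LEVEL = {Structure: 0, Model: 1, Chain: 2, Residue: 3, Atom: 4}
_CHILD_ATTR = {Structure: "models", Model: "chains", Chain: "residues", Residue: "atoms"}
_KIND_TYPE = {
    TraversalKind.MODEL: Model,
    TraversalKind.CHAIN: Chain,
    TraversalKind.RESIDUE: Residue,
    TraversalKind.ATOM: Atom,
}


def _level(node: TraversalRoot) -> int:
    try:
        return _NODE_LEVEL[type(node)]
    except KeyError:
        raise TypeError(f"not a hierarchy node: {type(node).__name__}") from None


def iter_nodes(root: TraversalRoot, kind: TraversalKind) -> Iterator[Any]:
    """Yield every ``kind``-level node contained in ``root``, document order.

    ``root`` itself is yielded when it is of the requested kind.
    """
    target = kind.value
    level = _level(root)
    if level == target:
        yield root
        return
    if level > target:
        return
    for child in getattr(root, _CHILD_ATTR[type(root)]):
        yield from iter_nodes(child, kind)


def count(root: TraversalRoot, kind: TraversalKind) -> int:
    """Number of ``kind``-level nodes contained in ``root``.

    Computed arithmetically from container lengths (no per-atom visit),
    so counting atoms in a large structure is cheap.
    """
    target = kind.value
    level = _level(root)
    if level == target:
        return 1
    if level > target:
        return 0
    children = getattr(root, _CHILD_ATTR[type(root)])
    if level + 1 == target:
        return len(children)
    return sum(count(child, kind) for child in children)


def fold_over(
    root: TraversalRoot,
    kind: TraversalKind,
    fn: Callable[..., Acc],
    init: Acc,
    direction: FoldDirection = FoldDirection.LEFT,
) -> Acc:
    """Eagerly fold over all ``kind``-level nodes of ``root``.

    LEFT folds in document order calling ``fn(acc, node)``; RIGHT folds
    from the last node backwards calling ``fn(node, acc)`` — the usual
    foldl/foldr conventions on the document-order sequence, so a
    non-associative ``fn`` distinguishes the two.  Accumulation is eager;
    errors raised by ``fn`` propagate with the node position attached.
    """
    nodes = list(iter_nodes(root, kind))
    acc = init
    if direction is FoldDirection.LEFT:
        for index, node in enumerate(nodes):
            try:
                acc = fn(acc, node)
            except Exception as exc:
                raise TraversalError(
                    f"fold function failed at {kind.name} #{index}: {exc}"
                ) from exc
    else:
        for index in range(len(nodes) - 1, -1, -1):
            try:
                acc = fn(nodes[index], acc)
            except Exception as exc:
                raise TraversalError(
                    f"fold function failed at {kind.name} #{index}: {exc}"
                ) from exc
    return acc


def map_with_state(
    root: TraversalRoot,
    kind: TraversalKind,
    fn: Callable[[State, Node], Tuple[State, Node]],
    state0: State,
) -> Tuple[TraversalRoot, State]:
    """Shape-preserving map threading a state through nodes in document order.

    ``fn(state, node) -> (state, node)`` must return a node of the same
    kind.  Returns the rebuilt root and the final state.  Equivalent to
    :func:`map_over` when ``fn`` ignores its state.
    """
    expected = _KIND_TYPE[kind]
    counter = [0]

    def rebuild(node: TraversalRoot, state: State) -> Tuple[State, TraversalRoot]:
        level = _level(node)
        if level == kind.value:
            index = counter[0]
            counter[0] += 1
            try:
                state, new_node = fn(state, node)
            except Exception as exc:
                raise TraversalError(
                    f"map function failed at {kind.name} #{index}: {exc}"
                ) from exc
            if not isinstance(new_node, expected):
                raise TypeError(
                    f"map function must return {expected.__name__}, "
                    f"got {type(new_node).__name__} at {kind.name} #{index}"
                )
            return state, new_node
        if level > kind.value:
            return state, node
        attr = _CHILD_ATTR[type(node)]
        new_children = []
        for child in getattr(node, attr):
            state, new_child = rebuild(child, state)
            new_children.append(new_child)
        return state, replace(node, **{attr: new_children})

    final_state, new_root = rebuild(root, state0)
    return new_root, final_state


def map_over(
    root: TraversalRoot, kind: TraversalKind, fn: Callable[[Node], Node]
) -> TraversalRoot:
    """Apply ``fn`` to every ``kind``-level node, returning a new root."""
    new_root, _ = map_with_state(root, kind, lambda state, node: (state, fn(node)), None)
    return new_root
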