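"""Monotone Boolean composites evaluated under three-valued (Kleene) logic.

A composite endpoint is an AND/OR expression over named binary components.
When some components are unobserved the composite may still be determined:
an OR is 1 as soon as any operand is 1, an AND is 0 as soon as any operand
is 0.  Kleene evaluation returns ``unknown`` exactly when the observed
components leave both values possible, which is the "derived endpoint"
semantics: derivable rows are those whose composite evaluates to 0 or 1.

Because the expressions are negation-free, they are monotone: once a row's
endpoint is derivable, observing further components can never change the
derived value.  Negated definitions are rejected as unsupported.

Definitions are written as nested JSON-style documents, e.g.::

    {"or": ["z1", "z2", "z3"]}                 # event in any component
    {"and": ["z1", {"or": ["z2", "z3"]}]}      # z1 plus at least one of z2/z3
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = [
    "CompositeDefinition",
    "simple_composite",
    "complex_composite",
    "derive_endpoint",
    "complete_records",
]

#: Scalar tri-state values: 0, 1, or None for "unknown".
TriState = Optional[int]

_Node = Union[str, tuple]  # "name" | ("and"|"or", (children...))


def _parse(node) -> _Node:
    if isinstance(node, str):
        if not node:
            raise ConfigError("component name must be a non-empty string")
        return node
    if isinstance(node, Mapping):
        if len(node) != 1:
            raise ConfigError(f"expression node must have exactly one key: {node!r}")
        (op, children), = node.items()
        if op in ("not", "xor"):
            raise ConfigError(
                f"operator {op!r} is unsupported: composites must be monotone "
                "(AND/OR only)"
            )
        if op not in ("and", "or"):
            raise ConfigError(f"unknown operator {op!r}; expected 'and' or 'or'")
        if not isinstance(children, Sequence) or len(children) < 1:
            raise ConfigError(f"operator {op!r} needs a non-empty list of operands")
        return (op, tuple(_parse(c) for c in children))
    raise ConfigError(f"cannot parse expression node {node!r}")


class CompositeDefinition:
    """An AND/OR expression tree over named binary components."""

    def __init__(self, expression) -> None:
        self._root = _parse(expression)
        self._components = tuple(dict.fromkeys(self._collect(self._root)))

    @staticmethod
    def _collect(node: _Node) -> Iterable[str]:
        if isinstance(node, str):
            yield node
        else:
            for child in node[1]:
                yield from CompositeDefinition._collect(child)

    @property
    def components(self) -> tuple[str, ...]:
        """Component names referenced by the definition, in first-use order."""
        return self._components

    def evaluate(self, values: Mapping[str, TriState]) -> TriState:
        """Kleene evaluation of the composite for one row.

        ``values`` maps every referenced component to 0, 1 or None (unknown).
        Returns 0, 1, or None when the observed components do not determine
        the composite.
        """
        for name in self._components:
            if name not in values:
                raise DomainError(f"no value supplied for component {name!r}")
            v = values[name]
            if v not in (0, 1, None):
                raise DomainError(f"component {name!r} has non-tri-state value {v!r}")
        return self._eval(self._root, values)

    @staticmethod
    def _eval(node: _Node, values: Mapping[str, TriState]) -> TriState:
        if isinstance(node, str):
            return values[node]
        op, children = node
        results = [CompositeDefinition._eval(c, values) for c in children]
        if op == "or":
            if any(r == 1 for r in results):
                return 1
            if all(r == 0 for r in results):
                return 0
            return None
        if any(r == 0 for r in results):
            return 0
        if all(r == 1 for r in results):
            return 1
        return None

    def evaluate_frame(self, data: pd.DataFrame) -> np.ndarray:
        """Vectorized Kleene evaluation; returns int8 array with -1 = unknown.

        Missing cells in the component columns (NA) are treated as unknown.
        """
        missing_cols = [c for c in self._components if c not in data.columns]
        if missing_cols:
            raise DomainError(f"dataset lacks component columns {missing_cols}")
        cols = {}
        for name in self._components:
            col = data[name]
            arr = col.to_numpy(dtype="float64", na_value=np.nan)
            bad = ~(np.isnan(arr) | (arr == 0) | (arr == 1))
            if bad.any():
                raise DomainError(
                    f"column {name!r} contains non-binary value "
                    f"{arr[bad][0]!r} (row {int(np.flatnonzero(bad)[0])})"
                )
            out = np.full(arr.shape, -1, dtype=np.int8)
            out[arr == 0] = 0
            out[arr == 1] = 1
            cols[name] = out
        return self._eval_vec(self._root, cols)

    @staticmethod
    def _eval_vec(node: _Node, cols: Mapping[str, np.ndarray]) -> np.ndarray:
        if isinstance(node, str):
            return cols[node]
        op, children = node
        parts = [CompositeDefinition._eval_vec(c, cols) for c in children]
        stacked = np.stack(parts)
        if op == "or":
            result = np.full(stacked.shape[1], -1, dtype=np.int8)
            result[(stacked == 1).any(axis=0)] = 1
            result[(stacked == 0).all(axis=0)] = 0
        else:
            result = np.full(stacked.shape[1], -1, dtype=np.int8)
            result[(stacked == 1).all(axis=0)] = 1
            result[(stacked == 0).any(axis=0)] = 0
        return result

    def to_json(self):
        def unparse(node: _Node):
            if isinstance(node, str):
                return node
            return {node[0]: [unparse(c) for c in node[1]]}

        return unparse(self._root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CompositeDefinition({self.to_json()!r})"


def simple_composite(components: Sequence[str] = ("z1", "z2", "z3")) -> CompositeDefinition:
    """Event in any component: OR(z1, ..., zK)."""
    return CompositeDefinition({"or": list(components)})


def complex_composite(
    anchor: str = "z1", others: Sequence[str] = ("z2", "z3")
) -> CompositeDefinition:
    """Anchor component plus at least one other: AND(z1, OR(z2, z3))."""
    return CompositeDefinition({"and": [anchor, {"or": list(others)}]})


def derive_endpoint(
    data: pd.DataFrame, definition: CompositeDefinition
) -> pd.DataFrame:
    """Attach derived-endpoint columns ``y_deriv`` and ``r_y_deriv``.

    ``y_deriv`` is the Kleene value of the composite (NA where underivable);
    ``r_y_deriv`` is 1 where the endpoint is derivable.  Rows with every
    component observed always get the complete-data composite value.
    """
    tri = definition.evaluate_frame(data)
    out = data.copy()
    y = pd.array(tri, dtype="Int8")
    y[tri == -1] = pd.NA
    out["y_deriv"] = y
    out["r_y_deriv"] = (tri != -1).astype(np.int8)
    return out


def complete_records(
    data: pd.DataFrame, definition: CompositeDefinition
) -> pd.DataFrame:
    """Rows where every component referenced by the definition is observed,
    with the composite computed into column ``y``.

    Note the contrast with :func:`derive_endpoint`: a row with z1 = 1 but z2
    missing is excluded here even though its OR-composite is derivable.
    """
    mask = np.ones(len(data), dtype=bool)
    for name in definition.components:
        if name not in data.columns:
            raise DomainError(f"dataset lacks component column {name!r}")
        mask &= data[name].notna().to_numpy()
    subset = data.loc[mask].copy()
    tri = definition.evaluate_frame(subset)
    subset["y"] = pd.array(tri, dtype="Int8")
    return subset
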