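"""Design-matrix construction shared by the model-based engines.

A *term* is a string: a continuous column name, a categorical column name
(expanded to indicator columns for every level after the first), or a
product ``"a:b"`` of two such expansions (used e.g. for gender-by-age-group
interactions).  Level order comes from the variable schema so donor and
recipient files are always encoded identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import SchemaError, VariableSchema


def _expand_factor(
    df: pd.DataFrame, name: str, schema_map: dict[str, VariableSchema]
) -> tuple[np.ndarray, list[str]]:
    var = schema_map.get(name)
    if var is None:
        raise SchemaError(f"unknown design variable {name!r}")
    col = df[name]
    if var.is_categorical:
        levels = var.levels[1:]  # first level is the reference
        mat = np.column_stack([(col.to_numpy() == lev).astype(float) for lev in levels])
        names = [f"{name}={lev}" for lev in levels]
        return mat, names
    return col.to_numpy(dtype=float)[:, None], [name]


def expand_term(
    df: pd.DataFrame, term: str, schema_map: dict[str, VariableSchema]
) -> tuple[np.ndarray, list[str]]:
    parts = term.split(":")
    mat, names = _expand_factor(df, parts[0], schema_map)
    for part in parts[1:]:
        m2, n2 = _expand_factor(df, part, schema_map)
        mat = np.einsum("ij,ik->ijk", mat, m2).reshape(len(df), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
    return mat, names


def build_design(
    df: pd.DataFrame,
    terms: list[str],
    schema_map: dict[str, VariableSchema],
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Return (X, column names, term -> column-index map)."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    spans: dict[str, list[int]] = {}
    if add_intercept:
        blocks.append(np.ones((len(df), 1)))
        names.append("const")
    for term in terms:
        mat, block_names = expand_term(df, term, schema_map)
        start = sum(b.shape[1] for b in blocks)
        spans[term] = list(range(start, start + mat.shape[1]))
        blocks.append(mat)
        names.extend(block_names)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return X, names, spans


def indicator_matrix(
    df: pd.DataFrame, names: list[str], schema_map: dict[str, VariableSchema]
) -> tuple[np.ndarray, list[str]]:
    """Numeric encoding of a variable block: continuous columns as-is,
    categoricals as reference-dropped indicators."""
    blocks, out_names = [], []
    for name in names:
        mat, block_names = _expand_factor(df, name, schema_map)
        blocks.append(mat)
        out_names.extend(block_names)
    X = np.hstack(blocks) if blocks else np.empty((len(df), 0))
    return X, out_names
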