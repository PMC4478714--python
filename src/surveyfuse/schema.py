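"""Survey data model: variable schemas, typed survey tables and delimited-text I/O.

Statistical matching works with two rectangular surveys sharing a block of
*common* (bridge) variables ``X``: a small *donor* survey that additionally
carries the *specific* (fusing) variables ``Y`` to be transferred, and a large
*recipient* survey observed on ``X`` only.  Because survey codings such as
``1='Female'`` are ambiguous without metadata, every table carries an explicit
schema (continuous vs categorical, category levels, roles) and no type
inference is ever performed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ROLE_COMMON = "common"
ROLE_SPECIFIC = "specific"
ROLE_IDENTIFIER = "identifier"
_ROLES = (ROLE_COMMON, ROLE_SPECIFIC, ROLE_IDENTIFIER)

KIND_CONTINUOUS = "continuous"
KIND_CATEGORICAL = "categorical"
_KINDS = (KIND_CONTINUOUS, KIND_CATEGORICAL)


class SchemaError(ValueError):
    """A variable schema or a fusion specification is inconsistent."""


class SurveyDataError(ValueError):
    """Survey data violate their declared schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Metadata for one survey variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema set.
    role : {'common', 'specific', 'identifier'}
        ``common`` variables are observed in both files and link them;
        ``specific`` variables exist only in the donor file and are the
        target of the imputation.
    kind : {'continuous', 'categorical'}
    levels : tuple of str
        Ordered category labels (categorical only).
    ordered : bool
        Whether the categorical levels carry an ordering (used to pick
        rank-based association measures).
    units : str
        Free-text units (cm, kg, mmHg, mg/dL, ...), informational.
    codes : mapping
        Optional alias map from raw file tokens (e.g. numeric survey codes
        ``"1"``) to level labels.
    """

    name: str
    role: str = ROLE_COMMON
    kind: str = KIND_CONTINUOUS
    levels: tuple[str, ...] = ()
    ordered: bool = False
    units: str = ""
    codes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemaError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.kind not in _KINDS:
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if self.kind == KIND_CATEGORICAL:
            if not self.levels:
                raise SchemaError(f"categorical variable {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"variable {self.name!r}: duplicate levels")
        elif self.levels:
            raise SchemaError(f"continuous variable {self.name!r} cannot have levels")
        bad = set(self.codes.values()) - set(self.levels)
        if bad:
            raise SchemaError(f"variable {self.name!r}: code targets {bad} not in levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind == KIND_CATEGORICAL


def check_schema_set(schema: Sequence[VariableSchema]) -> dict[str, VariableSchema]:
    """Validate name uniqueness and return a name->schema map."""
    out: dict[str, VariableSchema] = {}
    for var in schema:
        if var.name in out:
            raise SchemaError(f"duplicate variable name {var.name!r}")
        out[var.name] = var
    return out


@dataclass(frozen=True)
class FusionSpec:
    """The X/Y partition of a fusion problem.

    ``common_names`` are the bridge variables present in both files;
    ``specific_names`` are the variables to impute (donor only).
    """

    common_names: tuple[str, ...]
    specific_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "common_names", tuple(self.common_names))
        object.__setattr__(self, "specific_names", tuple(self.specific_names))
        if not self.common_names or not self.specific_names:
            raise SchemaError("common and specific name lists must be non-empty")
        overlap = set(self.common_names) & set(self.specific_names)
        if overlap:
            raise SchemaError(f"variables {sorted(overlap)} are both common and specific")

    def validate_against(
        self,
        donor_schema: Sequence[VariableSchema],
        recipient_schema: Sequence[VariableSchema] | None = None,
    ) -> None:
        donor_names = set(check_schema_set(donor_schema))
        missing = (set(self.common_names) | set(self.specific_names)) - donor_names
        if missing:
            raise SchemaError(f"names {sorted(missing)} not in donor schema")
        if recipient_schema is not None:
            rec_names = set(check_schema_set(recipient_schema))
            missing = set(self.common_names) - rec_names
            if missing:
                raise SchemaError(f"common names {sorted(missing)} not in recipient schema")


class SurveyTable:
    """A rectangular survey: a DataFrame plus its variable schema.

    Specific variables may be entirely missing (``NaN``) — that is how a
    recipient file is represented.  Common and identifier variables must be
    fully observed; categorical values must lie in their declared levels and
    continuous values must be finite.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        schema: Sequence[VariableSchema],
        check: bool = True,
    ) -> None:
        self._schema = list(schema)
        self._by_name = check_schema_set(self._schema)
        df = df.copy()
        for var in self._schema:
            if var.name not in df.columns:
                if var.role == ROLE_SPECIFIC:
                    df[var.name] = np.nan
                else:
                    raise SurveyDataError(f"column {var.name!r} missing from data")
            if var.kind == KIND_CONTINUOUS:
                if df[var.name].dtype != np.float64:
                    df[var.name] = pd.to_numeric(df[var.name], errors="coerce")
            else:
                col = df[var.name]
                if col.dtype != object:
                    df[var.name] = col.where(col.isna(), col.astype(str))
        self._df = df[[v.name for v in self._schema]]
        if not self._df.index.is_unique:
            raise SurveyDataError("row identifiers must be unique")
        if check:
            self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def schema(self) -> list[VariableSchema]:
        return list(self._schema)

    @property
    def n(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return self.n

    def variable(self, name: str) -> VariableSchema:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def names(self, role: str | None = None) -> list[str]:
        return [v.name for v in self._schema if role is None or v.role == role]

    @property
    def common_names(self) -> list[str]:
        return self.names(ROLE_COMMON)

    @property
    def specific_names(self) -> list[str]:
        return self.names(ROLE_SPECIFIC)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for var in self._schema:
            col = self._df[var.name]
            missing = col.isna()
            if missing.any() and var.role != ROLE_SPECIFIC:
                row = self._df.index[missing][0]
                raise SurveyDataError(
                    f"variable {var.name!r}: missing value at row {row!r} "
                    f"(only specific variables may be missing)"
                )
            if var.kind == KIND_CONTINUOUS:
                vals = col.to_numpy(dtype=float)
                bad = ~np.isfinite(vals) & ~np.isnan(vals)
                if bad.any():
                    row = self._df.index[bad][0]
                    raise SurveyDataError(
                        f"variable {var.name!r}: non-finite value at row {row!r}"
                    )
            else:
                ok = col.isin(var.levels) | missing
                if not ok.all():
                    row = self._df.index[~ok][0]
                    raise SurveyDataError(
                        f"variable {var.name!r}: value {col.loc[row]!r} at row {row!r} "
                        f"not in levels {list(var.levels)}"
                    )

    def is_complete(self, names: Iterable[str] | None = None) -> bool:
        names = list(names) if names is not None else [v.name for v in self._schema]
        return not self._df[names].isna().any().any()

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "SurveyTable":
        return SurveyTable(self._df.copy(), self._schema, check=False)

    def take(self, index) -> "SurveyTable":
        return SurveyTable(self._df.loc[index], self._schema, check=False)

    def with_columns(self, updates: Mapping[str, object]) -> "SurveyTable":
        df = self._df.copy()
        for name, values in updates.items():
            df[name] = values
        return SurveyTable(df, self._schema)

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, path, delimiter: str = ",", na_token: str = "") -> None:
        df = self._df.copy()
        df.insert(0, "_row_id", self._df.index)
        df.to_csv(path, sep=delimiter, index=False, na_rep=na_token)


def _schema_from_mapping(entry: Mapping) -> VariableSchema:
    return VariableSchema(
        name=str(entry["name"]),
        role=entry.get("role", ROLE_COMMON),
        kind=entry.get("kind", KIND_CONTINUOUS),
        levels=tuple(str(v) for v in entry.get("levels", ()) or ()),
        ordered=bool(entry.get("ordered", False)),
        units=entry.get("units", ""),
        codes={str(k): str(v) for k, v in (entry.get("codes") or {}).items()},
    )


def load_schema_config(path) -> tuple[list[VariableSchema], dict]:
    """Read a YAML schema config; returns (schema list, full config mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    schema = [_schema_from_mapping(e) for e in cfg["variables"]]
    check_schema_set(schema)
    return schema, cfg


def load_survey(
    path,
    schema: Sequence[VariableSchema],
    delimiter: str = ",",
    na_token: str = "",
    id_column: str = "_row_id",
) -> SurveyTable:
    """Load a delimited-text survey against an explicit schema.

    Out-of-level categorical tokens and non-numeric continuous tokens raise a
    :class:`SurveyDataError` naming the offending row and column; nothing is
    silently coerced.  The ``na_token`` (default: empty field) marks
    "not collected" and is only allowed in the specific block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_name = check_schema_set(schema)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SurveyDataError(f"{path}: empty file, no header") from None
        missing = set(by_name) - set(header)
        if missing:
            raise SurveyDataError(f"{path}: header missing schema columns {sorted(missing)}")
        col_pos = {name: header.index(name) for name in by_name}
        id_pos = header.index(id_column) if id_column in header else None
        records: dict[str, list] = {name: [] for name in by_name}
        ids: list = []
        for rownum, raw in enumerate(reader, start=2):
            ids.append(raw[id_pos] if id_pos is not None else rownum - 2)
            for name, var in by_name.items():
                token = raw[col_pos[name]].strip()
                if token == na_token:
                    if var.role != ROLE_SPECIFIC:
                        raise SurveyDataError(
                            f"{path}: line {rownum}, column {name!r}: missing value "
                            f"outside the specific block"
                        )
                    records[name].append(np.nan)
                    continue
                if var.kind == KIND_CONTINUOUS:
                    try:
                        records[name].append(float(token))
                    except ValueError:
                        raise SurveyDataError(
                            f"{path}: line {rownum}, column {name!r}: "
                            f"non-numeric token {token!r}"
                        ) from None
                else:
                    label = var.codes.get(token, token)
                    if label not in var.levels:
                        raise SurveyDataError(
                            f"{path}: line {rownum}, column {name!r}: value {token!r} "
                            f"not in levels {list(var.levels)}"
                        )
                    records[name].append(label)
    df = pd.DataFrame(records, index=pd.Index(ids, name="_row_id"))
    return SurveyTable(df, schema)


def split_donor_recipient(
    table: SurveyTable, donor_flag: str
) -> tuple[SurveyTable, SurveyTable]:
    """Partition one combined table into a donor file and a recipient file.

    ``donor_flag`` names a binary indicator column (boolean, 0/1 or a
    two-level categorical); flagged rows become donors and must be complete
    on the specific block, the rest become recipients with the specific
    block blanked.
    """
    col = table.df[donor_flag]
    uniq = set(col.dropna().unique().tolist())
    truthy = {True, 1, 1.0, "1", "true", "True", "Yes", "yes"}
    if not uniq <= (truthy | {False, 0, 0.0, "0", "false", "False", "No", "no"}):
        raise SurveyDataError(
            f"donor flag {donor_flag!r} is not binary (values {sorted(map(str, uniq))})"
        )
    mask = col.isin(list(truthy)).to_numpy()
    if not mask.any():
        raise SurveyDataError("donor partition is empty")
    spec_names = table.specific_names
    donor_df = table.df.loc[mask]
    if donor_df[spec_names].isna().any().any():
        bad = donor_df.index[donor_df[spec_names].isna().any(axis=1)][0]
        raise SurveyDataError(f"donor row {bad!r} has missing specific values")
    recipient_df = table.df.loc[~mask].copy()
    recipient_df[spec_names] = np.nan
    if not (~mask).any():
        warnings.warn("all rows flagged as donors: recipient table is empty")
    donor = SurveyTable(donor_df, table.schema, check=False)
    recipient = SurveyTable(recipient_df, table.schema, check=False)
    return donor, recipient


def validate_fusion_inputs(
    donor: SurveyTable, recipient: SurveyTable, spec: FusionSpec
) -> dict:
    """Pure diagnostics on donor coverage of the recipient common block.

    A valid transfer needs the donor file to represent the parent population:
    every recipient category must be present among donors, and recipient
    continuous ranges should be covered (values outside the donor range can
    only be imputed by extrapolation).  Nothing here raises; downstream
    engines decide whether uncovered levels are fatal.
    """
    spec.validate_against(donor.schema, recipient.schema)
    uncovered: dict[str, list[str]] = {}
    overlap: dict[str, dict] = {}
    for name in spec.common_names:
        var = donor.variable(name)
        d, r = donor.df[name], recipient.df[name]
        if var.is_categorical:
            missing = sorted(set(r.dropna().unique()) - set(d.dropna().unique()))
            if missing:
                uncovered[name] = missing
        else:
            d_lo, d_hi = float(d.min()), float(d.max())
            r_lo, r_hi = float(r.min()), float(r.max())
            entry = {
                "donor_range": (d_lo, d_hi),
                "recipient_range": (r_lo, r_hi),
                "extrapolation_low": (r_lo, d_lo) if r_lo < d_lo else None,
                "extrapolation_high": (d_hi, r_hi) if r_hi > d_hi else None,
            }
            overlap[name] = entry
    return {"uncovered_levels": uncovered, "continuous_overlap": overlap}
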