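"""Data model, CSV ingestion/emission, and permeability-unit transforms.

The central containers are :class:`CompoundRecord` (one compound: identity,
observed log10 permeability coefficient, pKa list, named descriptors) and
:class:`DescriptorTable` (an n x p numeric matrix with explicit missing
markers and an optional autoscaling state).  Permeability coefficients Kp are
expressed in cm/h and modelled on a log10 scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "DescriptorTable",
    "NormParams",
    "read_descriptor_table",
    "write_descriptor_table",
    "permeability_coefficient",
    "log_transform",
    "antilog",
    "MISSING_TOKENS",
    "RESERVED_COLUMNS",
]

#: CSV cell values (case-insensitive, after stripping) parsed as missing.
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Header names with a reserved role when no explicit schema is supplied.
RESERVED_COLUMNS = {
    "id": "id",
    "name": "name",
    "smiles": "smiles",
    "cas": "cas",
    "log_kp": "response",
    "pka_acid": "pka_acid",
    "pka_base": "pka_base",
}


@dataclass
class CompoundRecord:
    """One compound: identity, response, ionization constants, descriptors.

    ``log_kp_obs`` is the observed log10 Kp (cm/h); ``pka_values`` is a list
    of ``(pka, tag)`` pairs with tag ``"acid"`` or ``"base"``; ``descriptors``
    maps descriptor name to a float, with ``nan`` marking a missing value
    (keys are identical across all records of one table).
    """

    id: str
    log_kp_obs: Optional[float] = None
    name: Optional[str] = None
    cas: Optional[str] = None
    smiles: Optional[str] = None
    pka_values: list[tuple[float, str]] = field(default_factory=list)
    descriptors: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class NormParams:
    """Per-descriptor centering/scaling constants (mean, sample SD)."""

    means: dict[str, float]
    scales: dict[str, float]

    def covers(self, names: Iterable[str]) -> bool:
        return all(n in self.means and n in self.scales for n in names)


@dataclass
class DescriptorTable:
    """n x p descriptor matrix with names, ids and normalization state.

    ``values`` is float with ``nan`` as the missing marker.  When
    ``normalized`` is true, ``norm_params`` holds the means and sample
    standard deviations (n-1 denominator) used for autoscaling.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    normalized: bool = False
    norm_params: Optional[NormParams] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.compound_ids) or p != len(self.descriptor_names):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.compound_ids)} ids x {len(self.descriptor_names)} names"
            )
        if len(set(self.compound_ids)) != n:
            raise ValueError("duplicate compound ids")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("duplicate descriptor names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"descriptor {name!r} not in table") from None
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "DescriptorTable":
        """Column subset in the order of ``names``."""
        idx = [self.descriptor_names.index(n) for n in names]
        params = None
        if self.norm_params is not None:
            params = NormParams(
                {n: self.norm_params.means[n] for n in names},
                {n: self.norm_params.scales[n] for n in names},
            )
        return DescriptorTable(
            list(self.compound_ids), list(names), self.values[:, idx].copy(),
            normalized=self.normalized, norm_params=params,
        )

    def drop_columns(self, names: Iterable[str]) -> "DescriptorTable":
        drop = set(names)
        keep = [n for n in self.descriptor_names if n not in drop]
        return self.subset(keep)

    def take_rows(self, indices: Sequence[int]) -> "DescriptorTable":
        return replace(
            self,
            compound_ids=[self.compound_ids[i] for i in indices],
            values=self.values[list(indices), :].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.descriptor_names
        )


def _parse_cell(raw: object) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.lower() in MISSING_TOKENS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        return math.nan


def _parse_pka_cell(raw: object, tag: str) -> list[tuple[float, str]]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return []
    out = []
    for part in str(raw).split(";"):
        part = part.strip()
        if part.lower() in MISSING_TOKENS:
            continue
        out.append((float(part), tag))
    return out


def read_descriptor_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    *,
    require_response: bool = True,
) -> tuple[list[CompoundRecord], DescriptorTable]:
    """Read a compound/descriptor CSV into records plus a numeric table.

    Column roles come from ``schema`` (header name -> role in ``{"id",
    "name", "cas", "smiles", "response", "pka_acid", "pka_base",
    "descriptor", "passthrough"}``) or, absent a schema, from the reserved
    header names (``id``, ``smiles``, ``cas``, ``log_kp``, ``pka_acid``,
    ``pka_base``); every unreserved column is a numeric descriptor.
    Non-numeric descriptor cells (empty, ``NA``, ``NaN``) become missing
    markers.  Records and table share row order.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    roles: dict[str, str] = {}
    for col in df.columns:
        if schema is not None:
            roles[col] = schema.get(col, "descriptor")
        else:
            roles[col] = RESERVED_COLUMNS.get(col, "descriptor")
    id_cols = [c for c, r in roles.items() if r == "id"]
    if len(id_cols) != 1:
        raise ValueError(f"exactly one id column required, found {id_cols}")
    id_col = id_cols[0]
    resp_cols = [c for c, r in roles.items() if r == "response"]
    if require_response and not resp_cols:
        raise ValueError("no response (log_kp) column found")
    resp_col = resp_cols[0] if resp_cols else None
    desc_cols = [c for c, r in roles.items() if r == "descriptor"]

    ids = [str(v).strip() for v in df[id_col]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dupes}")

    records: list[CompoundRecord] = []
    for i, cid in enumerate(ids):
        row = df.iloc[i]
        pka: list[tuple[float, str]] = []
        for col, role in roles.items():
            if role == "pka_acid":
                pka.extend(_parse_pka_cell(row[col], "acid"))
            elif role == "pka_base":
                pka.extend(_parse_pka_cell(row[col], "base"))
        rec = CompoundRecord(
            id=cid,
            log_kp_obs=_parse_cell(row[resp_col]) if resp_col else None,
            name=_opt_str(row, roles, "name"),
            cas=_opt_str(row, roles, "cas"),
            smiles=_opt_str(row, roles, "smiles"),
            pka_values=pka,
            descriptors={c: _parse_cell(row[c]) for c in desc_cols},
        )
        records.append(rec)

    values = np.array(
        [[r.descriptors[c] for c in desc_cols] for r in records], dtype=float
    ).reshape(len(records), len(desc_cols))
    table = DescriptorTable(ids, desc_cols, values)
    return records, table


def _opt_str(row, roles: Mapping[str, str], role: str) -> Optional[str]:
    for col, r in roles.items():
        if r == role:
            v = str(row[col]).strip()
            return v if v else None
    return None


def write_descriptor_table(records: Sequence[CompoundRecord],
                           table: DescriptorTable, path) -> None:
    """Emit the records + table back to CSV (reserved header names)."""
    if [r.id for r in records] != list(table.compound_ids):
        raise ValueError("records and table row order disagree")
    data: dict[str, list] = {"id": list(table.compound_ids)}
    if any(r.name for r in records):
        data["name"] = [r.name or "" for r in records]
    if any(r.cas for r in records):
        data["cas"] = [r.cas or "" for r in records]
    if any(r.smiles for r in records):
        data["smiles"] = [r.smiles or "" for r in records]
    if any(r.log_kp_obs is not None for r in records):
        data["log_kp"] = [
            "" if r.log_kp_obs is None or math.isnan(r.log_kp_obs)
            else repr(r.log_kp_obs) for r in records
        ]
    acid = [";".join(repr(v) for v, t in r.pka_values if t == "acid")
            for r in records]
    base = [";".join(repr(v) for v, t in r.pka_values if t == "base")
            for r in records]
    if any(acid):
        data["pka_acid"] = acid
    if any(base):
        data["pka_base"] = base
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        data[name] = ["" if math.isnan(v) else repr(float(v)) for v in col]
    pd.DataFrame(data).to_csv(path, index=False)


def permeability_coefficient(j_ss: float, delta_cv: float) -> float:
    """Kp = steady-state flux / donor concentration difference (cm/h)."""
    if not delta_cv > 0:
        raise ValueError(f"concentration difference must be positive, got {delta_cv}")
    return j_ss / delta_cv


def log_transform(kp: float) -> float:
    """log10 of a positive permeability coefficient."""
    if not kp > 0:
        raise ValueError(f"Kp must be positive for a log transform, got {kp}")
    return math.log10(kp)


def antilog(log_kp: float) -> float:
    """Inverse of :func:`log_transform`: 10 ** log_kp."""
    return 10.0 ** log_kp
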