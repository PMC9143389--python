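"""Descriptor filtering, collinearity pruning, autoscaling, ion classes.

The cleaning cascade applied before model building: remove descriptors with
more than one missing value (imputing the single allowed gap by the fitting
column mean), remove near-invariant descriptors, prune collinear pairs by
squared Spearman rank correlation (r^2 > 0.64 by default), and autoscale to
zero mean / unit sample standard deviation.  Compounds are also assigned one
of four ion classes (neutral / acid / base / zwitterion) from their pKa list
relative to pH 7.

Each destructive step can append JSON-lines provenance records describing
what was dropped or imputed and why.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import DescriptorTable, NormParams

__all__ = [
    "IonClass",
    "ProvenanceLog",
    "drop_missing",
    "drop_invariant",
    "spearman_prune",
    "normalize",
    "apply_normalization",
    "assign_ion_class",
]


@dataclass(frozen=True)
class IonClass:
    """Ionization category of a compound at physiological pH."""

    value: str

    CLASSES = ("neutral", "acid", "base", "zwitterion")

    def __post_init__(self) -> None:
        if self.value not in self.CLASSES:
            raise ValueError(f"unknown ion class {self.value!r}")


class ProvenanceLog:
    """JSON-lines sink for drop/impute events."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def record(self, **event) -> None:
        self.events.append(event)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")


def drop_missing(table: DescriptorTable, max_missing: int = 1,
                 log: Optional[ProvenanceLog] = None) -> DescriptorTable:
    """Drop descriptors missing more than ``max_missing`` values.

    Descriptors at or under the allowance keep their rows, with the missing
    entries imputed by the fitting-set column mean.
    """
    values = table.values.copy()
    keep: list[str] = []
    for j, name in enumerate(table.descriptor_names):
        col = values[:, j]
        n_missing = int(np.isnan(col).sum())
        if n_missing > max_missing:
            if log:
                log.record(op="drop_missing", descriptor=name,
                           n_missing=n_missing, max_missing=max_missing)
            continue
        if n_missing:
            mean = float(np.nanmean(col))
            values[np.isnan(col), j] = mean
            if log:
                log.record(op="impute", descriptor=name,
                           n_imputed=n_missing, imputed_value=mean)
        keep.append(name)
    if not keep:
        raise ValueError("all descriptors removed by the missing-value filter")
    idx = [table.descriptor_names.index(n) for n in keep]
    return DescriptorTable(list(table.compound_ids), keep, values[:, idx])


def drop_invariant(table: DescriptorTable, min_distinct: int = 2,
                   min_variance: float = 1e-12,
                   log: Optional[ProvenanceLog] = None) -> DescriptorTable:
    """Drop descriptors with little or no discrimination between compounds."""
    keep = []
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        distinct = len(np.unique(col[~np.isnan(col)]))
        var = float(np.nanvar(col, ddof=1)) if distinct > 1 else 0.0
        if distinct < min_distinct or var <= min_variance:
            if log:
                log.record(op="drop_invariant", descriptor=name,
                           n_distinct=distinct, variance=var)
            continue
        keep.append(name)
    return table.subset(keep)


def spearman_prune(
    table: DescriptorTable,
    response: Sequence[float],
    r2_threshold: float = 0.64,
    log: Optional[ProvenanceLog] = None,
) -> tuple[DescriptorTable, list[dict]]:
    """Prune collinear descriptor pairs by squared Spearman correlation.

    Pairs with rank correlation rho^2 strictly above ``r2_threshold`` are
    resolved from the most correlated pair down: the member whose |Spearman
    correlation with the response| is lower is dropped (ties: the
    lexicographically later name goes).  Average ranks are used for ties.
    Returns the pruned table and a report of dropped pairs.
    """
    if np.isnan(table.values).any():
        raise ValueError("spearman_prune requires a table with no missing values")
    y = np.asarray(response, dtype=float)
    names = table.descriptor_names
    p = len(names)
    if p < 2:
        return table, []
    # Spearman = Pearson on average ranks; rankdata averages ties
    ranks = np.column_stack([
        stats.rankdata(table.values[:, j]) for j in range(p)])
    rho = np.corrcoef(ranks, rowvar=False)
    y_rank = stats.rankdata(y)
    resp_rho = np.array([
        np.corrcoef(ranks[:, j], y_rank)[0, 1] for j in range(p)])
    pairs = []
    for a in range(p):
        for b in range(a + 1, p):
            r2 = rho[a, b] ** 2
            if r2 > r2_threshold:
                pairs.append((r2, names[a], names[b]))
    # resolve strongest collinearity first; name order breaks exact r2 ties
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    report: list[dict] = []
    for r2, na, nb in pairs:
        if na in dropped or nb in dropped:
            continue
        ca = abs(resp_rho[names.index(na)])
        cb = abs(resp_rho[names.index(nb)])
        if ca > cb:
            victim = nb
        elif cb > ca:
            victim = na
        else:
            victim = max(na, nb)
        dropped.add(victim)
        ev = dict(op="spearman_prune", pair=[na, nb], pair_r2=float(r2),
                  dropped=victim,
                  response_abs_rho={na: float(ca), nb: float(cb)})
        report.append(ev)
        if log:
            log.record(**ev)
    return table.drop_columns(dropped), report


def normalize(table: DescriptorTable) -> DescriptorTable:
    """Autoscale every descriptor to mean 0 and unit sample SD (n-1).

    chi_ij = (x_ij - <x_j>) / s_j, with s_j the sample standard deviation.
    The centering/scaling constants are stored so external sets can be put
    on the training scale with :func:`apply_normalization`.
    """
    if np.isnan(table.values).any():
        raise ValueError("normalize requires a table with no missing values")
    means, scales = {}, {}
    out = table.values.copy()
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        m = float(np.mean(col))
        s = float(np.std(col, ddof=1))
        if s <= 0:
            raise ValueError(f"descriptor {name!r} has zero variance; "
                             "remove it before autoscaling")
        out[:, j] = (col - m) / s
        means[name], scales[name] = m, s
    return DescriptorTable(
        list(table.compound_ids), list(table.descriptor_names), out,
        normalized=True, norm_params=NormParams(means, scales),
    )


def apply_normalization(table: DescriptorTable,
                        params: NormParams) -> DescriptorTable:
    """Autoscale with *supplied* constants (training-set means/scales).

    Used for test and external compounds so they are transformed with the
    fitting-set parameters rather than their own statistics; values outside
    the training range map to finite values without clipping.
    """
    if not params.covers(table.descriptor_names):
        missing = [n for n in table.descriptor_names if n not in params.means]
        raise ValueError(f"normalization parameters missing for {missing}")
    out = table.values.copy()
    for j, name in enumerate(table.descriptor_names):
        out[:, j] = (table.values[:, j] - params.means[name]) / params.scales[name]
    return DescriptorTable(
        list(table.compound_ids), list(table.descriptor_names), out,
        normalized=True, norm_params=params,
    )


def assign_ion_class(pka_values: Sequence[tuple[float, str]]) -> IonClass:
    """Assign neutral / acid / base / zwitterion from a pKa list.

    Precedence (making the four overlapping clauses a partition):
    an empty list is neutral; a compound whose strongest acid-tagged pKa is
    above 7 while its strongest base-tagged pKa is below 7 is a zwitterion;
    otherwise all pKa <= 7 means acid, all pKa >= 7 means base, and anything
    else is neutral.
    """
    if not pka_values:
        return IonClass("neutral")
    for v, tag in pka_values:
        if tag not in ("acid", "base"):
            raise ValueError(f"pKa tag must be 'acid' or 'base', got {tag!r}")
    acids = [v for v, t in pka_values if t == "acid"]
    bases = [v for v, t in pka_values if t == "base"]
    if acids and bases and max(acids) > 7 and min(bases) < 7:
        return IonClass("zwitterion")
    all_vals = [v for v, _ in pka_values]
    if all(v <= 7 for v in all_vals):
        return IonClass("acid")
    if all(v >= 7 for v in all_vals):
        return IonClass("base")
    return IonClass("neutral")
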