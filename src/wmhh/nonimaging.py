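"""Declarative harmonisation of heterogeneous covariate tables.

Different cohorts record the same quantity in different raw units (activity
as h/week vs day/week x min/day, height in m vs cm, smoking as a binary vs a
four-class status).  A :class:`Ruleset` declares, per variable, how to bring
a cohort's raw table into the common target units; :func:`compare_cohorts`
then tests the harmonised cohorts variable-by-variable (t-test for
continuous, chi-square for categorical variables).

Rule kinds:

* ``passthrough`` — copy unchanged;
* ``linear_rescale`` — ``scale * x + offset`` (e.g. min/day -> h/week via
  scale 7/60);
* ``combine_fields`` — row-wise product or sum of several raw fields times a
  scale (e.g. day/week x min/day / 60 -> h/week); a missing operand
  propagates to a missing result;
* ``categorical_collapse`` — total mapping of declared source classes onto
  target classes; undeclared values are an error, never silently bucketed.

No imputation is performed anywhere: statistics run on complete cases and
the exclusion count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .harmonisation_stats import chi_square, independent_ttest, significance_marker

__all__ = [
    "ConversionRule",
    "Ruleset",
    "CohortComparison",
    "apply_rules",
    "combine_fields",
    "compare_cohorts",
    "complete_cases",
    "load_ruleset",
    "default_ruleset",
]

_KINDS = ("passthrough", "linear_rescale", "combine_fields", "categorical_collapse")


@dataclass
class ConversionRule:
    variable: str
    kind: str
    target_unit: str = ""
    source_unit: str | None = None
    source_field: str | None = None  # raw column name when it differs
    scale: float = 1.0
    offset: float = 0.0
    fields: tuple = ()
    combiner: str = "product"  # for combine_fields: "product" or "sum"
    mapping: dict = field(default_factory=dict)
    optional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "linear_rescale" and self.scale == 0:
            raise ValueError("linear_rescale scale must be non-zero")
        if self.kind == "combine_fields" and not self.fields:
            raise ValueError("combine_fields rule needs operand fields")
        if self.kind == "categorical_collapse" and not self.mapping:
            raise ValueError("categorical_collapse rule needs a mapping")

    def invert(self) -> "ConversionRule":
        if self.kind == "passthrough":
            return self
        if self.kind == "linear_rescale":
            return ConversionRule(
                variable=self.variable, kind="linear_rescale",
                scale=1.0 / self.scale, offset=-self.offset / self.scale,
                target_unit=self.source_unit or "", source_unit=self.target_unit,
            )
        raise ValueError(f"rule kind {self.kind!r} has no declared inverse")


@dataclass
class Ruleset:
    rules: dict  # variable -> ConversionRule

    def __iter__(self):
        return iter(self.rules.values())

    def __getitem__(self, variable: str) -> ConversionRule:
        return self.rules[variable]


def combine_fields(frame: pd.DataFrame, fields: Sequence[str], combiner: str = "product",
                   scale: float = 1.0) -> pd.Series:
    """Row-wise combination of raw fields; missing operands propagate."""
    for f in fields:
        if f not in frame.columns:
            raise KeyError(f"operand field {f!r} not present")
        if not pd.api.types.is_numeric_dtype(frame[f]):
            raise TypeError(f"operand field {f!r} is not numeric")
    ops = [frame[f].astype(float) for f in fields]
    if combiner == "product":
        out = ops[0]
        for o in ops[1:]:
            out = out * o
    elif combiner == "sum":
        out = sum(ops)
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return out * scale


def apply_rules(raw_table: pd.DataFrame, ruleset: Ruleset,
                units: Mapping[str, str] | None = None):
    """Harmonise a raw covariate table.

    Returns ``(table, units)`` where ``units`` maps each output variable to
    its target unit.  Source-unit annotations, when supplied, are checked
    against the rules' declared source units.
    """
    out = pd.DataFrame(index=raw_table.index)
    out_units: dict[str, str] = {}
    claimed = set()
    for r in ruleset:
        claimed.add(r.source_field or r.variable)
        claimed.update(r.fields)
    for col in raw_table.columns:
        if col not in claimed:
            out[col] = raw_table[col]
            if units and col in units:
                out_units[col] = units[col]
    for rule in ruleset:
        src = (rule.source_field or rule.variable) if rule.kind != "combine_fields" else None
        if rule.kind == "combine_fields":
            missing = [f for f in rule.fields if f not in raw_table.columns]
            if missing:
                if rule.optional:
                    continue
                raise KeyError(f"variable {rule.variable!r}: missing operand(s) {missing}")
            out[rule.variable] = combine_fields(
                raw_table, rule.fields, rule.combiner, rule.scale
            )
        else:
            if src not in raw_table.columns:
                if rule.optional:
                    continue
                raise KeyError(f"variable {src!r} not present in table")
            if units and rule.source_unit and units.get(src) and units[src] != rule.source_unit:
                raise ValueError(
                    f"variable {src!r}: table unit {units[src]!r} does not match "
                    f"rule source unit {rule.source_unit!r}"
                )
            col = raw_table[src]
            if rule.kind == "passthrough":
                out[rule.variable] = col
            elif rule.kind == "linear_rescale":
                if not pd.api.types.is_numeric_dtype(col):
                    raise TypeError(f"variable {src!r} is not numeric")
                out[rule.variable] = col.astype(float) * rule.scale + rule.offset
            elif rule.kind == "categorical_collapse":
                values = set(col.dropna().astype(str).unique())
                unmapped = sorted(values - set(rule.mapping))
                if unmapped:
                    raise ValueError(
                        f"variable {src!r}: unmapped categorical value(s) {unmapped}"
                    )
                out[rule.variable] = col.astype(str).where(col.notna()).map(rule.mapping)
        out_units[rule.variable] = rule.target_unit
    return out, out_units


def complete_cases(table: pd.DataFrame):
    """Drop rows with any missing harmonised variable; report the count."""
    filtered = table.dropna()
    return filtered, int(len(table) - len(filtered))


@dataclass
class CohortComparison:
    table: pd.DataFrame  # variable, test, statistic, p, marker
    n_excluded_a: int
    n_excluded_b: int
    skipped: list


def compare_cohorts(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    *, id_columns: Sequence[str] = ("subject_id",)) -> CohortComparison:
    """Variable-by-variable comparison of two harmonised cohorts.

    Continuous variables are compared with an independent t-test,
    categorical ones with a chi-square test on the contingency table.
    Complete-case filtering is applied first and the exclusion counts are
    reported.  Variables present in only one table are reported as skipped.
    """
    a, n_ex_a = complete_cases(table_a)
    b, n_ex_b = complete_cases(table_b)
    common = [c for c in a.columns if c in b.columns and c not in id_columns]
    skipped = sorted(
        (set(a.columns) ^ set(b.columns)) - set(id_columns)
    )
    rows = []
    for col in common:
        sa, sb = a[col], b[col]
        if pd.api.types.is_numeric_dtype(sa) and pd.api.types.is_numeric_dtype(sb):
            try:
                res = independent_ttest(sa.to_numpy(float), sb.to_numpy(float))
                test = "t"
            except ValueError:
                rows.append({"variable": col, "test": "t", "statistic": 0.0,
                             "p": 1.0, "marker": "", "note": "degenerate"})
                continue
        else:
            levels = sorted(set(sa.astype(str)) | set(sb.astype(str)))
            counts = np.array([
                [int((sa.astype(str) == lv).sum()) for lv in levels],
                [int((sb.astype(str) == lv).sum()) for lv in levels],
            ], dtype=float)
            counts = counts[:, counts.sum(axis=0) > 0]
            if counts.shape[1] < 2:
                rows.append({"variable": col, "test": "chi2", "statistic": 0.0,
                             "p": 1.0, "marker": "", "note": "single_level"})
                continue
            res = chi_square(counts)
            test = "chi2"
        rows.append({"variable": col, "test": test, "statistic": res.statistic,
                     "p": res.p, "marker": significance_marker(res.p), "note": ""})
    return CohortComparison(pd.DataFrame(rows), n_ex_a, n_ex_b, skipped)


def _rules_from_dict(spec: Mapping) -> Ruleset:
    rules = {}
    for var, body in spec.items():
        body = dict(body)
        kind = body.pop("kind")
        rules[var] = ConversionRule(
            variable=var, kind=kind,
            target_unit=body.pop("target_unit", ""),
            source_unit=body.pop("source_unit", None),
            source_field=body.pop("source_field", None),
            scale=float(body.pop("scale", 1.0)),
            offset=float(body.pop("offset", 0.0)),
            fields=tuple(body.pop("fields", ())),
            combiner=body.pop("combiner", "product"),
            mapping=dict(body.pop("mapping", {})),
            optional=bool(body.pop("optional", False)),
        )
        if body:
            raise ValueError(f"rule {var!r}: unknown keys {sorted(body)}")
    return Ruleset(rules)


def load_ruleset(path_or_dict, section: str | None = None) -> Ruleset:
    """Load a ruleset from a YAML file (or an already-parsed mapping)."""
    if isinstance(path_or_dict, Mapping):
        spec = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            spec = yaml.safe_load(fh)
    if section is not None:
        spec = spec[section]
    if "variables" in spec:
        spec = spec["variables"]
    return _rules_from_dict(spec)


def default_ruleset(style: str) -> Ruleset:
    """Built-in ruleset for the synthetic cohorts' raw-unit conventions."""
    text = resources.files("wmhh").joinpath("data/default_rules.yaml").read_text()
    spec = yaml.safe_load(text)
    if style not in spec:
        raise KeyError(f"no default ruleset for style {style!r}")
    return _rules_from_dict(spec[style]["variables"])
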