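"""Regression specification and design-matrix construction.

Treatment coding with declared (default: alphabetically first) reference
levels.  Interaction terms are written ``"a:b:c"`` and expand to the full
product basis of the participating factors' non-reference dummies.  Boolean
position flags are treated as two-level factors with ``False`` as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["RegressionSpec", "DesignMatrix", "build_design", "squeeze_to_open_interval"]

DEFAULT_FIXED_TERMS = [
    "after_argument",
    "after_verb",
    "role",
    "language",
    "nominality",
    "verb_class",
    "nominality:role",
    "after_argument:after_verb:role:language",
]


@dataclass
class RegressionSpec:
    fixed_terms: list[str] = field(default_factory=lambda: list(DEFAULT_FIXED_TERMS))
    group: str | None = "sentence_id"
    group_slopes: list[str] = field(default_factory=lambda: ["after_argument", "after_verb", "role"])
    group_interaction_slope: bool = False  # random slope for the 3-way interaction (off by default)
    reference_levels: dict[str, str] = field(default_factory=dict)
    slope_prior_sd: float = 1.0
    intercept_prior_sd: float = 5.0
    group_sd_prior_df: float = 3.0
    group_sd_prior_scale: float = 2.5
    phi_prior: str = "half_normal"  # half_normal (sigma=10) | exponential (rate=1)
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    target_accept: float = 0.8
    seed: int = 0
    check_diagnostics: bool = True
    shared_warmup: bool = True  # adapt tuning on one chain, reuse for the rest
    centered_groups: bool = False  # centered group effects (better when groups are data-dominated)

    def __post_init__(self):
        if self.phi_prior not in ("half_normal", "exponential"):
            raise ValueError(f"unknown phi prior {self.phi_prior!r}")


def squeeze_to_open_interval(p, n: int):
    """Map [0,1] responses into (0,1): ``(p * (n - 1) + 0.5) / n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (np.asarray(p, dtype=float) * (n - 1) + 0.5) / n


@dataclass
class DesignMatrix:
    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    col_specs: list[dict[str, str]]          # factor -> required level, {} = intercept
    factor_levels: dict[str, list[str]]      # reference level first
    group_codes: np.ndarray | None           # (n,) int codes, or None
    group_labels: list[str] | None
    Z: np.ndarray | None                     # (n, K) random-effect covariates
    re_names: list[str] | None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels) if self.group_labels else 0

    def row_for(self, values: Mapping[str, str]) -> np.ndarray:
        """Fixed-effect row vector for a cell given its factor levels."""
        vals = {f: _level_str(v) for f, v in values.items()}
        for f, lvl in vals.items():
            if f in self.factor_levels and lvl not in self.factor_levels[f]:
                raise KeyError(f"unseen level {lvl!r} for factor {f!r}")
        row = np.zeros(len(self.colnames))
        for j, spec in enumerate(self.col_specs):
            if all(f in vals and vals[f] == lvl for f, lvl in spec.items()):
                row[j] = 1.0
        return row


def _level_str(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    return str(v)


def _term_factors(term: str) -> list[str]:
    return term.split(":")


def build_design(records: pd.DataFrame, spec: RegressionSpec) -> DesignMatrix:
    """Build the response vector, treatment-coded fixed-effect matrix and
    grouping structure from a predictability records table."""
    if len(records) == 0:
        raise ValueError("empty records table")
    if "p_correct" not in records.columns:
        raise ValueError("records table lacks a p_correct column")
    factors = sorted({f for term in spec.fixed_terms for f in _term_factors(term)})
    levels: dict[str, list[str]] = {}
    codes: dict[str, pd.Series] = {}
    for f in factors:
        if f not in records.columns:
            raise ValueError(f"records table lacks factor column {f!r}")
        col = records[f].map(_level_str)
        lvls = sorted(col.unique())
        if len(lvls) < 2:
            raise ValueError(f"factor {f!r} has a single level {lvls[0]!r}")
        ref = _level_str(spec.reference_levels.get(f, lvls[0]))
        if ref not in lvls:
            raise ValueError(f"declared reference level {ref!r} not found for factor {f!r}")
        levels[f] = [ref] + [l for l in lvls if l != ref]
        codes[f] = col

    colnames = ["Intercept"]
    col_specs: list[dict[str, str]] = [{}]
    seen = {frozenset()}
    for term in spec.fixed_terms:
        fs = _term_factors(term)
        dummy_sets = [[(f, lvl) for lvl in levels[f][1:]] for f in fs]
        for combo in product(*dummy_sets):
            key = frozenset(combo)
            if key in seen:
                continue
            seen.add(key)
            col_specs.append(dict(combo))
            colnames.append(":".join(f"{f}[{lvl}]" for f, lvl in combo))

    n = len(records)
    X = np.zeros((n, len(colnames)))
    X[:, 0] = 1.0
    for j, cspec in enumerate(col_specs[1:], start=1):
        ind = np.ones(n, dtype=bool)
        for f, lvl in cspec.items():
            ind &= (codes[f] == lvl).to_numpy()
        X[:, j] = ind

    y = squeeze_to_open_interval(records["p_correct"].to_numpy(dtype=float), n)

    group_codes = group_labels = Z = re_names = None
    if spec.group is not None and spec.group in records.columns:
        cat = pd.Categorical(records[spec.group].astype(str))
        group_codes = np.asarray(cat.codes, dtype=np.intp)
        group_labels = list(cat.categories)
        zcols, re_names_l = [np.ones(n)], ["Intercept"]
        slope_cols: list[np.ndarray] = []
        for s in spec.group_slopes:
            if s not in records.columns:
                continue
            col = records[s].map(_level_str)
            lvls = levels.get(s) or sorted(col.unique())
            for lvl in lvls[1:]:
                v = (col == lvl).to_numpy(dtype=float)
                zcols.append(v)
                slope_cols.append(v)
                re_names_l.append(f"{s}[{lvl}]")
        if spec.group_interaction_slope and len(slope_cols) >= 2:
            prod_col = np.ones(n)
            for v in slope_cols:
                prod_col = prod_col * v
            zcols.append(prod_col)
            re_names_l.append("interaction")
        Z = np.column_stack(zcols)
        re_names = re_names_l

    return DesignMatrix(
        y=y,
        X=X,
        colnames=colnames,
        col_specs=col_specs,
        factor_levels=levels,
        group_codes=group_codes,
        group_labels=group_labels,
        Z=Z,
        re_names=re_names,
    )
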