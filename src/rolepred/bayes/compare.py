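"""Model comparison, language contrasts and stimulus-condition regression."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .design import RegressionSpec, build_design
from .glmm import PosteriorSummary, fit_beta_hierarchical

__all__ = ["compare_loo_stacking", "pairwise_language_contrasts", "fit_stimulus_regression"]


def compare_loo_stacking(
    fits: Sequence[PosteriorSummary], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """PSIS-LOO elpd and stacking weights for models fit to the same response.

    Returns one row per model with ``elpd_loo``, ``weight`` (simplex) and the
    worst Pareto-k diagnostic.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    y0 = fits[0].design.y
    for f in fits[1:]:
        if f.design.y.shape != y0.shape or not np.allclose(f.design.y, y0):
            raise ValueError("fits were not computed on identical response vectors")
    names = list(names) if names is not None else [f"model_{i}" for i in range(len(fits))]
    idatas = {n: f.idata for n, f in zip(names, fits)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(idatas, ic="loo", method="stacking")
        k_max = {}
        for n, f in zip(names, fits):
            loo = az.loo(f.idata, pointwise=True)
            k_max[n] = float(np.max(loo.pareto_k.values))
    out = cmp.reset_index().rename(columns={"index": "model"})
    if "model" not in out.columns:  # arviz versions name the index differently
        out = out.rename(columns={out.columns[0]: "model"})
    out["pareto_k_max"] = out["model"].map(k_max)
    return out[["model", "rank", "elpd_loo", "weight", "pareto_k_max"]]


def pairwise_language_contrasts(
    fit: PosteriorSummary,
    cells: Sequence[Mapping[str, str]],
    languages: Sequence[str] | None = None,
    language_factor: str = "language",
    support_threshold: float = 0.95,
) -> pd.DataFrame:
    """Draw-wise differences of cell means between all ordered language pairs.

    Each ``cell`` fixes the non-language factors.  ``suppressed`` marks
    contrasts whose directional posterior mass (the larger of P(diff > 0)
    and P(diff < 0)) falls below ``support_threshold``.
    """
    if languages is None:
        if language_factor not in fit.design.factor_levels:
            raise KeyError(f"fit has no factor {language_factor!r}")
        languages = fit.design.factor_levels[language_factor]
    rows = []
    for cell in cells:
        draws = {
            lang: fit.cell_mean_draws({**cell, language_factor: lang}) for lang in languages
        }
        for l1 in languages:
            for l2 in languages:
                if l1 == l2:
                    continue
                d = draws[l1] - draws[l2]
                p_gt0 = float(np.mean(d > 0))
                rows.append({
                    **{str(k): str(v) for k, v in cell.items()},
                    "language_1": l1, "language_2": l2,
                    "mean_diff": float(d.mean()),
                    "q2.5": float(np.quantile(d, 0.025)),
                    "q97.5": float(np.quantile(d, 0.975)),
                    "p_gt0": p_gt0,
                    "suppressed": max(p_gt0, 1.0 - p_gt0) < support_threshold,
                })
    return pd.DataFrame(rows)


def fit_stimulus_regression(
    records: pd.DataFrame,
    conditions: Sequence[str],
    spec: RegressionSpec | None = None,
) -> PosteriorSummary:
    """Beta regression of final-position stimulus scores on role and conditions.

    Uses role x condition interactions and by-item random intercept + slopes;
    with a single item the grouping variance is unidentifiable, so a warning
    is issued and a fixed-effects-only model is fit.
    """
    df = records.copy()
    cond_cols = []
    for c in conditions:
        col = c if c in df.columns else f"cond_{c}"
        if col not in df.columns:
            raise ValueError(f"records table lacks condition column {c!r}")
        cond_cols.append(col)
    df["item_id"] = df["sentence_id"].astype(str).str.split("|").str[0]
    base = spec or RegressionSpec()
    fixed = ["role"] + cond_cols + [f"role:{c}" for c in cond_cols]
    group = "item_id"
    slopes = ["role"] + cond_cols
    if df["item_id"].nunique() < 2:
        warnings.warn("single stimulus item: fitting fixed effects only", UserWarning)
        group = None
        slopes = []
    rspec = RegressionSpec(
        fixed_terms=fixed, group=group, group_slopes=slopes,
        reference_levels=base.reference_levels,
        slope_prior_sd=base.slope_prior_sd, intercept_prior_sd=base.intercept_prior_sd,
        group_sd_prior_df=base.group_sd_prior_df, group_sd_prior_scale=base.group_sd_prior_scale,
        phi_prior=base.phi_prior, chains=base.chains, draws=base.draws,
        warmup=base.warmup, target_accept=base.target_accept, seed=base.seed,
        check_diagnostics=base.check_diagnostics,
    )
    design = build_design(df, rspec)
    return fit_beta_hierarchical(design, rspec)
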