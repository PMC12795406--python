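"""Beta-GLMM simulators used for parameter-recovery and model-recovery checks."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["simulate_records"]


def simulate_records(
    n: int,
    effects: Mapping[str, float],
    intercept: float,
    phi: float,
    group_sd: float = 0.0,
    records_per_group: int = 4,
    seed: int = 0,
    language_offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate predictability-style records from a known beta GLMM.

    ``effects`` holds logit-scale coefficients for the binary predictors
    ``after_argument``, ``after_verb`` and ``role`` (role = P indicator);
    ``language_offsets`` optionally adds a language factor with per-level
    logit offsets (first level is the reference).  Groups are consecutive
    blocks of ``records_per_group`` records sharing a random intercept.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    aa = rng.random(n) < 0.5
    av = rng.random(n) < 0.5
    role_p = rng.random(n) < 0.5
    eta = np.full(n, float(intercept))
    eta += effects.get("after_argument", 0.0) * aa
    eta += effects.get("after_verb", 0.0) * av
    eta += effects.get("role", 0.0) * role_p
    langs = None
    if language_offsets:
        levels = list(language_offsets)
        langs = np.array(levels)[rng.integers(len(levels), size=n)]
        eta += np.array([language_offsets[l] for l in langs])
    groups = np.arange(n) // records_per_group
    if group_sd > 0:
        u = rng.normal(0.0, group_sd, size=groups.max() + 1)
        eta += u[groups]
    mu = expit(eta)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)
    df = pd.DataFrame({
        "sentence_id": [f"s{g:05d}" for g in groups],
        "language": langs if langs is not None else "synthetic",
        "role": np.where(role_p, "P", "A"),
        "after_argument": aa,
        "after_verb": av,
        "nominality": "OTHER",
        "verb_class": "motion",
        "p_correct": y,
    })
    return df
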