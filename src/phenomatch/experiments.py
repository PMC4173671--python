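"""Replicated simulation experiments: coefficient recovery and selection.

These are the package's power/validation studies: generate many synthetic
datasets from known generative coefficients, push them through the fitting
machinery, and summarise how well the truth is recovered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modeling import ModelSpec, Term, backward_select, fit_model, preset_specs
from .synthetic import PredictorConfig, TruthParams, gen_recruitment, sample_predictors

__all__ = ["coefficient_recovery", "recovery_summary", "selection_consistency"]

TRUTH_BY_COLUMN = {
    "const": "b0",
    "LS:D_low": "b1_low",
    "LS:D_high": "b1_high",
    "PM": "b2",
    "PM^2:D_low": "b3_low",
    "PM^2:D_high": "b3_high",
    "S^2": "b4",
    "CA": "b5",
    "WT": "b6",
}


def coefficient_recovery(
    truth: TruthParams,
    n_reps: int = 100,
    n_years: int = 300,
    seeds: list[int] | None = None,
    predictor_cfg: PredictorConfig | None = None,
) -> pd.DataFrame:
    """Fit the recruitment model on replicated synthetic datasets.

    Each replicate draws fresh yearly predictors, generates recruit counts
    from ``truth``, and refits the standard recruitment structure by OLS.
    Returns one row of coefficient estimates per replicate.
    """
    if seeds is None:
        seeds = list(range(1, n_reps + 1))
    spec = preset_specs()["recruitment"]
    rows = []
    for seed in seeds:
        pred = sample_predictors(n_years, seed, predictor_cfg)
        r = gen_recruitment(pred, truth, seed + 100_000)
        fit = fit_model(pred.assign(R=r), spec)
        rows.append(fit.params)
    return pd.DataFrame(rows, index=pd.Index(seeds, name="seed"))


def recovery_summary(estimates: pd.DataFrame, truth: TruthParams) -> pd.DataFrame:
    """Mean estimate, Monte-Carlo s.e. and z-score against the truth."""
    n = len(estimates)
    out = []
    for col in estimates.columns:
        true_val = getattr(truth, TRUTH_BY_COLUMN[col])
        mean = estimates[col].mean()
        mc_se = estimates[col].std(ddof=1) / np.sqrt(n)
        out.append(
            {"term": col, "truth": true_val, "mean_estimate": mean,
             "mc_se": mc_se, "z": (mean - true_val) / mc_se}
        )
    return pd.DataFrame(out).set_index("term")


def selection_consistency(
    n_seeds: int = 50,
    n_years: int = 200,
    n_candidates: int = 6,
    active: tuple[int, ...] = (0, 1),
    effect: float = 0.5,
    noise_sd: float = 0.1,
    base_seed: int = 0,
) -> float:
    """Fraction of replicates where backward CV selection recovers exactly
    the active term set.

    Candidates are independent standard-normal predictors; ``active`` ones
    carry slope ``effect``.  Exact recovery requires every inactive term
    dropped and every active term kept.
    """
    active_names = {f"x{i}" for i in active}
    full = ModelSpec(
        response="y", terms=tuple(Term(f"x{i}") for i in range(n_candidates))
    )
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s + 1)
        rec = pd.DataFrame(
            {f"x{i}": rng.normal(0, 1, n_years) for i in range(n_candidates)}
        )
        y = 1.0 + rng.normal(0, noise_sd, n_years)
        for i in active:
            y = y + effect * rec[f"x{i}"].to_numpy()
        rec["y"] = y
        trace = backward_select(rec, full)
        hits += {t.predictor for t in trace.final_spec.terms} == active_names
    return hits / n_seeds
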