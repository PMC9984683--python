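"""Model comparison across monitoring timepoints and feature-importance reports.

Outputs are plain tidy tables (CSV-ready), suitable for boxplots of
per-fold AUC distributions and ranked importance bars; report generation is
deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .predict import CVResult, fdr_adjust, mcnemar_compare

__all__ = ["ModelComparison", "compare_timepoints", "importance_report"]


@dataclass
class ModelComparison:
    """Pairwise comparison of cross-validated models."""

    auc_table: pd.DataFrame  # model, fold, auc  (boxplot-ready)
    pairwise: pd.DataFrame  # model_a, model_b, statistic, p, p_fdr, winner
    alpha: float = 0.05


def compare_timepoints(results: "dict[str, CVResult]", alpha: float = 0.05
                       ) -> ModelComparison:
    """Compare cross-validated models (e.g. one per timepoint) pairwise.

    Per-fold AUCs are collected for plotting; each model pair is compared by
    McNemar's test on the patients predicted by both, and p-values are
    FDR-adjusted.  ``winner`` names the model with the higher mean AUC when
    the adjusted p falls below ``alpha`` ('' otherwise).  A single model
    yields an empty pairwise table.
    """
    auc_rows = [
        {"model": name, "fold": f, "auc": a}
        for name, res in results.items()
        for f, a in enumerate(res.fold_auc)
    ]
    auc_table = pd.DataFrame(auc_rows, columns=["model", "fold", "auc"])

    rows = []
    for a, b in combinations(results, 2):
        ra, rb = results[a], results[b]
        merged = ra.patients.merge(rb.patients, on="patient_id",
                                   suffixes=("_a", "_b"))
        stat, p = mcnemar_compare(merged["pred_a"], merged["pred_b"],
                                  merged["outcome_a"])
        rows.append({"model_a": a, "model_b": b, "statistic": stat, "p": p})
    pairwise = pd.DataFrame(rows, columns=["model_a", "model_b", "statistic", "p"])
    if len(pairwise):
        pairwise["p_fdr"] = fdr_adjust(pairwise["p"].to_numpy())
        means = {name: res.mean_auc for name, res in results.items()}
        pairwise["winner"] = [
            (r.model_a if means[r.model_a] >= means[r.model_b] else r.model_b)
            if r.p_fdr < alpha else ""
            for r in pairwise.itertuples()
        ]
    else:
        pairwise["p_fdr"] = pd.Series(dtype=float)
        pairwise["winner"] = pd.Series(dtype=str)
    return ModelComparison(auc_table=auc_table, pairwise=pairwise, alpha=alpha)


def importance_report(result: CVResult,
                      covariate_names: "list[str] | tuple[str, ...]" = ()
                      ) -> pd.DataFrame:
    """Ranked impurity-importance table with feature provenance.

    ``source`` is 'IMPACT' for clinical covariates and 'EEG' otherwise.
    """
    imp = result.importances.sort_values(ascending=False)
    return pd.DataFrame({
        "feature": imp.index,
        "importance": imp.to_numpy(),
        "source": ["IMPACT" if f in set(covariate_names) else "EEG"
                   for f in imp.index],
    }).reset_index(drop=True)
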