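"""Breeders'-equation response prediction under top-k sire selection.

Predicted genetic gain per generation is R = i·ρ·σg, with i the standardized
selection intensity for truncation selection of the top k of n candidates, ρ the
accuracy of selection (mean of the square roots of the sire EBV reliabilities) and
σg the genetic standard deviation of the trait.  Gains from within-country
evaluation are expressed as a percentage of the gain under the pooled multi-country
evaluation (%PGG), whose rows are 100 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mme import EvaluationResult

__all__ = [
    "SelectionScenario",
    "DEFAULT_TOP_K",
    "selection_intensity",
    "candidate_accuracy",
    "predicted_gain",
    "percent_gain",
    "rank_sires",
    "gain_table",
]

#: the k values of the published comparison: top 5, 10, 25, 50, 75 and 100 sires
DEFAULT_TOP_K = (5, 10, 25, 50, 75, 100)

#: annotation carried into reports: sire selection is roughly two thirds of the
#: total progress achievable over all four selection pathways
SIRE_PATHWAY_NOTE = "sire-selection pathway only (~66% of total achievable progress)"


@dataclass(frozen=True)
class SelectionScenario:
    k: int
    n_candidates: int
    trait: str
    source: str  # e.g. within_KE, within_SA, multi

    def __post_init__(self) -> None:
        if not (0 < self.k <= self.n_candidates):
            raise ValueError(f"need 0 < k <= n_candidates, got k={self.k}, "
                             f"n={self.n_candidates}")


def selection_intensity(k: int, n: int) -> float:
    """Standardized selection intensity for truncation selection of the top k of n.

    Infinite-population truncated-normal form: with selected proportion p = k/n and
    truncation point z the upper-p quantile of N(0,1), i = φ(z)/p.  The boundary
    k = n (no truncation) gives i = 0.
    """
    if k <= 0 or n <= 0:
        raise ValueError(f"k and n must be positive, got k={k}, n={n}")
    if k > n:
        raise ValueError(f"cannot select top {k} of {n} candidates")
    p = k / n
    if k == n:
        return 0.0
    z = norm.isf(p)
    return float(norm.pdf(z) / p)


def candidate_accuracy(result: EvaluationResult, candidates, trait: str,
                       mode: str = "mean_all", k: int | None = None) -> float:
    """ρ: mean accuracy (√reliability) over the candidate sires.

    ``mean_all`` (default) averages over every candidate; ``mean_top_k`` averages
    over the k sires ranked highest on EBV for the trait.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    acc = result.accuracy_series(trait)
    missing = [c for c in candidates if c not in acc.index]
    if missing:
        raise KeyError(f"candidates without reliabilities: {missing[:10]}")
    if mode == "mean_top_k":
        if k is None:
            raise ValueError("mean_top_k mode requires k")
        candidates = rank_sires(result, trait, candidates)[:k]
    elif mode != "mean_all":
        raise ValueError(f"unknown accuracy mode {mode!r}")
    return float(acc.loc[candidates].mean())


def predicted_gain(i: float, rho: float, sigma_g: float) -> float:
    """R = i·ρ·σg, in trait units per generation."""
    if min(i, rho, sigma_g) < 0:
        raise ValueError("i, rho and sigma_g must be non-negative")
    return i * rho * sigma_g


def percent_gain(pgg_source: float, pgg_multi: float) -> float:
    """Gain of a source expressed as a percentage of the multi-country gain."""
    if pgg_multi <= 0:
        raise ValueError("multi-country gain must be positive")
    return 100.0 * pgg_source / pgg_multi


def rank_sires(result: EvaluationResult, trait: str, candidates) -> list[str]:
    """Candidates in descending EBV order; ties broken by ascending animal id."""
    ebv = result.ebv_series(trait)
    return sorted(candidates, key=lambda a: (-ebv[a], a))


def gain_table(results: dict[str, EvaluationResult],
               sigma_g: dict[str, dict[str, float]],
               candidates: dict[str, list[str]],
               traits: list[str] | None = None,
               k_values=DEFAULT_TOP_K,
               multi_source: str = "multi",
               accuracy_mode: str = "mean_all") -> pd.DataFrame:
    """One row per trait × k × source: i, ρ, σg, PGG and %PGG vs the multi source.

    ``results`` maps source name → fitted evaluation; ``sigma_g`` maps source →
    trait → genetic SD; ``candidates`` maps source → its sire candidate list, whose
    length sets n in the intensity formula (for the pooled source pass the summed
    per-country sire lists, duplicates included, to mirror a pooled candidate count
    that does not deduplicate shared sires).
    """
    if multi_source not in results:
        raise ValueError(f"missing multi-country source {multi_source!r} in results")
    for src in results:
        if src not in candidates:
            raise ValueError(f"no candidate list for source {src!r}")
    if traits is None:
        traits = sorted(results[multi_source].ebv["trait"].unique())

    rows = []
    for trait in traits:
        rho_all = {
            src: candidate_accuracy(res, sorted(set(candidates[src])), trait)
            for src, res in results.items()
        } if accuracy_mode == "mean_all" else None
        for k in k_values:
            pgg = {}
            for src in results:
                n = len(candidates[src])
                kk = min(k, n)
                i = selection_intensity(kk, n)
                if rho_all is not None:
                    rho = rho_all[src]
                else:
                    rho = candidate_accuracy(results[src],
                                             sorted(set(candidates[src])), trait,
                                             mode=accuracy_mode, k=kk)
                sg = sigma_g[src][trait]
                pgg[src] = (i, rho, sg, predicted_gain(i, rho, sg))
            base = pgg[multi_source][3]
            for src in results:
                i, r, sg, g = pgg[src]
                rows.append((trait, k, src, i, r, sg, g,
                             percent_gain(g, base) if base > 0 else np.nan))
    return pd.DataFrame(
        rows, columns=["trait", "scenario_k", "source", "i", "rho", "sigma_g",
                       "pgg", "pct_pgg"]
    )


def write_gain_table(table: pd.DataFrame, path) -> None:
    """Gains TSV: 2-dp presentation columns plus full-precision companions."""
    out = table.copy()
    for col in ("i", "rho", "sigma_g", "pgg", "pct_pgg"):
        out[f"{col}_full"] = out[col]
        out[col] = out[col].round(2)
    out.to_csv(path, sep="\t", index=False)
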