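"""Perturbagen screening for aging-signature reversal.

Each drug condition's modZ profile is rank-transformed to percentiles
within the condition; genes at or above the upper tertile are called "up",
at or below the lower tertile "down". A signature DEG is reversed when the
drug call opposes its aging direction. Per drug, the dose/time condition
reversing the most DEGs is kept, and a drug is a candidate when it reverses
strictly more than half of the screenable DEGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import PerturbationProfiles

__all__ = [
    "ScreenConfig",
    "percentile_transform",
    "tertile_call",
    "count_reversals",
    "screen_drugs",
]


@dataclass
class ScreenConfig:
    lower_tertile: float = 100.0 / 3.0
    upper_tertile: float = 200.0 / 3.0
    majority_strict: bool = True  # candidate iff n_reversed > n_screenable/2

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_tertile < self.upper_tertile < 100.0:
            raise ValueError("need 0 < lower < upper < 100")


def percentile_transform(modz: np.ndarray | pd.Series) -> np.ndarray:
    """Percentile = 100 (rank - 0.5) / G, average ranks for ties."""
    values = np.asarray(modz, float)
    if len(values) < 2:
        raise ValueError("need at least 2 genes")
    if np.ptp(values) == 0:
        warnings.warn("all modZ values equal; percentiles all 50", stacklevel=2)
        return np.full(len(values), 50.0)
    ranks = rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / len(values)


def tertile_call(percentiles: np.ndarray, config: ScreenConfig | None = None) -> np.ndarray:
    """Per-gene call: 'up' at/above upper tertile, 'down' at/below lower,
    else 'null'."""
    config = config or ScreenConfig()
    p = np.asarray(percentiles, float)
    calls = np.full(len(p), "null", dtype=object)
    calls[p >= config.upper_tertile] = "up"
    calls[p <= config.lower_tertile] = "down"
    return calls


def count_reversals(calls: pd.Series, signature: pd.Series) -> int:
    """Count signature genes whose call opposes the aging direction.

    ``calls`` maps gene -> {up, down, null}; ``signature`` maps gene -> +1/-1
    aging direction. Null calls never reverse. Both are intersected first.
    """
    shared = calls.index.intersection(signature.index)
    n = 0
    for g in shared:
        s, c = int(signature[g]), calls[g]
        if (s > 0 and c == "down") or (s < 0 and c == "up"):
            n += 1
    return n


def screen_drugs(
    profiles: PerturbationProfiles,
    signature: pd.Series,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Score every drug for signature reversal and pick its best condition.

    Per condition: percentile-transform the modZ vector over its gene
    universe, make tertile calls, count reversed signature genes. Per drug
    keep the condition with the most reversals (ties: larger summed distance
    of reversed genes from the 50th percentile, then lexicographic label).
    Candidate iff n_reversed > n_screenable / 2 (strict).
    """
    config = config or ScreenConfig()
    genes = profiles.modz.index
    screenable = [g for g in signature.index if g in genes]
    n_screenable = len(screenable)
    if n_screenable == 0:
        warnings.warn("no signature genes present in perturbation profiles", stacklevel=2)
    sig = signature.loc[screenable]
    per_condition = []
    for label in profiles.modz.columns:
        pct = percentile_transform(profiles.modz[label].to_numpy())
        pct_s = pd.Series(pct, index=genes)
        calls = pd.Series(tertile_call(pct, config), index=genes)
        n_rev = count_reversals(calls.loc[screenable], sig) if n_screenable else 0
        reversed_genes = [
            g
            for g in screenable
            if (sig[g] > 0 and calls[g] == "down") or (sig[g] < 0 and calls[g] == "up")
        ]
        tiebreak = float(np.abs(pct_s.loc[reversed_genes] - 50.0).sum()) if reversed_genes else 0.0
        meta = profiles.conditions.loc[label]
        per_condition.append(
            {
                "drug": meta["drug"],
                "dose": meta["dose"],
                "time": meta["time"],
                "condition": label,
                "n_reversed": n_rev,
                "tiebreak": tiebreak,
            }
        )
    cond = pd.DataFrame(per_condition)
    results = []
    for drug, grp in cond.groupby("drug", sort=False):
        best = grp.sort_values(
            ["n_reversed", "tiebreak", "condition"], ascending=[False, False, True]
        ).iloc[0]
        n_rev = int(best["n_reversed"])
        results.append(
            {
                "drug": drug,
                "best_dose": best["dose"],
                "best_time": best["time"],
                "n_screenable": n_screenable,
                "n_reversed": n_rev,
                "candidate": bool(n_rev > n_screenable / 2.0) if n_screenable else False,
            }
        )
    out = pd.DataFrame(results).sort_values(
        ["n_reversed", "drug"], ascending=[False, True]
    ).reset_index(drop=True)
    return out
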