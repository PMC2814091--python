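"""Cross-contrast comparison of per-CpG deltas.

Joins the culture and aging contrasts on CpG id, selects CpGs changed in
both (absolute delta strictly above a shared threshold in each contrast),
and summarizes their agreement: Pearson correlation of the two delta
vectors and a df=1 chi-square on the 2x2 sign table (no continuity
correction by default).  Also compares culture DM counts between donor
subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from senemeth.diffmeth import (
    ContrastResult,
    ContrastSpec,
    DELTA_THRESHOLD,
    SHARED_DELTA_THRESHOLD,
    contrast_stats,
)
from senemeth.io_formats import BetaMatrix, StudyDesign

__all__ = [
    "ConcordanceResult",
    "join_contrasts",
    "select_shared_dm",
    "concordance_stats",
    "subgroup_dm_counts",
]


@dataclass
class ConcordanceResult:
    n_selected: int
    threshold: float
    pearson_r: float
    sign_table: np.ndarray  # 2x2: rows A up/down, cols B up/down
    chi2: float             # NaN when a margin is empty
    chi2_p: float

    def to_dict(self) -> dict:
        return {
            "n_selected": self.n_selected,
            "threshold": self.threshold,
            "pearson_r": self.pearson_r,
            "sign_table": self.sign_table.tolist(),
            "chi2": None if np.isnan(self.chi2) else self.chi2,
            "chi2_p": None if np.isnan(self.chi2_p) else self.chi2_p,
        }


def join_contrasts(result_a: ContrastResult,
                   result_b: ContrastResult) -> pd.DataFrame:
    """Inner join of two contrasts' deltas on cpg_id.

    Returns a frame with columns delta_a, delta_b.
    """
    joined = pd.merge(
        result_a.table[["delta"]].rename(columns={"delta": "delta_a"}),
        result_b.table[["delta"]].rename(columns={"delta": "delta_b"}),
        left_index=True, right_index=True, how="inner",
    )
    if joined.empty:
        raise ValueError("contrasts share no CpG ids")
    return joined


def select_shared_dm(joined: pd.DataFrame,
                     threshold: float = SHARED_DELTA_THRESHOLD) -> pd.DataFrame:
    """Rows with |delta_a| > threshold AND |delta_b| > threshold (strict)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    mask = (joined["delta_a"].abs() > threshold) & \
           (joined["delta_b"].abs() > threshold)
    return joined[mask]


def chi2_2x2(table: np.ndarray, continuity_correction: bool = False
             ) -> tuple[float, float]:
    """df=1 chi-square from the closed form N(ad - bc)^2 / product of
    margins; returns (chi2, p), (nan, nan) when a margin is zero."""
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return float("nan"), float("nan")
    num = abs(a * d - b * c)
    if continuity_correction:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num ** 2 / margins
    return chi2, float(stats.chi2.sf(chi2, df=1))


def concordance_stats(subset: pd.DataFrame,
                      threshold: float = SHARED_DELTA_THRESHOLD,
                      continuity_correction: bool = False) -> ConcordanceResult:
    """Pearson r of (delta_a, delta_b) plus the sign-agreement chi-square.

    ``subset`` is the output of :func:`select_shared_dm`; strict selection
    guarantees no zero deltas.
    """
    if len(subset) < 2:
        raise ValueError(f"need >= 2 selected CpGs, got {len(subset)}")
    da = subset["delta_a"].to_numpy()
    db = subset["delta_b"].to_numpy()
    r = float(np.corrcoef(da, db)[0, 1])
    table = np.array([
        [int(((da > 0) & (db > 0)).sum()), int(((da > 0) & (db < 0)).sum())],
        [int(((da < 0) & (db > 0)).sum()), int(((da < 0) & (db < 0)).sum())],
    ])
    chi2, p = chi2_2x2(table, continuity_correction)
    if np.isnan(chi2):
        warnings.warn("a margin of the sign table is zero; chi-square "
                      "undefined", stacklevel=2)
    return ConcordanceResult(len(subset), threshold, r, table, chi2, p)


def subgroup_dm_counts(
    beta: BetaMatrix,
    design: StudyDesign,
    spec: ContrastSpec,
    subgroup_var: str = "age_group",
    subgroup_levels: tuple[str, str] = ("young", "elderly"),
    delta_threshold: float = DELTA_THRESHOLD,
    p_threshold: float | None = None,
) -> dict:
    """Run ``spec`` within each subgroup and count |delta| > threshold CpGs.

    Relative difference is (n_first - n_second) / n_first * 100, with the
    first-listed subgroup as denominator.
    """
    counts = {}
    for level in subgroup_levels:
        sub_spec = ContrastSpec(
            f"{spec.name}_{level}", spec.variable, spec.level_a,
            spec.level_b, spec.paired,
            {**spec.subset, subgroup_var: level},
        )
        result = contrast_stats(beta, design, sub_spec)
        mask = result.table["delta"].abs() > delta_threshold
        if p_threshold is not None:
            mask &= result.table["p"] <= p_threshold
        counts[level] = int(mask.sum())
    first, second = (counts[lvl] for lvl in subgroup_levels)
    rel = float("nan") if first == 0 else (first - second) / first * 100.0
    return {
        "counts": counts,
        "relative_difference_pct": rel,
        "delta_threshold": delta_threshold,
        "p_threshold": p_threshold,
    }
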