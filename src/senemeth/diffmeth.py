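"""Per-CpG contrast statistics, differential-methylation labels and
Euclidean hierarchical clustering for heatmap ordering.

A contrast compares mean beta between two sample groups (late vs. early
passage, or elderly vs. young donors).  The default test is the unpaired
pooled-variance two-sided Student's t; a paired mode (one-sample t on
within-donor differences) is available for the same-donor early/late
design.  BH-adjusted q-values are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from senemeth.io_formats import BetaMatrix, StudyDesign

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "CULTURE_CONTRAST",
    "AGING_CONTRAST",
    "contrast_stats",
    "classify_dm",
    "hierarchical_cluster",
]

DELTA_THRESHOLD = 0.20
SHARED_DELTA_THRESHOLD = 0.15
P_THRESHOLD = 0.01


@dataclass(frozen=True)
class ContrastSpec:
    """Which two groups to compare, and how.

    ``subset`` optionally restricts the samples first (column == value),
    e.g. the culture contrast within young donors only.
    """

    name: str
    variable: str
    level_a: str
    level_b: str
    paired: bool = False
    subset: dict[str, str] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        if self.level_a == self.level_b:
            raise ValueError("contrast levels must be distinct")

    def swapped(self) -> "ContrastSpec":
        return ContrastSpec(self.name + "_swapped", self.variable,
                            self.level_b, self.level_a, self.paired,
                            dict(self.subset))


#: late vs. early passage, all donors, same-donor pairs available
CULTURE_CONTRAST = ContrastSpec("culture", "passage_group", "early", "late")
#: elderly vs. young donors at the early passage
AGING_CONTRAST = ContrastSpec("aging", "age_group", "young", "elderly",
                              subset={"passage_group": "early"})


@dataclass
class ContrastResult:
    """Per-CpG statistics of one contrast.

    ``table`` is indexed by cpg_id with columns mean_a, mean_b, delta
    (mean_b - mean_a), t, p, q, n_a, n_b and dm_label in
    {hyper, hypo, unchanged}.
    """

    spec: ContrastSpec
    table: pd.DataFrame

    @property
    def cpg_ids(self) -> pd.Index:
        return self.table.index

    def dm_cpgs(self, direction: str | None = None) -> pd.Index:
        lab = self.table["dm_label"]
        mask = lab.isin(["hyper", "hypo"]) if direction is None \
            else lab == direction
        return self.table.index[mask]

    def write_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "cpg_id"
        df.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def read_tsv(cls, path, spec: ContrastSpec) -> "ContrastResult":
        return cls(spec, pd.read_csv(path, sep="\t", index_col="cpg_id"))


def _group_samples(design: StudyDesign, spec: ContrastSpec) -> tuple[list, list]:
    table = design.table
    for col, val in spec.subset.items():
        table = table[table[col] == val]
    a = list(table.index[table[spec.variable] == spec.level_a])
    b = list(table.index[table[spec.variable] == spec.level_b])
    for level, ids in ((spec.level_a, a), (spec.level_b, b)):
        if len(ids) < 2:
            raise ValueError(
                f"contrast {spec.name!r}: group {level!r} has "
                f"{len(ids)} sample(s), need >= 2"
            )
    return a, b


def _unpaired_t(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance two-sided Student's t, vectorized over rows."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf) * np.sign(diff + (diff == 0)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t on within-donor differences, vectorized over rows."""
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                     np.where(mean == 0, 0.0, np.inf) * np.sign(mean + (mean == 0)))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (mean == 0), 1.0, p)
    return t, p


def contrast_stats(beta: BetaMatrix, design: StudyDesign,
                   spec: ContrastSpec) -> ContrastResult:
    """Group means, delta = mean_B - mean_A, t, p and BH q per CpG.

    CpGs with missing values in the contrast's samples are excluded.
    """
    a_ids, b_ids = _group_samples(design, spec)
    sub = beta.values[a_ids + b_ids]
    sub = sub.dropna(axis=0)
    xa = sub[a_ids].to_numpy()
    xb = sub[b_ids].to_numpy()

    if spec.paired:
        donors_a = design.table.loc[a_ids, "donor_id"]
        donors_b = design.table.loc[b_ids, "donor_id"]
        common = [d for d in donors_a if d in set(donors_b)]
        if len(common) < 2:
            raise ValueError(
                f"contrast {spec.name!r}: paired mode needs >= 2 complete "
                f"donor pairs, found {len(common)}"
            )
        a_by_donor = {d: s for s, d in donors_a.items()}
        b_by_donor = {d: s for s, d in donors_b.items()}
        xa = sub[[a_by_donor[d] for d in common]].to_numpy()
        xb = sub[[b_by_donor[d] for d in common]].to_numpy()
        t, p = _paired_t(xb - xa)
    else:
        t, p = _unpaired_t(xa, xb)

    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_a": xa.mean(axis=1),
            "mean_b": xb.mean(axis=1),
            "delta": xb.mean(axis=1) - xa.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
            "n_a": xa.shape[1],
            "n_b": xb.shape[1],
            "dm_label": "unchanged",
        },
        index=sub.index,
    )
    return classify_dm(ContrastResult(spec, table))


def classify_dm(result: ContrastResult,
                delta_threshold: float = DELTA_THRESHOLD,
                p_threshold: float | None = P_THRESHOLD) -> ContrastResult:
    """Label each CpG hyper/hypo/unchanged.

    hyper iff delta > +delta_threshold (strictly) and, when a p_threshold
    is given, p <= p_threshold; hypo symmetrically; everything else
    unchanged.  Relabels in place and returns the result.
    """
    if not 0.0 < delta_threshold <= 1.0:
        raise ValueError("delta_threshold must lie in (0, 1]")
    if p_threshold is not None and not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must lie in (0, 1]")
    tbl = result.table
    sig = np.ones(len(tbl), dtype=bool) if p_threshold is None \
        else (tbl["p"].to_numpy() <= p_threshold)
    delta = tbl["delta"].to_numpy()
    label = np.where((delta > delta_threshold) & sig, "hyper",
                     np.where((delta < -delta_threshold) & sig, "hypo",
                              "unchanged"))
    tbl["dm_label"] = label
    return result


@dataclass
class ClusterTree:
    """Leaf ordering plus the scipy linkage matrix of one clustering."""

    labels: list[str]
    leaf_order: list[str]
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(beta: BetaMatrix, axis: str = "samples") -> ClusterTree:
    """Agglomerative clustering (Euclidean distance, average linkage).

    ``axis`` is ``"samples"`` (cluster columns) or ``"cpgs"`` (cluster
    rows).  Deterministic given input order; scipy breaks distance ties by
    lower pair index.
    """
    if axis not in ("samples", "cpgs"):
        raise ValueError("axis must be 'samples' or 'cpgs'")
    values = beta.values
    if values.isna().any().any():
        raise ValueError("clustering requires a complete matrix")
    mat = values.to_numpy().T if axis == "samples" else values.to_numpy()
    labels = list(values.columns if axis == "samples" else values.index)
    if len(labels) < 2:
        raise ValueError(f"need >= 2 items on axis {axis!r} to cluster")
    linkage = hierarchy.linkage(mat, method="average", metric="euclidean")
    order = hierarchy.leaves_list(linkage)
    return ClusterTree(labels, [labels[i] for i in order], linkage)
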