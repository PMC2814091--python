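"""Methylation--expression linkage and array-vs-pyrosequencing comparison.

Methylation and expression tables are joined by uppercase gene symbol:
probes failing the present-call filter are dropped, a gene's probe sets are
aggregated (mean of log2 intensities by default) and each CpG is matched
independently to its gene's aggregate.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from senemeth.io_formats import BetaMatrix, ExpressionMatrix, PyroProfile

__all__ = [
    "present_filter",
    "match_by_symbol",
    "expression_log2_ratio",
    "link_genes",
    "methylation_expression_summary",
    "delta_vs_expression",
    "compare_platforms",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = (0.0, 0.25, 0.75, 1.0)
PRESENT_MIN_FRACTION = 0.5


def present_filter(expression: ExpressionMatrix,
                   min_fraction: float = PRESENT_MIN_FRACTION) -> list[str]:
    """Probe ids detected as present (call P) in strictly more than
    ``min_fraction`` of the hybridizations."""
    frac = (expression.calls == "P").mean(axis=1)
    return list(expression.probe_ids[frac > min_fraction])


def match_by_symbol(annotation: pd.DataFrame,
                    expression: ExpressionMatrix,
                    probe_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Map each annotated CpG to its gene's expression probe sets.

    Returns a frame indexed by cpg_id with columns gene_symbol and
    probe_ids (tuple); CpGs whose gene has no (retained) probe set are
    excluded, with counts logged.  ``probe_ids`` optionally restricts the
    probes considered (e.g. the output of :func:`present_filter`).
    """
    probes = expression.probe_to_symbol
    if probe_ids is not None:
        probes = probes.loc[list(probe_ids)]
    by_symbol: dict[str, tuple[str, ...]] = {
        sym: tuple(grp.index) for sym, grp in probes.groupby(probes)
    }
    rows = []
    n_unannotated = n_unmatched = 0
    for cpg, sym in annotation["gene_symbol"].items():
        if sym is None or (isinstance(sym, float) and np.isnan(sym)):
            n_unannotated += 1
            continue
        sym = str(sym).upper()
        if sym not in by_symbol:
            n_unmatched += 1
            continue
        rows.append({"cpg_id": cpg, "gene_symbol": sym,
                     "probe_ids": by_symbol[sym]})
    logger.info("match_by_symbol: %d CpGs matched, %d without symbol, "
                "%d without expression probe", len(rows), n_unannotated,
                n_unmatched)
    return pd.DataFrame(rows, columns=["cpg_id", "gene_symbol", "probe_ids"]
                        ).set_index("cpg_id")


def _aggregate_probes(expression: ExpressionMatrix, probe_ids: Iterable[str],
                      aggregation: str = "mean") -> pd.Series:
    sub = expression.intensities.loc[list(probe_ids)]
    if aggregation == "mean":
        return sub.mean(axis=0)
    if aggregation == "max":
        return sub.loc[sub.mean(axis=1).idxmax()]
    raise ValueError(f"unknown aggregation {aggregation!r}")


def expression_log2_ratio(expression: ExpressionMatrix,
                          samples_a: Sequence[str],
                          samples_b: Sequence[str]) -> pd.Series:
    """Per-probe log2 ratio: mean intensity in B minus mean in A."""
    return (expression.intensities[list(samples_b)].mean(axis=1)
            - expression.intensities[list(samples_a)].mean(axis=1))


def link_genes(
    beta: BetaMatrix,
    expression: ExpressionMatrix,
    mapping: pd.DataFrame,
    meth_groups: tuple[Sequence[str], Sequence[str]],
    expr_groups: tuple[Sequence[str], Sequence[str]],
    aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-gene linkage records.

    One row per gene with its CpGs and probe sets, group-mean beta and
    log2 intensity, delta-beta, log2 expression ratio and a
    direction-agreement flag (methylation up while expression down, or
    vice versa; NaN when either change is exactly zero).
    """
    if mapping.empty:
        raise ValueError("empty CpG-probe mapping")
    ma, mb = [list(g) for g in meth_groups]
    ea, eb = [list(g) for g in expr_groups]
    rows = []
    for sym, grp in mapping.groupby("gene_symbol"):
        cpgs = [c for c in grp.index if c in beta.cpg_ids]
        if not cpgs:
            continue
        probes = grp["probe_ids"].iloc[0]
        bsub = beta.values.loc[cpgs]
        intens = _aggregate_probes(expression, probes, aggregation)
        beta_a = float(bsub[ma].to_numpy().mean())
        beta_b = float(bsub[mb].to_numpy().mean())
        expr_a = float(intens[ea].mean())
        expr_b = float(intens[eb].mean())
        delta = beta_b - beta_a
        ratio = expr_b - expr_a
        agree = np.nan if delta == 0 or ratio == 0 \
            else float(np.sign(delta) != np.sign(ratio))
        rows.append({
            "gene_symbol": sym,
            "cpg_ids": tuple(cpgs),
            "probe_ids": tuple(probes),
            "beta_a": beta_a, "beta_b": beta_b,
            "expr_a": expr_a, "expr_b": expr_b,
            "delta_beta": delta, "log2_ratio": ratio,
            "direction_agreement": agree,
            "mean_beta": float(bsub.to_numpy().mean()),
            "mean_expr": float(intens.mean()),
        })
    return pd.DataFrame(rows).set_index("gene_symbol")


def methylation_expression_summary(
    linked: pd.DataFrame,
    bin_edges: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Mean and dispersion of log2 intensity per gene-mean-beta bin.

    Bins follow ``pandas.cut`` over ``bin_edges`` (right-closed, lowest
    edge included).  Empty bins are kept and flagged.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    if linked.empty:
        raise ValueError("no linked genes to summarize")
    bins = pd.cut(linked["mean_beta"], bins=edges, include_lowest=True)
    grouped = linked.groupby(bins, observed=False)["mean_expr"]
    out = pd.DataFrame({
        "n_genes": grouped.size(),
        "mean_intensity": grouped.mean(),
        "sd_intensity": grouped.std(),
    })
    out["empty"] = out["n_genes"] == 0
    if out["empty"].any():
        logger.warning("%d empty methylation bins", int(out["empty"].sum()))
    if (out["n_genes"] > 0).sum() == 1:
        logger.warning("all genes fall into a single methylation bin")
    return out


def delta_vs_expression(
    linked: pd.DataFrame,
    candidates: Sequence[str] | None = None,
) -> dict:
    """Per-gene (delta-beta, log2 ratio) pairs, their Pearson correlation,
    and the direction-agreement fraction over a candidate gene list.

    Genes with a zero delta or zero ratio are excluded from the agreement
    denominator.
    """
    if linked.empty:
        raise ValueError("no linked genes")
    pairs = linked[["delta_beta", "log2_ratio"]].copy()
    corr = float(np.corrcoef(pairs["delta_beta"],
                             pairs["log2_ratio"])[0, 1]) \
        if len(pairs) >= 2 else float("nan")
    agreement = float("nan")
    n_candidates = 0
    if candidates is not None:
        cand = [str(c).upper() for c in candidates]
        sub = linked.loc[linked.index.intersection(cand),
                         "direction_agreement"].dropna()
        n_candidates = len(sub)
        if n_candidates:
            agreement = float(sub.mean())
    return {
        "pairs": pairs,
        "correlation": corr,
        "agreement_fraction": agreement,
        "n_candidates": n_candidates,
    }


def compare_platforms(
    beta: BetaMatrix,
    profiles: Sequence[PyroProfile],
    groups: tuple[Sequence[str], Sequence[str]],
) -> dict:
    """Array-vs-pyrosequencing consistency at the profiled target CpGs.

    Per target CpG: group-mean array beta and pyro fraction (percent/100),
    the platform offset (pyro - array), each platform's between-group
    delta, plus the Pearson correlation of the two delta vectors across
    CpGs and a per-island neighbor-vs-target similarity summary.
    """
    a_ids, b_ids = [list(g) for g in groups]
    rows = []
    neighbor_corrs = {}
    for prof in profiles:
        if prof.target_cpg_id not in beta.cpg_ids:
            raise KeyError(
                f"profile target {prof.target_cpg_id!r} missing from the "
                "beta matrix"
            )
        missing = [s for s in a_ids + b_ids if s not in prof.percent.columns]
        if missing:
            raise ValueError(
                f"island {prof.island_id!r}: missing group samples "
                f"{missing[:5]}"
            )
        array = beta.values.loc[prof.target_cpg_id]
        pyro = prof.percent.loc[prof.target_position] / 100.0
        arr_a, arr_b = float(array[a_ids].mean()), float(array[b_ids].mean())
        pyr_a, pyr_b = float(pyro[a_ids].mean()), float(pyro[b_ids].mean())
        all_ids = a_ids + b_ids
        rows.append({
            "cpg_id": prof.target_cpg_id,
            "island_id": prof.island_id,
            "array_a": arr_a, "array_b": arr_b,
            "pyro_a": pyr_a, "pyro_b": pyr_b,
            "offset": float((pyro[all_ids] - array[all_ids]).mean()),
            "array_delta": arr_b - arr_a,
            "pyro_delta": pyr_b - pyr_a,
        })
        corrs = []
        target_vec = prof.percent.loc[prof.target_position].to_numpy()
        for pos in prof.percent.index:
            if pos == prof.target_position:
                continue
            vec = prof.percent.loc[pos].to_numpy()
            if np.std(vec) > 0 and np.std(target_vec) > 0:
                corrs.append(float(np.corrcoef(target_vec, vec)[0, 1]))
        neighbor_corrs[prof.island_id] = (float(np.mean(corrs))
                                          if corrs else float("nan"))
    per_cpg = pd.DataFrame(rows).set_index("cpg_id")
    if len(per_cpg) >= 2:
        delta_corr = float(np.corrcoef(per_cpg["array_delta"],
                                       per_cpg["pyro_delta"])[0, 1])
    else:
        delta_corr = float("nan")
    return {
        "per_cpg": per_cpg,
        "delta_correlation": delta_corr,
        "mean_offset": float(per_cpg["offset"].mean()),
        "neighbor_target_correlation": neighbor_corrs,
    }
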