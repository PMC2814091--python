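"""Over-representation of DM gene lists in gene sets.

One-sided hypergeometric tail test (P[X >= k]) of a selected gene list
against each set of a collection, within a universe of genes carrying at
least one analyzed CpG; BH adjustment across the tested sets.  Cytogenetic
band sets are built directly from the CpG annotation so positional
enrichment reuses the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from senemeth.diffmeth import ContrastResult
from senemeth.io_formats import FormatError, GeneSetCollection, parse_band

__all__ = [
    "genes_from_cpgs",
    "gene_universe",
    "overrepresentation",
    "band_sets",
]

logger = logging.getLogger(__name__)


def genes_from_cpgs(result: ContrastResult, annotation: pd.DataFrame,
                    direction: str) -> list[str]:
    """Deduplicated gene symbols of CpGs labeled ``direction``.

    CpGs without a gene symbol are dropped (count logged).
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    cpgs = result.dm_cpgs(direction)
    symbols = annotation.loc[annotation.index.intersection(cpgs),
                             "gene_symbol"]
    n_missing = int(symbols.isna().sum())
    if n_missing:
        logger.info("%d %s CpGs lack a gene symbol and were dropped",
                    n_missing, direction)
    genes = sorted(symbols.dropna().str.upper().unique())
    if not genes:
        logger.info("no genes for direction %s", direction)
    return genes


def gene_universe(cpg_ids: Iterable[str], annotation: pd.DataFrame) -> set[str]:
    """All genes with >= 1 CpG among ``cpg_ids`` (the sampling frame)."""
    ids = annotation.index.intersection(pd.Index(cpg_ids))
    return set(annotation.loc[ids, "gene_symbol"].dropna().str.upper())


def hypergeom_tail(k: int, n_universe: int, n_set: int, n_selected: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N=n_universe, K=n_set, n=n_selected)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_selected))


def overrepresentation(
    selected: Sequence[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    direction: str = "",
    min_set_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in every set.

    Sets are intersected with the universe first; emptied (or sub-minimum)
    sets are skipped.  Returns one row per tested set with columns k, n, K,
    N, p and BH q, sorted by p.
    """
    uni = {str(g).upper() for g in universe}
    sel = {str(g).upper() for g in selected}
    outside = sel - uni
    if outside:
        raise ValueError(
            f"selected genes outside the universe: {sorted(outside)[:10]}"
        )
    restricted = sets.restricted_to(uni)
    rows = []
    for name in restricted.names():
        members = restricted[name].members
        if len(members) < min_set_size:
            continue
        k = len(sel & members)
        rows.append({
            "set_name": name,
            "k": k,
            "n": len(sel),
            "K": len(members),
            "N": len(uni),
            "p": hypergeom_tail(k, len(uni), len(members), len(sel)),
            "direction": direction,
        })
    df = pd.DataFrame(rows,
                      columns=["set_name", "k", "n", "K", "N", "p",
                               "direction"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "set_name"]).reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def band_sets(annotation: pd.DataFrame) -> GeneSetCollection:
    """One gene set per cytogenetic band present in the annotation.

    Genes with an unparseable or absent band are excluded with a warning.
    """
    coll = GeneSetCollection()
    by_band: dict[str, set[str]] = {}
    for _, row in annotation.iterrows():
        gene, band = row["gene_symbol"], row["band"]
        if not gene or pd.isna(gene) or not band:
            continue
        try:
            parse_band(band)
        except FormatError:
            logger.warning("gene %s: unparseable band %r, excluded from "
                           "band sets", gene, band)
            continue
        by_band.setdefault(band, set()).add(str(gene).upper())
    for band, genes in sorted(by_band.items()):
        coll.add(f"band_{band}", genes,
                 description=f"genes at cytogenetic band {band}")
    return coll
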