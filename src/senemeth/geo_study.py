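"""Reproduction recipe for the deposited 16-sample methylation study.

The deposited series-matrix file is not redistributable here; download it
manually (see README) and point :func:`load_geo_study` at the uncompressed
text file.  Sample metadata keys in GEO submissions are free-form, so the
design builder is best-effort: it infers passage group, age group and donor
pairing from the ``!Sample_*`` header lines and accepts a hand-written
design TSV as an override.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from senemeth import concordance as conc
from senemeth import diffmeth
from senemeth.io_formats import (
    BetaMatrix,
    FormatError,
    StudyDesign,
    read_design_tsv,
    read_geo_series_matrix,
)
from senemeth.preprocess import filter_missing

__all__ = ["design_from_geo_metadata", "load_geo_study",
           "compute_headline_counts"]

#: donor-age boundary between the study's young and elderly groups (years)
YOUNG_MAX_AGE = 50
#: passages at or below this count as "early"
EARLY_MAX_PASSAGE = 2

_INT_RE = re.compile(r"(\d+)")
_PASSAGE_TITLE_RE = re.compile(r"\bP(\d+)\b", re.IGNORECASE)


def _first_int(text: str) -> int | None:
    m = _INT_RE.search(str(text))
    return int(m.group(1)) if m else None


def _find_column(meta: pd.DataFrame, *needles: str) -> str | None:
    for col in meta.columns:
        low = col.lower()
        if any(n in low for n in needles):
            return col
    return None


def design_from_geo_metadata(meta: pd.DataFrame) -> StudyDesign:
    """Best-effort study design from series-matrix sample metadata.

    Passage numbers are taken from a characteristics column mentioning
    "passage", falling back to a ``P<number>`` token in the sample title;
    ages from a column mentioning "age"; donors from a column mentioning
    donor/patient/individual, falling back to grouping samples that share
    an age.
    """
    passage_col = _find_column(meta, "passage")
    age_col = _find_column(meta, "age")
    donor_col = _find_column(meta, "donor", "patient", "individual")
    title_col = _find_column(meta, "title")

    rows = []
    for sample_id, row in meta.iterrows():
        passage = None
        if passage_col is not None:
            passage = _first_int(row[passage_col])
        if passage is None and title_col is not None:
            m = _PASSAGE_TITLE_RE.search(str(row[title_col]))
            passage = int(m.group(1)) if m else None
        if passage is None:
            raise FormatError(
                f"sample {sample_id!r}: cannot infer passage number from "
                "metadata; supply a design TSV instead"
            )
        age = _first_int(row[age_col]) if age_col is not None else None
        if age is None:
            raise FormatError(
                f"sample {sample_id!r}: cannot infer donor age from "
                "metadata; supply a design TSV instead"
            )
        donor = str(row[donor_col]) if donor_col is not None else f"age{age}"
        rows.append({
            "sample_id": sample_id,
            "donor_id": donor,
            "passage_group": "early" if passage <= EARLY_MAX_PASSAGE
            else "late",
            "age_group": "young" if age <= YOUNG_MAX_AGE else "elderly",
            "age_years": age,
            "passage_number": passage,
        })
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


def load_geo_study(matrix_path: str | Path,
                   design_path: str | Path | None = None
                   ) -> tuple[BetaMatrix, StudyDesign]:
    """Load the deposited beta matrix plus a (possibly inferred) design.

    The deposited values are taken as the analyzed betas (already
    normalized by the submitters); CpGs with missing values are dropped.
    """
    matrix, meta = read_geo_series_matrix(matrix_path)
    if not isinstance(matrix, BetaMatrix):
        raise FormatError(f"{matrix_path}: data table is not on the beta "
                          "scale")
    beta, _ = filter_missing(matrix)
    design = (read_design_tsv(design_path) if design_path is not None
              else design_from_geo_metadata(meta))
    missing = set(beta.sample_ids) - set(design.sample_ids)
    if missing:
        raise FormatError(f"design lacks samples: {sorted(missing)[:5]}")
    return beta, design


def compute_headline_counts(beta: BetaMatrix, design: StudyDesign,
                            delta_threshold: float = 0.20,
                            shared_threshold: float = 0.15,
                            p_threshold: float = 0.01) -> dict:
    """The study's headline DM/concordance counts from a beta matrix.

    Returns per-direction DM counts for both contrasts (delta + t-test
    significance), shared-change counts at the strict and relaxed delta
    cutoffs (delta only), and the culture DM counts within each donor-age
    subgroup (delta only).
    """
    results = {}
    for spec in (diffmeth.CULTURE_CONTRAST, diffmeth.AGING_CONTRAST):
        res = diffmeth.contrast_stats(beta, design, spec)
        diffmeth.classify_dm(res, delta_threshold, p_threshold)
        results[spec.name] = res

    joined = conc.join_contrasts(results["culture"], results["aging"])
    subgroups = conc.subgroup_dm_counts(
        beta, design, diffmeth.CULTURE_CONTRAST,
        delta_threshold=delta_threshold, p_threshold=None)

    out = {"n_cpgs": beta.shape[0]}
    for contrast in ("culture", "aging"):
        tbl = results[contrast].table
        out[f"{contrast}_hyper"] = int((tbl["dm_label"] == "hyper").sum())
        out[f"{contrast}_hypo"] = int((tbl["dm_label"] == "hypo").sum())
    out["shared_strict"] = int(len(conc.select_shared_dm(joined,
                                                         delta_threshold)))
    out["shared_relaxed"] = int(len(conc.select_shared_dm(joined,
                                                          shared_threshold)))
    selected = conc.select_shared_dm(joined, shared_threshold)
    if len(selected) >= 2:
        cres = conc.concordance_stats(selected, shared_threshold)
        out["shared_pearson_r"] = cres.pearson_r
        out["shared_chi2_p"] = cres.chi2_p
    out["culture_dm_young"] = subgroups["counts"]["young"]
    out["culture_dm_elderly"] = subgroups["counts"]["elderly"]
    return out
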