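"""Readers/writers for the pipeline's external formats and the core data model.

All tabular formats are tab-separated UTF-8 with a decimal point, matching
GEO/GMT conventions.  Missing beta values are written as ``NA``; empty cells
and ``NA`` are both accepted on read.  Gene symbols are case-normalized to
uppercase at ingest so that methylation and expression tables join on a
canonical key.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "StudyDesign",
    "ExpressionMatrix",
    "GeneSetCollection",
    "PyroProfile",
    "FormatError",
    "read_beta_tsv",
    "write_beta_tsv",
    "read_geo_series_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_pyro_csv",
    "write_pyro_csv",
    "parse_band",
]

PASSAGE_GROUPS = ("early", "late")
AGE_GROUPS = ("young", "elderly")

_BAND_RE = re.compile(r"^(\d{1,2}|X|Y)([pq])(\d+(?:\.\d+)?)$")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def parse_band(band: str) -> tuple[str, str, str]:
    """Split a cytogenetic band string like ``10q22`` into (chrom, arm, band).

    Raises :class:`FormatError` if the string does not parse.
    """
    m = _BAND_RE.match(band)
    if m is None:
        raise FormatError(f"unparseable cytogenetic band: {band!r}")
    return m.group(1), m.group(2), m.group(3)


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation fractions in [0, 1].

    ``values`` is a float DataFrame indexed by CpG id with one column per
    sample; missing entries are NaN.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "CpG ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value out of [0, 1] at CpG {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)])

    def subset_cpgs(self, cpg_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(cpg_ids)])


def read_beta_tsv(path: str | Path) -> BetaMatrix:
    """Read a beta matrix TSV: first column CpG ids, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    _check_unique(df.index, f"CpG ids in {path}")
    _check_unique(df.columns, f"sample ids in {path}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        numeric = pd.to_numeric(raw.mask(raw.isin(["", "NA"])),
                                errors="coerce")
        bad = numeric.isna() & ~raw.isin(["", "NA"])
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"non-numeric beta value at CpG {row!r}, sample {col!r} "
                f"in {path}: {df.loc[row, col]!r}"
            )
        out[col] = numeric.to_numpy()
    return BetaMatrix(out)


def write_beta_tsv(beta: BetaMatrix, path: str | Path) -> None:
    df = beta.values.copy()
    df.index.name = "cpg_id"
    # no float_format: the shortest round-trip repr keeps reader/writer
    # pairs lossless and downstream stages bit-reproducible from disk
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# StudyDesign
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """Per-sample metadata: donor, passage group, age group, optional ages.

    ``table`` is indexed by sample_id with columns donor_id, passage_group,
    age_group, age_years, passage_number.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"donor_id", "passage_group", "age_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample ids")
        for col in ("age_years", "passage_number"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        bad_pg = set(self.table["passage_group"]) - set(PASSAGE_GROUPS)
        if bad_pg:
            raise FormatError(f"unknown passage_group values: {sorted(bad_pg)}")
        bad_ag = set(self.table["age_group"]) - set(AGE_GROUPS)
        if bad_ag:
            raise FormatError(f"unknown age_group values: {sorted(bad_ag)}")
        for donor, grp in self.table.groupby("donor_id"):
            if grp["passage_group"].duplicated().any():
                raise FormatError(
                    f"donor {donor!r} has more than one sample per passage group"
                )
            if grp["age_group"].nunique() > 1:
                raise FormatError(f"donor {donor!r} has inconsistent age_group")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids matching all column==value conditions."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])

    def donors_with_complete_pairs(self) -> list[str]:
        """Donors contributing one early and one late sample."""
        out = []
        for donor, grp in self.table.groupby("donor_id", sort=False):
            if set(grp["passage_group"]) >= set(PASSAGE_GROUPS):
                out.append(donor)
        return out


def read_design_tsv(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str)
    for col in ("age_years", "passage_number"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return StudyDesign(df)


def write_design_tsv(design: StudyDesign, path: str | Path) -> None:
    df = design.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe-by-sample log2 intensities with present/marginal/absent calls."""

    intensities: pd.DataFrame
    calls: pd.DataFrame
    probe_to_symbol: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.shape != self.calls.shape:
            raise FormatError(
                "intensity and call matrices differ in shape: "
                f"{self.intensities.shape} vs {self.calls.shape}"
            )
        _check_unique(self.intensities.index, "probe ids")
        bad = set(np.unique(self.calls.to_numpy())) - {"P", "M", "A"}
        if bad:
            raise FormatError(f"unknown present calls: {sorted(bad)}")
        self.probe_to_symbol = self.probe_to_symbol.reindex(
            self.intensities.index
        ).str.upper()

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    """One wide TSV: probe_id, gene_symbol, per-sample intensity and call."""
    df = pd.DataFrame(index=expr.probe_ids)
    df["gene_symbol"] = expr.probe_to_symbol
    for s in expr.sample_ids:
        df[s] = expr.intensities[s]
        df[f"{s}__call"] = expr.calls[s]
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    samples = [c for c in df.columns
               if c != "gene_symbol" and not c.endswith("__call")]
    intens = df[samples].astype(float)
    calls = df[[f"{s}__call" for s in samples]]
    calls.columns = samples
    return ExpressionMatrix(intens, calls, df["gene_symbol"].astype(str))


# ---------------------------------------------------------------------------
# GeneSetCollection / GMT
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets with deduplicated, uppercase member symbols."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        symbols = frozenset(str(m).upper() for m in members if str(m).strip())
        if not symbols:
            raise FormatError(f"gene set {name!r} has no members")
        self.sets[name] = GeneSet(name, description, symbols)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a gene universe, dropping emptied sets."""
        uni = {str(g).upper() for g in universe}
        out = GeneSetCollection()
        for gs in self.sets.values():
            members = gs.members & uni
            if members:
                out.sets[gs.name] = GeneSet(gs.name, gs.description,
                                            frozenset(members))
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated name, description, member symbols."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            coll.add(fields[0], fields[2:], description=fields[1])
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll.sets.values():
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# CpG annotation manifest
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["gene_symbol", "chromosome", "band", "island_id",
                      "neighbor_offsets"]


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """Read the CpG annotation manifest.

    Returns a DataFrame indexed by cpg_id with columns gene_symbol,
    chromosome, band, island_id and neighbor_offsets (list of int bp).
    Band strings are validated against the chromosome+arm+band grammar.
    """
    df = pd.read_csv(path, sep="\t", index_col="cpg_id", dtype=str,
                     keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    _check_unique(df.index, "CpG ids")
    df["gene_symbol"] = df["gene_symbol"].str.upper().replace({"": None})
    for cpg, band in df["band"].items():
        if band:
            parse_band(band)
    df["neighbor_offsets"] = df["neighbor_offsets"].map(
        lambda s: [int(x) for x in s.split(",")] if s else []
    )
    return df


def write_annotation_tsv(annotation: pd.DataFrame, path: str | Path) -> None:
    df = annotation.copy()
    df["neighbor_offsets"] = df["neighbor_offsets"].map(
        lambda offs: ",".join(str(int(o)) for o in offs)
    )
    df.index.name = "cpg_id"
    df.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# Pyrosequencing profiles
# ---------------------------------------------------------------------------

@dataclass
class PyroProfile:
    """Percent methylation across one CpG island measured by pyrosequencing.

    ``percent`` is a position-by-sample DataFrame of percent methylation in
    [0, 100]; ``target_position`` marks the bp offset of the array-assayed CpG.
    """

    island_id: str
    target_cpg_id: str
    target_position: int
    percent: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.percent.to_numpy(dtype=float)
        if np.any((arr < 0) | (arr > 100)):
            raise FormatError(
                f"percent methylation out of [0, 100] in island {self.island_id!r}"
            )
        if self.target_position not in set(self.percent.index):
            raise FormatError(
                f"target position {self.target_position} not among listed "
                f"positions of island {self.island_id!r}"
            )


def write_pyro_csv(profiles: Iterable[PyroProfile], path: str | Path) -> None:
    """Long-format CSV: island_id, target_cpg_id, position_bp, is_target,
    sample_id, percent_meth."""
    rows = []
    for prof in profiles:
        for pos in prof.percent.index:
            for sample in prof.percent.columns:
                rows.append({
                    "island_id": prof.island_id,
                    "target_cpg_id": prof.target_cpg_id,
                    "position_bp": int(pos),
                    "is_target": int(pos == prof.target_position),
                    "sample_id": sample,
                    "percent_meth": float(prof.percent.loc[pos, sample]),
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pyro_csv(path: str | Path) -> list[PyroProfile]:
    df = pd.read_csv(path)
    required = {"island_id", "target_cpg_id", "position_bp", "is_target",
                "sample_id", "percent_meth"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"pyro CSV missing columns: {sorted(missing)}")
    out = []
    for (island, target_cpg), grp in df.groupby(["island_id", "target_cpg_id"],
                                                sort=False):
        wide = grp.pivot(index="position_bp", columns="sample_id",
                         values="percent_meth")
        wide = wide[grp["sample_id"].unique()]
        targets = grp.loc[grp["is_target"] == 1, "position_bp"].unique()
        if len(targets) != 1:
            raise FormatError(
                f"island {island!r}: expected exactly one target position, "
                f"found {len(targets)}"
            )
        out.append(PyroProfile(str(island), str(target_cpg),
                               int(targets[0]), wide))
    return out


# ---------------------------------------------------------------------------
# GEO series-matrix dialect
# ---------------------------------------------------------------------------

def _dequote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


def read_geo_series_matrix(
    path: str | Path,
) -> tuple[BetaMatrix | ExpressionMatrix, pd.DataFrame]:
    """Parse a GEO series-matrix text file (subset of the dialect).

    Header lines start with ``!``; the single data table sits between
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end``.
    Returns the data table — as a :class:`BetaMatrix` when every value lies
    in [0, 1], otherwise an :class:`ExpressionMatrix` with all calls ``P`` —
    plus a sample-metadata frame assembled from the ``!Sample_*`` lines
    (one row per sample; characteristics lines of the form ``key: value``
    become their own columns).
    """
    header: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                saw_begin, in_table = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                saw_end, in_table = True, False
                continue
            if in_table:
                if line.strip():
                    table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line[1:].partition("\t")
                header.setdefault(key, []).append(
                    [_dequote(f) for f in rest.split("\t")]
                )
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing series_matrix_table_begin/end sentinels"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty data table")

    rows = [ln.split("\t") for ln in table_lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise FormatError(
                f"{path}: ragged data table at line {i + 1} "
                f"({len(r)} fields, expected {width})"
            )
    cells = [[_dequote(c) for c in r] for r in rows]
    columns = cells[0][1:]
    index = [r[0] for r in cells[1:]]
    data = pd.DataFrame(
        [[np.nan if c in ("", "NA", "null") else float(c) for c in r[1:]]
         for r in cells[1:]],
        index=pd.Index(index, name="id"), columns=columns, dtype=float,
    )

    meta = pd.DataFrame(index=pd.Index(columns, name="sample_id"))
    for key, entries in header.items():
        if not key.startswith("Sample_"):
            continue
        name = key[len("Sample_"):]
        for entry in entries:
            vals = (entry + [""] * len(columns))[: len(columns)]
            # characteristics lines carry "key: value" payloads
            kv = [v.partition(": ") for v in vals]
            if name.startswith("characteristics") and all(
                mid for _, mid, _ in kv if _ or mid
            ) and any(mid for _, mid, _ in kv):
                col = next(k for k, mid, _ in kv if mid)
                meta[col.strip()] = [v for _, _, v in kv]
            else:
                col = name
                suffix = 2
                while col in meta.columns:
                    col = f"{name}.{suffix}"
                    suffix += 1
                meta[col] = vals

    arr = data.to_numpy()
    finite = arr[~np.isnan(arr)]
    if finite.size and finite.min() >= 0.0 and finite.max() <= 1.0:
        return BetaMatrix(data), meta
    calls = pd.DataFrame("P", index=data.index, columns=data.columns)
    symbols = pd.Series(data.index, index=data.index, dtype=str)
    return ExpressionMatrix(data, calls, symbols), meta
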