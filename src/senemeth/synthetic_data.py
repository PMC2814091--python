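"""Synthetic bisulfite-array study generator with ground truth.

Emulates the statistical structure the downstream analysis assumes: a
16-sample design (8 donors, 4 young / 4 elderly, each sampled at an early
and a late passage), bimodal promoter beta baselines, additive delta-beta
effects at a minority of CpGs — some shared between the culture and aging
contrasts with concordant sign — bounded per-sample beta noise, and gene
expression negatively coupled to promoter methylation.

Effects are additive on the beta scale with clipping to (0.01, 0.99); the
ground truth table records the *realized* per-contrast delta (after any
clipping) alongside the nominal label, so recovery tests compare against
what the generator actually injected.

All randomness flows from a single seed through independently spawned
child streams, one per generated artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from senemeth.io_formats import (
    BetaMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    PyroProfile,
    StudyDesign,
)

__all__ = [
    "SimulationParams",
    "TruthTable",
    "IntensityPair",
    "generate_annotation",
    "generate_methylation_study",
    "generate_intensities",
    "generate_expression",
    "generate_pyro_profiles",
]

#: cytogenetic bands used for synthetic gene placement
_BAND_POOL = ("1p36", "2p25", "5q31", "6q27", "7p15", "10q22",
              "12q24", "17q21", "20q13", "21q22")

TF_TARGET_SET = "SP1_TARGETS"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study.

    Baseline beta means are drawn from a three-mode mixture (low /
    intermediate / high methylation); per-sample values are Beta-distributed
    around the CpG mean with concentration ``phi``.
    """

    n_cpgs: int = 2000
    n_donors_young: int = 4
    n_donors_elderly: int = 4
    mixture_weights: tuple[float, float, float] = (0.45, 0.10, 0.45)
    mixture_means: tuple[float, float, float] = (0.10, 0.50, 0.90)
    mixture_concentration: float = 30.0
    phi: float = 200.0
    n_dm_culture: tuple[int, int] = (10, 15)   # (hyper, hypo)
    n_dm_aging: tuple[int, int] = (15, 20)
    effect_range: tuple[float, float] = (0.15, 0.40)
    shared_fraction: float = 0.3
    sign_concordance: float = 0.9
    passage_drift: float = 0.0
    expression_slope: float = -4.0
    expression_intercept: float = 10.0
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        for name in ("shared_fraction", "sign_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isclose(sum(self.mixture_weights), 1.0):
            raise ValueError("mixture_weights must sum to 1")
        lo, hi = self.effect_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"invalid effect_range {self.effect_range}")
        if sum(self.n_dm_culture) + sum(self.n_dm_aging) > self.n_cpgs:
            raise ValueError("more true DM CpGs requested than CpGs")

    @property
    def n_donors(self) -> int:
        return self.n_donors_young + self.n_donors_elderly

    def with_(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class TruthTable:
    """Per-CpG ground truth: realized deltas and labels per contrast.

    ``table`` is indexed by cpg_id with columns delta_culture, delta_aging
    (realized mean differences the respective contrast would see in
    expectation), label_culture / label_aging in {hyper, hypo, null} and a
    ``clipped`` flag marking CpGs whose nominal effect was truncated.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for contrast in ("culture", "aging"):
            lab = self.table[f"label_{contrast}"]
            delta = self.table[f"delta_{contrast}"]
            if ((lab == "null") != (delta == 0.0)).any():
                raise ValueError(f"label/delta inconsistency in {contrast}")
            if ((lab == "hyper") & (delta < 0)).any() or \
               ((lab == "hypo") & (delta > 0)).any():
                raise ValueError(f"label sign mismatch in {contrast}")

    def true_positives(self, contrast: str, direction: str | None = None) -> pd.Index:
        lab = self.table[f"label_{contrast}"]
        mask = lab != "null" if direction is None else lab == direction
        return self.table.index[mask]

    def write_tsv(self, path) -> None:
        df = self.table.copy()
        df.index.name = "cpg_id"
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class IntensityPair:
    """Methylated (M) and unmethylated (U) channel signals per CpG/sample."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame

    def __post_init__(self) -> None:
        m, u = self.methylated.to_numpy(), self.unmethylated.to_numpy()
        if np.nanmin(m, initial=0.0) < 0 or np.nanmin(u, initial=0.0) < 0:
            raise ValueError("channel intensities must be >= 0")


def _cpg_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:07d}" for i in range(1, n + 1)], name="cpg_id")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    params: SimulationParams, seed: int | None = None
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Assign CpGs to genes (1-3 CpGs each), genes to bands and gene sets.

    The collection carries a handful of GO-style sets plus one designated
    TF-target set (:data:`TF_TARGET_SET`).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    cpgs = _cpg_ids(params.n_cpgs)

    genes: list[str] = []
    gene_of: list[str] = []
    i = 0
    g = 0
    while i < params.n_cpgs:
        g += 1
        name = f"GENE{g:05d}"
        genes.append(name)
        for _ in range(min(int(rng.integers(1, 4)), params.n_cpgs - i)):
            gene_of.append(name)
            i += 1

    band_of_gene = {g: _BAND_POOL[int(rng.integers(len(_BAND_POOL)))]
                    for g in genes}
    n_neigh = rng.integers(2, 5, size=params.n_cpgs)
    offsets = [
        sorted(rng.choice(np.arange(-90, 91, 5)[np.arange(-90, 91, 5) != 0],
                          size=k, replace=False).tolist())
        for k in n_neigh
    ]
    annotation = pd.DataFrame(
        {
            "gene_symbol": gene_of,
            "chromosome": [band_of_gene[g].rstrip("0123456789.")[:-1]
                           for g in gene_of],
            "band": [band_of_gene[g] for g in gene_of],
            "island_id": [f"isl_{g}" for g in gene_of],
            "neighbor_offsets": offsets,
        },
        index=cpgs,
    )

    coll = GeneSetCollection()
    n_sets = max(2, min(8, len(genes) // 5))
    shuffled = list(genes)
    rng.shuffle(shuffled)
    for s, chunk in enumerate(np.array_split(np.array(shuffled), n_sets)):
        if len(chunk):
            coll.add(f"PATHWAY_{s + 1:02d}", chunk.tolist(),
                     description=f"synthetic pathway {s + 1}")
    n_tf = max(1, len(genes) // 5)
    coll.add(TF_TARGET_SET,
             rng.choice(np.array(genes), size=n_tf, replace=False).tolist(),
             description="genes with TF binding sites in the promoter")
    return annotation, coll


# ---------------------------------------------------------------------------
# Methylation study
# ---------------------------------------------------------------------------

def _draw_baselines(params: SimulationParams, rng: np.random.Generator,
                    size: int) -> np.ndarray:
    mode = rng.choice(3, size=size, p=np.asarray(params.mixture_weights))
    means = np.asarray(params.mixture_means)[mode]
    c = params.mixture_concentration
    base = rng.beta(means * c, (1.0 - means) * c)
    return np.clip(base, 0.01, 0.99)


def _design(params: SimulationParams, rng: np.random.Generator) -> StudyDesign:
    rows = []
    for d in range(params.n_donors):
        young = d < params.n_donors_young
        donor = f"D{d + 1}"
        age = int(rng.integers(21, 51)) if young else int(rng.integers(53, 86))
        late_passage = int(rng.integers(8, 16))
        for pg, pnum in (("early", 2), ("late", late_passage)):
            rows.append({
                "sample_id": f"{donor}_{pg}",
                "donor_id": donor,
                "passage_group": pg,
                "age_group": "young" if young else "elderly",
                "age_years": age,
                "passage_number": pnum,
            })
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


def _assign_effects(
    params: SimulationParams, rng: np.random.Generator, baselines: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick DM CpGs and effect sizes; returns (eff_culture, eff_aging,
    adjusted baselines).

    Shared CpGs carry effects in both contrasts; their aging sign agrees
    with the culture sign with probability ``sign_concordance``.  Baselines
    of DM CpGs are re-drawn until the additive effect fits inside
    (0.01, 0.99), so nominal effects are realized un-clipped whenever the
    mixture allows it.
    """
    n = params.n_cpgs
    eff_c = np.zeros(n)
    eff_a = np.zeros(n)
    base = baselines.copy()

    n_c = sum(params.n_dm_culture)
    n_a = sum(params.n_dm_aging)
    n_shared = int(round(params.shared_fraction * min(n_c, n_a)))

    order = rng.permutation(n)
    shared_idx = order[:n_shared]
    culture_only = order[n_shared:n_shared + (n_c - n_shared)]
    aging_only = order[n_c:n_c + (n_a - n_shared)]

    def draw_effect() -> float:
        lo, hi = params.effect_range
        return float(rng.uniform(lo, hi))

    def signs(n_hyper: int, n_hypo: int, k: int) -> np.ndarray:
        pool = np.array([1.0] * n_hyper + [-1.0] * n_hypo)
        rng.shuffle(pool)
        return pool[:k]

    sign_c_shared = signs(*params.n_dm_culture, n_shared)
    concordant = rng.random(n_shared) < params.sign_concordance
    sign_a_shared = np.where(concordant, sign_c_shared, -sign_c_shared)

    remaining_c = (params.n_dm_culture[0] - int((sign_c_shared > 0).sum()),
                   params.n_dm_culture[1] - int((sign_c_shared < 0).sum()))
    remaining_a = (params.n_dm_aging[0] - int((sign_a_shared > 0).sum()),
                   params.n_dm_aging[1] - int((sign_a_shared < 0).sum()))
    sign_c_only = signs(max(remaining_c[0], 0), max(remaining_c[1], 0),
                        len(culture_only))
    sign_a_only = signs(max(remaining_a[0], 0), max(remaining_a[1], 0),
                        len(aging_only))

    for idx, s_c, s_a in zip(shared_idx, sign_c_shared, sign_a_shared):
        eff_c[idx] = s_c * draw_effect()
        eff_a[idx] = s_a * draw_effect()
    for idx, s in zip(culture_only, sign_c_only):
        eff_c[idx] = s * draw_effect()
    for idx, s in zip(aging_only, sign_a_only):
        eff_a[idx] = s * draw_effect()

    # give DM CpGs baseline headroom for the summed effect where possible
    dm = np.flatnonzero((eff_c != 0) | (eff_a != 0))
    for idx in dm:
        lo_need = 0.01 + max(0.0, -(min(eff_c[idx], 0) + min(eff_a[idx], 0)))
        hi_need = 0.99 - max(0.0, max(eff_c[idx], 0) + max(eff_a[idx], 0))
        for _ in range(200):
            if lo_need <= base[idx] <= hi_need:
                break
            base[idx] = _draw_baselines(params, rng, 1)[0]
    return eff_c, eff_a, base


def generate_methylation_study(
    params: SimulationParams, seed: int | None = None
) -> tuple[BetaMatrix, StudyDesign, TruthTable]:
    """Simulate the beta matrix, design and ground truth of one study.

    Per CpG *i* a baseline mean is drawn from the configured mixture; each
    sample's value is Beta-distributed with mean
    ``clip(baseline + applicable effects, 0.01, 0.99)`` and concentration
    ``phi``.  Culture effects apply to late-passage samples, aging effects
    to all samples of elderly donors; the aging contrast reads them off the
    early-passage samples.
    """
    root = np.random.default_rng(params.seed if seed is None else seed)
    r_design, r_base, r_eff, r_noise = root.spawn(4)

    design = _design(params, r_design)
    baselines = _draw_baselines(params, r_base, params.n_cpgs)
    eff_c, eff_a, baselines = _assign_effects(params, r_eff, baselines)

    cpgs = _cpg_ids(params.n_cpgs)
    samples = design.sample_ids
    mu = np.empty((params.n_cpgs, len(samples)))
    for j, sid in enumerate(samples):
        row = design.table.loc[sid]
        m = baselines.copy()
        if row["passage_group"] == "late":
            drift = params.passage_drift * max(row["passage_number"] - 8, 0)
            m = m + eff_c + np.sign(eff_c) * drift
        if row["age_group"] == "elderly":
            m = m + eff_a
        mu[:, j] = np.clip(m, 0.01, 0.99)

    values = r_noise.beta(mu * params.phi, (1.0 - mu) * params.phi)
    beta = BetaMatrix(pd.DataFrame(values, index=cpgs, columns=samples))

    early = [j for j, s in enumerate(samples)
             if design.table.loc[s, "passage_group"] == "early"]
    late = [j for j, s in enumerate(samples)
            if design.table.loc[s, "passage_group"] == "late"]
    young_early = [j for j in early
                   if design.table.iloc[j]["age_group"] == "young"]
    elderly_early = [j for j in early
                     if design.table.iloc[j]["age_group"] == "elderly"]

    delta_c = mu[:, late].mean(axis=1) - mu[:, early].mean(axis=1)
    delta_a = mu[:, elderly_early].mean(axis=1) - mu[:, young_early].mean(axis=1)
    # nulls are exactly zero by construction; clamp float fuzz
    delta_c[eff_c == 0] = 0.0
    delta_a[eff_a == 0] = 0.0

    def labels(eff: np.ndarray) -> np.ndarray:
        lab = np.where(eff > 0, "hyper", np.where(eff < 0, "hypo", "null"))
        return lab

    clipped = (np.abs(delta_c - eff_c) > 1e-9) | (np.abs(delta_a - eff_a) > 1e-9)
    truth = TruthTable(pd.DataFrame(
        {
            "delta_culture": delta_c,
            "delta_aging": delta_a,
            "label_culture": labels(eff_c),
            "label_aging": labels(eff_a),
            "clipped": clipped,
        },
        index=cpgs,
    ))
    return beta, design, truth


# ---------------------------------------------------------------------------
# Channel intensities
# ---------------------------------------------------------------------------

def generate_intensities(
    beta: BetaMatrix,
    total_intensity: float = 2000.0,
    offset: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> IntensityPair:
    """Invent two-channel signals whose beta transform recovers the input.

    At ``noise_sd=0`` the pair satisfies ``M / (M + U + offset) == beta``
    exactly (the per-CpG total is inflated where needed so the offset can
    be absorbed without a negative channel); multiplicative log-normal
    noise is applied per channel otherwise.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be > 0")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    rng = np.random.default_rng(seed)
    b = beta.values.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        needed = np.where(b < 1.0, b * offset / (1.0 - b), np.inf)
    total = np.maximum(total_intensity, np.where(np.isfinite(needed),
                                                 needed, total_intensity))
    m = b * (total + offset)
    u = np.maximum(total - m, 0.0)  # clamp float fuzz at beta -> 1
    if noise_sd > 0:
        m = m * np.exp(rng.normal(0.0, noise_sd, size=m.shape))
        u = u * np.exp(rng.normal(0.0, noise_sd, size=u.shape))
    idx, cols = beta.cpg_ids, beta.sample_ids
    return IntensityPair(
        pd.DataFrame(m, index=idx, columns=cols),
        pd.DataFrame(u, index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gene_mean_beta(beta: BetaMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-sample mean beta over each gene's CpGs."""
    sym = annotation.loc[beta.cpg_ids, "gene_symbol"]
    return beta.values.groupby(sym).mean()


def generate_expression(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    slope: float = -4.0,
    intercept: float = 10.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    call_midpoint: float = 6.0,
    call_scale: float = 1.0,
) -> ExpressionMatrix:
    """Expression coupled to methylation: per gene and sample,
    ``log2 intensity = intercept + slope * gene_mean_beta + noise``.

    Present calls are Bernoulli with probability increasing in intensity
    (logistic around ``call_midpoint``).
    """
    rng = np.random.default_rng(seed)
    gmb = gene_mean_beta(beta, annotation)
    intens = intercept + slope * gmb
    if noise_sd > 0:
        intens = intens + rng.normal(0.0, noise_sd, size=intens.shape)
    p_present = 1.0 / (1.0 + np.exp(-(intens.to_numpy() - call_midpoint)
                                    / call_scale))
    calls = np.where(rng.random(intens.shape) < p_present, "P", "A")
    probe_ids = pd.Index([f"PB_{g}" for g in gmb.index], name="probe_id")
    return ExpressionMatrix(
        pd.DataFrame(intens.to_numpy(), index=probe_ids, columns=gmb.columns),
        pd.DataFrame(calls, index=probe_ids, columns=gmb.columns),
        pd.Series(list(gmb.index), index=probe_ids, dtype=str),
    )


# ---------------------------------------------------------------------------
# Pyrosequencing profiles
# ---------------------------------------------------------------------------

def generate_pyro_profiles(
    beta: BetaMatrix,
    annotation: pd.DataFrame,
    target_cpgs: Sequence[str] | None = None,
    n_targets: int = 6,
    platform_offset: float = -0.05,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> list[PyroProfile]:
    """Percent-methylation profiles across the islands of selected CpGs.

    Neighbor positions inherit the target's per-sample beta plus a small
    position-specific shift and per-measurement jitter, then the platform
    offset, clipped to [0, 100] percent.  Defaults keep neighbors highly
    correlated with their target across samples.
    """
    if not -0.3 < platform_offset < 0.3:
        raise ValueError("platform_offset must lie in (-0.3, 0.3)")
    rng = np.random.default_rng(seed)
    if target_cpgs is None:
        variances = beta.values.var(axis=1)
        target_cpgs = list(variances.sort_values(ascending=False)
                           .index[:n_targets])
    profiles = []
    for cpg in target_cpgs:
        if cpg not in beta.cpg_ids:
            raise KeyError(f"target CpG {cpg!r} not in beta matrix")
        ann = annotation.loc[cpg]
        positions = [0] + [int(o) for o in ann["neighbor_offsets"]]
        base = beta.values.loc[cpg].to_numpy()
        rows = {}
        for pos in sorted(positions):
            shift = 0.0 if pos == 0 else rng.normal(0.0, jitter_sd)
            eps = (rng.normal(0.0, jitter_sd / 2, size=base.shape)
                   if jitter_sd > 0 else 0.0)
            frac = np.clip(base + shift + eps + platform_offset, 0.0, 1.0)
            rows[pos] = 100.0 * frac
        percent = pd.DataFrame(rows, index=beta.sample_ids).T
        percent.index.name = "position_bp"
        profiles.append(PyroProfile(str(ann["island_id"]), cpg, 0, percent))
    return profiles
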