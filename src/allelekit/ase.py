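"""Allelic expression bias: TPM, per-tissue NB tests, categories, dynamics.

The test engine is an in-repo negative-binomial Wald test on
library-size-normalized counts (median-of-ratios size factors,
method-of-moments dispersion pooled per tissue, BH adjustment within
tissue).  The four-level category scheme is applied to adjusted p-values
and the fold change:

====================  =======================================
category              rule (FC = 2**|log2fc|)
====================  =======================================
none                  adjusted p >= 0.05
smaller               significant and FC <= 2
larger                significant and 2 < FC < 8
largest               significant and FC >= 8
====================  =======================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pairing import AllelePair
from .stats import benjamini_hochberg

ALPHA = 0.05
FC_SMALL = 2.0
FC_LARGE = 8.0
TPM_EXPRESSED = 0.5
TOP_FRACTION = 0.10
DISPERSION_FLOOR = 1e-8
PSEUDO_MEAN = 0.5

CATEGORY_ORDER = {"smaller": 1, "larger": 2, "largest": 3}


@dataclass(frozen=True)
class BiasCall:
    locus_id: str
    tissue: str
    log2fc: float
    p: float
    p_adj: float
    category: str


@dataclass
class SpatioTemporalProfile:
    locus_id: str
    effective_log2fc: dict[str, float]
    fc_range: float
    label: str = "neither"  # dynamic | stable | neither
    transition_type: str = "none"  # none | neighboring | jumping


# ---------------------------------------------------------------------------
# normalization


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM_g = (c_g / l_g) / sum_j (c_j / l_j) * 1e6, per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:5].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero samples yield all-zero TPM columns",
            stacklevel=2,
        )
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(tpm: pd.DataFrame, threshold: float = TPM_EXPRESSED) -> pd.Index:
    """Genes whose TPM strictly exceeds ``threshold`` in >= 1 sample."""
    return tpm.index[tpm.max(axis=1) > threshold]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference).

    Falls back to total-count scaling if no gene is positive in every
    sample."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= 1:
        log_geo_mean = np.log(positive).mean(axis=1)
        ratios = np.log(positive).sub(log_geo_mean, axis=0)
        sf = np.exp(ratios.median(axis=0))
    else:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.log(totals.replace(0, np.nan)).mean())
        sf = sf.fillna(1.0)
    return sf


def pooled_dispersion(norm_counts: pd.DataFrame) -> float:
    """Method-of-moments NB dispersion pooled (median) over genes,
    floored at 1e-8.  ``norm_counts`` are size-factor-normalized counts
    for the replicates of one tissue."""
    mean = norm_counts.mean(axis=1)
    var = norm_counts.var(axis=1, ddof=1)
    ok = mean > 0
    alpha = (var[ok] - mean[ok]) / mean[ok] ** 2
    alpha = alpha[alpha > 0]
    if len(alpha) == 0:
        return DISPERSION_FLOOR
    return max(float(alpha.median()), DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# per-pair testing


def nb_wald_test(
    norm_a: np.ndarray, norm_b: np.ndarray, dispersion: float
) -> tuple[float, float]:
    """Two-sided Wald test of equal allele means from normalized counts.

    Returns ``(log2fc, p)`` with log2fc of A over B using pseudo-mean 0.5
    on both alleles; the variance of the log-ratio comes from the NB
    mean-variance relation var = m + dispersion * m**2.
    """
    norm_a = np.asarray(norm_a, dtype=float)
    norm_b = np.asarray(norm_b, dtype=float)
    if norm_a.size < 2 or norm_b.size < 2:
        raise ValueError("need >= 2 replicates per allele")
    m_a = norm_a.mean() + PSEUDO_MEAN
    m_b = norm_b.mean() + PSEUDO_MEAN
    log2fc = math.log2(m_a / m_b)
    var_a = (m_a + dispersion * m_a**2) / norm_a.size
    var_b = (m_b + dispersion * m_b**2) / norm_b.size
    var_log = var_a / m_a**2 + var_b / m_b**2
    if var_log <= 0:
        return log2fc, 1.0
    z = abs(math.log(m_a / m_b)) / math.sqrt(var_log)
    p = math.erfc(z / math.sqrt(2.0))
    return log2fc, min(p, 1.0)


def classify_bias(
    log2fc: float,
    p_adj: float,
    alpha: float = ALPHA,
    fc_small: float = FC_SMALL,
    fc_large: float = FC_LARGE,
) -> str:
    if p_adj >= alpha:
        return "none"
    fc = 2.0 ** abs(log2fc)
    if fc <= fc_small:
        return "smaller"
    if fc < fc_large:
        return "larger"
    return "largest"


def test_allelic_bias(
    counts: pd.DataFrame,
    pairs: Sequence[AllelePair],
    sample_tissue: Mapping[str, str],
    include_global: bool = True,
) -> list[BiasCall]:
    """Per-tissue (and optionally pooled "global") bias calls for all pairs.

    Size factors are computed once over all samples; dispersion is pooled
    per tissue; BH adjustment is applied within each tissue across loci.
    """
    sf = size_factors(counts)
    norm = counts.div(sf, axis=1)
    tissues: dict[str, list[str]] = {}
    for sample in counts.columns:
        tissues.setdefault(sample_tissue[sample], []).append(sample)
    groups = dict(sorted(tissues.items()))
    if include_global:
        groups["global"] = list(counts.columns)

    calls: list[BiasCall] = []
    n_excluded = 0
    for tissue, samples in groups.items():
        if len(samples) < 2:
            n_excluded += len(pairs)
            continue
        sub = norm[samples]
        dispersion = pooled_dispersion(sub)
        rows = []
        for pair in pairs:
            if pair.gene_a not in sub.index or pair.gene_b not in sub.index:
                n_excluded += 1
                continue
            log2fc, p = nb_wald_test(
                sub.loc[pair.gene_a].to_numpy(),
                sub.loc[pair.gene_b].to_numpy(),
                dispersion,
            )
            rows.append((pair.locus_id, log2fc, p))
        if not rows:
            continue
        p_adj = benjamini_hochberg(np.array([r[2] for r in rows]))
        for (locus_id, log2fc, p), q in zip(rows, p_adj):
            calls.append(
                BiasCall(
                    locus_id=locus_id,
                    tissue=tissue,
                    log2fc=log2fc,
                    p=p,
                    p_adj=float(q),
                    category=classify_bias(log2fc, float(q)),
                )
            )
    if n_excluded:
        warnings.warn(f"{n_excluded} locus/tissue tests excluded", stacklevel=2)
    return calls


# ---------------------------------------------------------------------------
# spatiotemporal profiles


def build_profiles(
    calls: Iterable[BiasCall], tissues: Sequence[str]
) -> list[SpatioTemporalProfile]:
    """Significance-masked signed log2fc vectors and their ranges.

    A tissue where the adjusted p is >= 0.05 contributes an effective
    log2fc of 0 (the pair is considered to show no difference there).
    """
    per_locus: dict[str, dict[str, float]] = {}
    for call in calls:
        if call.tissue not in tissues:
            continue
        eff = call.log2fc if call.p_adj < ALPHA else 0.0
        per_locus.setdefault(call.locus_id, {})[call.tissue] = eff
    profiles = []
    for locus_id in sorted(per_locus):
        vec = {t: per_locus[locus_id].get(t, 0.0) for t in tissues}
        values = list(vec.values())
        profiles.append(
            SpatioTemporalProfile(
                locus_id=locus_id,
                effective_log2fc=vec,
                fc_range=max(values) - min(values),
            )
        )
    return profiles


def rank_dynamic_stable(
    profiles: list[SpatioTemporalProfile], top_fraction: float = TOP_FRACTION
) -> list[SpatioTemporalProfile]:
    """Label the top 10% by fc_range dynamic and the bottom 10% stable."""
    n = len(profiles)
    k = int(n * top_fraction)
    if n < 10 or k == 0:
        warnings.warn(
            f"only {n} loci: dynamic/stable labels withheld", stacklevel=2
        )
        return profiles
    by_range_desc = sorted(profiles, key=lambda p: (-p.fc_range, p.locus_id))
    by_range_asc = sorted(profiles, key=lambda p: (p.fc_range, p.locus_id))
    dynamic = {p.locus_id for p in by_range_desc[:k]}
    stable = {p.locus_id for p in by_range_asc[:k] if p.locus_id not in dynamic}
    for p in profiles:
        if p.locus_id in dynamic:
            p.label = "dynamic"
        elif p.locus_id in stable:
            p.label = "stable"
        else:
            p.label = "neither"
    return profiles


def transition_summary(
    calls: Iterable[BiasCall], tissues: Sequence[str]
) -> dict:
    """Neighboring vs jumping category transitions across tissues.

    On the ordered scale smaller < larger < largest (``none`` ignored), a
    locus is *jumping* if any pair of tissues differs by two steps,
    *neighboring* if any pair differs by one step, else *none*.  Counts
    are reported per tissue pair and overall.
    """
    per_locus: dict[str, dict[str, str]] = {}
    for call in calls:
        if call.tissue in tissues:
            per_locus.setdefault(call.locus_id, {})[call.tissue] = call.category

    per_pair: dict[tuple[str, str], dict[str, int]] = {}
    locus_type: dict[str, str] = {}
    for locus_id, cats in per_locus.items():
        worst = 0
        for i, t1 in enumerate(tissues):
            for t2 in tissues[i + 1 :]:
                c1, c2 = cats.get(t1, "none"), cats.get(t2, "none")
                if c1 == "none" or c2 == "none":
                    continue
                step = abs(CATEGORY_ORDER[c1] - CATEGORY_ORDER[c2])
                if step == 0:
                    continue
                kind = "neighboring" if step == 1 else "jumping"
                bucket = per_pair.setdefault((t1, t2), {"neighboring": 0, "jumping": 0})
                bucket[kind] += 1
                worst = max(worst, step)
        locus_type[locus_id] = {0: "none", 1: "neighboring", 2: "jumping"}[worst]

    overall = {
        "none": sum(1 for v in locus_type.values() if v == "none"),
        "neighboring": sum(1 for v in locus_type.values() if v == "neighboring"),
        "jumping": sum(1 for v in locus_type.values() if v == "jumping"),
    }
    return {
        "per_locus": locus_type,
        "per_tissue_pair": {f"{a}|{b}": v for (a, b), v in sorted(per_pair.items())},
        "overall": overall,
    }


def calls_to_frame(calls: Iterable[BiasCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                locus_id=c.locus_id,
                tissue=c.tissue,
                log2fc=c.log2fc,
                p=c.p,
                p_adj=c.p_adj,
                category=c.category,
            )
            for c in calls
        ]
    )
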