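"""Ks-peak detection and dating, LTR insertion ages, k-mer genome size.

Dating follows the rate-transfer scheme: a synonymous substitution rate r
is calibrated from an ortholog Ks anchor and its known divergence time via
``time = Ks / (2 r)``, and the same r dates paralog (WGD) Ks peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import gaussian_kde

KS_CEILING = 5.0
DEFAULT_MUTATION_RATE = 1.3e-8  # substitutions / site / year


@dataclass
class KsDistribution:
    """Ks values with exclusion flags (values above the ceiling are kept
    but never used for peak fitting)."""

    values: np.ndarray
    source: str = "paralog"
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("Ks values must be >= 0")
        if self.excluded is None:
            self.excluded = self.values > KS_CEILING
        self.excluded = np.asarray(self.excluded, dtype=bool)

    @property
    def usable(self) -> np.ndarray:
        return self.values[~self.excluded]


@dataclass(frozen=True)
class RateCalibration:
    r: float
    ks_anchor: float
    t_anchor: float


@dataclass(frozen=True)
class DatingResult:
    label: str
    ks_peak: float
    age_years: float

    @property
    def age_mya(self) -> float:
        return self.age_years / 1e6


def detect_ks_peaks(
    dist: KsDistribution,
    bandwidth: float | None = None,
    min_density_fraction: float = 0.05,
    grid_points: int = 2048,
) -> list[float]:
    """Local maxima of a Gaussian KDE of the usable Ks values on [0, 5].

    Peaks below ``min_density_fraction`` of the global density maximum are
    discarded; results are sorted ascending.  Bandwidth defaults to
    Silverman's rule.
    """
    values = dist.usable
    if values.size < 50:
        raise ValueError(
            f"need >= 50 usable Ks values for peak detection, got {values.size}"
        )
    if bandwidth is not None:
        kde = gaussian_kde(values, bw_method=bandwidth / values.std(ddof=1))
    else:
        kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(0.0, KS_CEILING, grid_points)
    density = kde(grid)
    idx, _ = signal.find_peaks(density, height=min_density_fraction * density.max())
    return sorted(float(grid[i]) for i in idx)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (as used by the KDE default)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    return values.std(ddof=1) * (4.0 / (3.0 * n)) ** 0.2


def calibrate_rate(ks_anchor: float, t_anchor_years: float) -> RateCalibration:
    """r = Ks_anchor / (2 * t_anchor)."""
    if ks_anchor <= 0 or t_anchor_years <= 0:
        raise ValueError("anchor Ks and time must both be positive")
    return RateCalibration(
        r=ks_anchor / (2.0 * t_anchor_years),
        ks_anchor=ks_anchor,
        t_anchor=t_anchor_years,
    )


def date_event(ks_peak: float, cal: RateCalibration, label: str = "") -> DatingResult:
    """age = Ks_peak / (2 r)."""
    if ks_peak < 0:
        raise ValueError("Ks peak must be >= 0")
    return DatingResult(label=label, ks_peak=ks_peak, age_years=ks_peak / (2.0 * cal.r))


def ltr_insertion_time(divergence: float, mu: float = DEFAULT_MUTATION_RATE) -> float:
    """Insertion age T = d / (2 mu) in years.

    ``divergence`` is the JC69-corrected distance between the 5' and 3'
    LTRs of one element; the two LTRs were identical at insertion and have
    each accumulated mutations at rate mu since.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return divergence / (2.0 * mu)


def ltr_divergence_from_p(p: float) -> float:
    """JC69-corrected LTR-pair distance from the raw mismatch proportion."""
    if p >= 0.75:
        raise ValueError(f"saturated: p = {p:.4f} >= 3/4")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kmer_genome_size(
    histogram: dict[int, float] | list[tuple[int, float]],
    error_tail_max_depth: int = 2,
    min_prominence_fraction: float = 0.05,
) -> tuple[float, int]:
    """Genome size = (total k-mer count) / (homozygous peak depth).

    Depths at or below ``error_tail_max_depth`` are excluded from the
    total (sequencing-error tail).  The homozygous peak is the
    highest-depth maximum among the top-2 most prominent local maxima — a
    diploid histogram shows a heterozygous peak at roughly half the
    homozygous depth.  Returns ``(genome_size, peak_depth)``.
    """
    items = sorted(dict(histogram).items())
    if not items:
        raise ValueError("empty k-mer histogram")
    depths = np.array([d for d, _ in items], dtype=int)
    counts = np.array([c for _, c in items], dtype=float)
    if np.any(depths < 1):
        raise ValueError("k-mer depths must be >= 1")
    keep = depths > error_tail_max_depth
    depths, counts = depths[keep], counts[keep]
    if depths.size == 0:
        raise ValueError("histogram contains only the error tail")
    # pad so a peak at either edge of the depth range is detectable
    padded = np.concatenate([[0.0], counts, [0.0]])
    idx, props = signal.find_peaks(
        padded, prominence=min_prominence_fraction * counts.max()
    )
    if idx.size == 0:
        raise ValueError(
            "no detectable coverage peak; histogram max count "
            f"{counts.max():.0f} at depth {int(depths[np.argmax(counts)])}"
        )
    order = np.argsort(props["prominences"])[::-1]
    top = idx[order[:2]] - 1  # undo padding offset
    peak_depth = int(depths[top].max())
    total = float(np.sum(depths * counts))
    return total / peak_depth, peak_depth
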