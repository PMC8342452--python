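"""Coexpression network modules and allelic eigengene divergence.

Network construction follows the unsigned weighted scheme: Pearson
correlation on log2(TPM+1), adjacency |cor|**beta with beta chosen as the
first power reaching a scale-free fit of 0.9, unsigned topological
overlap, average-linkage clustering with a fixed-height cut scanned to
respect the minimum module size (a simplification of dynamic tree cut),
and merging of modules whose eigengenes are closer than the merge cut
height on the 1 - correlation scale.

Allele pairs in the same module are *coordinated*; pairs in different
modules are *divergent* when their module eigengenes are farther apart
than 50% of the median per-module maximum eigengene distance, otherwise
*similar*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .pairing import AllelePair

SCALE_FREE_TARGET = 0.9
MIN_MODULE_SIZE = 60
MERGE_CUT_HEIGHT = 0.15
DIVERGENCE_FRACTION = 0.5
GREY = 0


@dataclass
class NetworkConfig:
    soft_power: int | None = None  # None => auto
    scale_free_target: float = SCALE_FREE_TARGET
    min_module_size: int = MIN_MODULE_SIZE
    merge_cut_height: float = MERGE_CUT_HEIGHT

    def __post_init__(self) -> None:
        if self.soft_power is not None and not 1 <= self.soft_power <= 30:
            raise ValueError("soft_power must be in [1, 30]")
        for name in ("scale_free_target", "merge_cut_height"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class ModuleAssignment:
    gene_module: dict[str, int]  # module 0 = unassigned/grey
    eigengenes: dict[int, np.ndarray]  # unit-norm sample-space vectors
    soft_power: int = 0

    def module_of(self, gene: str) -> int:
        return self.gene_module.get(gene, GREY)


@dataclass(frozen=True)
class DivergenceCall:
    locus_id: str
    cls: str  # coordinated | similar | divergent
    distance: float
    threshold: float


def _log_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM+1) with constant-expression genes removed (warned)."""
    log = np.log2(tpm.astype(float) + 1.0)
    sd = log.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"removed {int(constant.sum())} constant-expression genes",
            stacklevel=3,
        )
    return log.loc[~constant]


def _adjacency(log_expr: pd.DataFrame, beta: int) -> np.ndarray:
    cor = np.corrcoef(log_expr.to_numpy())
    cor = np.nan_to_num(cor, nan=0.0)
    return np.abs(cor) ** beta


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over connectivity bins, negated when
    the slope is positive; nan if fewer than 3 usable bins."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.unique(k).size < 2:
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return float("nan")
    x, y = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return -r2 if slope > 0 else r2


def pick_soft_power(tpm: pd.DataFrame, config: NetworkConfig | None = None) -> int:
    """First beta in 1..30 whose scale-free fit reaches the target;
    otherwise the argmax fit (with a warning); 6 if no fit is defined."""
    config = config or NetworkConfig()
    if config.soft_power is not None:
        return config.soft_power
    log_expr = _log_expression(tpm)
    if len(log_expr) < 20 or log_expr.shape[1] < 4:
        raise ValueError("need >= 20 genes and >= 4 samples to pick a soft power")
    cor = np.abs(np.nan_to_num(np.corrcoef(log_expr.to_numpy()), nan=0.0))
    np.fill_diagonal(cor, 0.0)
    fits: dict[int, float] = {}
    power = cor.copy()
    for beta in range(1, 31):
        if beta > 1:
            power = power * cor
        fit = scale_free_fit(power.sum(axis=1))
        if not np.isnan(fit):
            fits[beta] = fit
            if fit >= config.scale_free_target:
                return beta
    if not fits:
        warnings.warn("scale-free fit undefined for all powers; using 6", stacklevel=2)
        return 6
    best = max(fits, key=lambda b: (fits[b], -b))
    warnings.warn(
        f"no power reached fit {config.scale_free_target}; "
        f"using argmax beta={best} (fit {fits[best]:.3f})",
        stacklevel=2,
    )
    return best


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij),
    diagonal 1 by convention."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    k_min = np.minimum.outer(k, k)
    tom = (shared + a) / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(log_expr: np.ndarray) -> np.ndarray:
    """First PC over samples of gene-standardized expression, unit norm,
    sign-oriented to correlate positively with the module mean profile."""
    mean = log_expr.mean(axis=1, keepdims=True)
    sd = log_expr.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (log_expr - mean) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    profile = z.mean(axis=0)
    if np.dot(eig, profile) < 0:
        eig = -eig
    norm = np.linalg.norm(eig)
    return eig / norm if norm > 0 else eig


def detect_modules(
    tpm: pd.DataFrame,
    config: NetworkConfig | None = None,
    soft_power: int | None = None,
) -> ModuleAssignment:
    """TOM-based average-linkage module detection with eigengene merging."""
    config = config or NetworkConfig()
    log_expr = _log_expression(tpm)
    genes = list(log_expr.index)
    if len(genes) < config.min_module_size:
        warnings.warn("fewer genes than min module size: all grey", stacklevel=2)
        return ModuleAssignment({g: GREY for g in genes}, {}, soft_power=0)
    beta = soft_power or config.soft_power or pick_soft_power(tpm, config)
    adjacency = _adjacency(log_expr, beta)
    tom = topological_overlap(adjacency)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    linkage = average(squareform(dissim, checks=False))

    # fixed-height cut scanned over candidate heights (dynamic-cut stand-in)
    heights = np.unique(linkage[:, 2])
    best: tuple[int, int, float] | None = None  # (-n_modules, -n_assigned, h)
    for h in heights:
        labels = fcluster(linkage, t=h, criterion="distance")
        sizes = pd.Series(labels).value_counts()
        ok = sizes[sizes >= config.min_module_size]
        if len(ok) == 0:
            continue
        key = (-len(ok), -int(ok.sum()), float(h))
        if best is None or key < best:
            best = key
    if best is None:
        return ModuleAssignment({g: GREY for g in genes}, {}, soft_power=beta)
    labels = fcluster(linkage, t=best[2], criterion="distance")
    sizes = pd.Series(labels).value_counts()
    valid = set(sizes[sizes >= config.min_module_size].index)

    raw_modules: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        if lab in valid:
            raw_modules.setdefault(int(lab), []).append(idx)

    expr = log_expr.to_numpy()
    module_members = [sorted(v) for _, v in sorted(raw_modules.items())]
    module_members = _merge_similar(expr, module_members, config.merge_cut_height)

    gene_module = {g: GREY for g in genes}
    eigengenes: dict[int, np.ndarray] = {}
    for mid, members in enumerate(module_members, start=1):
        for idx in members:
            gene_module[genes[idx]] = mid
        eigengenes[mid] = _eigengene(expr[members])
    return ModuleAssignment(gene_module, eigengenes, soft_power=beta)


def _merge_similar(
    expr: np.ndarray, modules: list[list[int]], merge_cut_height: float
) -> list[list[int]]:
    """Merge modules whose eigengene correlation distance (1 - cor) is
    below the merge cut height, iterating until stable."""
    while len(modules) > 1:
        eigs = np.array([_eigengene(expr[m]) for m in modules])
        cor = np.corrcoef(eigs)
        dist = 1.0 - cor
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= merge_cut_height:
            break
        a, b = sorted((i, j))
        modules[a] = sorted(modules[a] + modules[b])
        del modules[b]
    return sorted(modules, key=lambda m: (-len(m), m[0]))


def eigengene_distance_threshold(assignment: ModuleAssignment) -> float:
    """0.5 x median over modules of the maximum pairwise eigengene
    distance from that module to any other module."""
    modules = sorted(assignment.eigengenes)
    if len(modules) < 2:
        return 0.0
    maxima = []
    for m in modules:
        dists = [
            float(np.linalg.norm(assignment.eigengenes[m] - assignment.eigengenes[o]))
            for o in modules
            if o != m
        ]
        maxima.append(max(dists))
    return DIVERGENCE_FRACTION * float(np.median(maxima))


def classify_allele_divergence(
    pairs: list[AllelePair], assignment: ModuleAssignment
) -> tuple[list[DivergenceCall], int]:
    """Coordinated / similar / divergent calls per pair; pairs with a
    grey (unassigned) allele are withheld and counted."""
    threshold = eigengene_distance_threshold(assignment)
    calls: list[DivergenceCall] = []
    withheld = 0
    for pair in pairs:
        m_a = assignment.module_of(pair.gene_a)
        m_b = assignment.module_of(pair.gene_b)
        if m_a == GREY or m_b == GREY:
            withheld += 1
            continue
        if m_a == m_b:
            calls.append(DivergenceCall(pair.locus_id, "coordinated", 0.0, threshold))
            continue
        distance = float(
            np.linalg.norm(assignment.eigengenes[m_a] - assignment.eigengenes[m_b])
        )
        cls = "divergent" if distance > threshold else "similar"
        calls.append(DivergenceCall(pair.locus_id, cls, distance, threshold))
    return calls, withheld
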