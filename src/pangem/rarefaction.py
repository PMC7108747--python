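"""Rarefaction curves, Heaps'-law fits and IQR areas.

Random genome subsets of increasing size are drawn (30 replicates per
size by default) and, for each, the sizes of the pangenome components
are recorded: the whole pangenome, the partitioned persistent / shell /
cloud, the soft core (families in ≥95% of the sampled genomes), its
complement, and the exact core / accessory.  Each component's growth is
summarized by a Heaps'-law fit F = κ·n^γ — γ near 0 indicates a closed
(stabilized) component, larger γ an open one — and by the IQR area, the
integral over n of the interquartile width, which measures how unstable
the estimate is under resampling.  Small subset sizes (≤15) are too
variable and are excluded from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bmm import run_binem
from .graph import PangenomeGraph
from .matrix import PAMatrix
from .nem import MRFConfig, run_nem
from .partition import CLOUD, PERSISTENT, SHELL, assign_partitions
from .selection import select_K

__all__ = [
    "COMPONENTS",
    "HeapsFit",
    "RarefactionResult",
    "component_counts",
    "rarefaction_curves",
    "fit_heaps",
    "iqr_area",
]

COMPONENTS = (
    "pangenome",
    "persistent",
    "shell",
    "cloud",
    "soft_core",
    "soft_accessory",
    "exact_core",
    "exact_accessory",
)


def soft_core_min_presence(n: int, threshold: float = 0.95) -> int:
    """Minimum presence count for the soft core: ⌈threshold·n⌉.

    Guarded against float round-up (0.95·20 must give 19, not 20).
    """
    return int(np.ceil(threshold * n - 1e-9))


def allowed_absences(n: int, threshold: float = 0.95) -> int:
    """Genomes a soft-core family may be absent from: n − ⌈threshold·n⌉.

    As n grows this increments by one every ⌈1/(1−threshold)⌉ genomes —
    the stair-step a fixed-threshold core imposes on rarefaction curves
    (a step every 20 genomes at the default 95% threshold).
    """
    return n - soft_core_min_presence(n, threshold)


@dataclass
class HeapsFit:
    kappa: float
    gamma: float
    se_kappa: float
    se_gamma: float
    converged: bool = True


@dataclass
class RarefactionResult:
    """Raw replicate counts, per-size quartiles, Heaps fits and IQR areas."""

    samples: pd.DataFrame  # columns: n, rep, component, count
    quartiles: pd.DataFrame  # columns: n, component, q1, median, q3
    heaps: dict[str, HeapsFit]
    iqr_areas: dict[str, float]


def component_counts(
    pa_subset: PAMatrix, partitioning=None, soft_threshold: float = 0.95
) -> dict[str, int]:
    """Family counts of every pangenome component on a genome subset.

    ``pa_subset`` must already be restricted to the subset (families with
    zero presence dropped); ``partitioning`` supplies the persistent /
    shell / cloud labels for those families (None leaves them at 0).
    The soft core holds families present in at least ⌈threshold·n⌉
    genomes, the exact core those present in all n.
    """
    n = pa_subset.n_genomes
    if n < 1:
        raise ValueError("subset must contain at least one genome")
    presence = pa_subset.X.sum(axis=1)
    soft_min = soft_core_min_presence(n, soft_threshold)
    counts = {
        "pangenome": pa_subset.n_families,
        "soft_core": int((presence >= soft_min).sum()),
        "exact_core": int((presence == n).sum()),
        "persistent": 0,
        "shell": 0,
        "cloud": 0,
    }
    counts["soft_accessory"] = counts["pangenome"] - counts["soft_core"]
    counts["exact_accessory"] = counts["pangenome"] - counts["exact_core"]
    if partitioning is not None:
        for lab in partitioning.labels:
            counts[str(lab)] += 1
    return counts


def _partition_subset(sub: PAMatrix, graph, K_full, reselect_K, config, em_steps=10):
    """Partition one genome subset, re-selecting K in [3, K_full] if asked."""
    if sub.n_families < 3:
        return None  # too few families to partition; partition counts stay 0
    K = 3
    if reselect_K and K_full > 3:
        grid = [k for k in range(3, K_full + 1) if k <= sub.n_families]
        K = select_K(sub, grid, em_steps=em_steps).K_hat if grid else 3
    else:
        K = min(max(K_full, 3), sub.n_families)
    if graph is not None:
        _, _, part = run_nem(sub, graph, K, config)
        return part
    _, T, _ = run_binem(sub, K)
    return assign_partitions(T, K, sub.family_ids)


def rarefaction_curves(
    pa: PAMatrix,
    graph: PangenomeGraph | None = None,
    max_n: int = 100,
    reps: int = 30,
    seed: int | None = None,
    K_full: int = 3,
    reselect_K: bool = True,
    config: MRFConfig | None = None,
    soft_threshold: float = 0.95,
    min_n_fit: int = 16,
) -> RarefactionResult:
    """Compute rarefaction curves over subset sizes 1…min(max_n, N).

    Each size is sampled ``reps`` times without replacement; every
    replicate is freshly partitioned (K re-selected between 3 and
    ``K_full`` unless ``reselect_K`` is off) and its component counts
    recorded.  Heaps' law is fitted per component on all replicate
    points with n ≥ ``min_n_fit``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if pa.n_genomes < 2:
        raise ValueError("rarefaction requires at least 2 genomes")
    rng = np.random.default_rng(seed)
    rows = []
    for n in range(1, min(max_n, pa.n_genomes) + 1):
        for rep in range(reps):
            idx = rng.choice(pa.n_genomes, size=n, replace=False)
            subset_ids = [pa.genome_ids[i] for i in idx]
            sub = pa.subset_genomes(subset_ids)
            sub_graph = graph.subset_genomes(subset_ids) if graph is not None else None
            part = _partition_subset(sub, sub_graph, K_full, reselect_K, config)
            counts = component_counts(sub, part, soft_threshold)
            for comp in COMPONENTS:
                rows.append((n, rep, comp, counts[comp]))
    samples = pd.DataFrame(rows, columns=["n", "rep", "component", "count"])

    quart = (
        samples.groupby(["n", "component"])["count"]
        .quantile([0.25, 0.5, 0.75])
        .unstack()
        .reset_index()
    )
    quart.columns = ["n", "component", "q1", "median", "q3"]

    heaps: dict[str, HeapsFit] = {}
    areas: dict[str, float] = {}
    for comp in COMPONENTS:
        pts = samples[samples.component == comp]
        try:
            heaps[comp] = fit_heaps(
                pts[["n", "count"]].to_numpy(dtype=float), min_n_fit=min_n_fit
            )
        except ValueError:
            heaps[comp] = HeapsFit(np.nan, np.nan, np.nan, np.nan, converged=False)
        q = quart[quart.component == comp].sort_values("n")
        areas[comp] = iqr_area(q["n"].to_numpy(), q["q1"].to_numpy(), q["q3"].to_numpy())
    return RarefactionResult(samples, quart, heaps, areas)


def fit_heaps(points: np.ndarray, min_n_fit: int = 16) -> HeapsFit:
    """Nonlinear least-squares Heaps'-law fit F = κ·n^γ.

    ``points`` is an array of (n, count) pairs — all replicate points,
    not medians.  Sizes below ``min_n_fit`` are excluded.  Starting
    values: κ₀ = mean count at the smallest fitted size, γ₀ = 0.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[pts[:, 0] >= min_n_fit]
    if len(np.unique(pts[:, 0])) < 3:
        raise ValueError(f"need >= 3 distinct sizes >= {min_n_fit} for the Heaps fit")
    if not (pts[:, 1] > 0).any():
        raise ValueError("all counts are zero; Heaps' law is undefined")
    n, y = pts[:, 0], pts[:, 1]
    kappa0 = float(y[n == n.min()].mean())

    def heaps(nn, kappa, gamma):
        return kappa * np.power(nn, gamma)

    try:
        popt, pcov = curve_fit(heaps, n, y, p0=(max(kappa0, 1e-9), 0.0), maxfev=10000)
        se = np.sqrt(np.diag(pcov))
        converged = bool(np.isfinite(se).all())
    except RuntimeError:
        warnings.warn("Heaps fit did not converge", RuntimeWarning, stacklevel=2)
        return HeapsFit(np.nan, np.nan, np.nan, np.nan, converged=False)
    return HeapsFit(float(popt[0]), float(popt[1]), float(se[0]), float(se[1]), converged)


def iqr_area(n: np.ndarray, q1: np.ndarray, q3: np.ndarray) -> float:
    """Trapezoidal integral of the interquartile width Q3(n) − Q1(n)."""
    n = np.asarray(n, dtype=float)
    if len(n) < 2:
        raise ValueError("need quartiles at >= 2 sizes")
    return float(np.trapezoid(np.asarray(q3) - np.asarray(q1), n))
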