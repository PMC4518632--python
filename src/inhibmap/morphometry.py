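"""Synapse-target morphometry: junction-area comparisons between target
classes, area-vs-target-size regressions, bouton-target proportions and
Sholl profiles.

Somatic inhibitory junctions are systematically larger than dendritic-shaft
junctions, which are larger than spine junctions; on shafts and spines the
junction area scales linearly with the size of the target structure
(dendritic cross-sectional area, spine-head volume). These procedures
quantify that: non-parametric class comparisons (Mann-Whitney U, exact for
small samples), ordinary least-squares regressions with Pearson r, the
fraction of an interneuron's boutons that are soma-targeting basket
terminals, and axonal Sholl intersection profiles around the target soma.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .morphology import Morphology

__all__ = [
    "SynapseMorphometryRecord",
    "ShollProfile",
    "class_area_comparison",
    "area_target_regression",
    "basket_terminal_proportion",
    "sholl_intersections",
]

_CLASSES = ("soma", "shaft", "spine")


@dataclass
class SynapseMorphometryRecord:
    """One synapse with its target metrics. ``target_size`` is the spine
    head volume (µm³) for spine targets, the dendritic cross-sectional area
    (µm²) for shaft targets, and absent for somatic targets (the soma has no
    size covariate in these analyses)."""

    junction_area: float
    target_class: str
    target_size: float | None = None
    bouton_volume: float | None = None
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.target_class not in _CLASSES:
            raise ValueError(f"unknown target class {self.target_class!r}")
        if not self.junction_area > 0:
            raise ValueError("junction_area must be > 0")
        if self.target_class == "soma":
            if self.target_size is not None:
                raise ValueError("somatic records carry no target size")
        elif self.target_size is None:
            raise ValueError(f"{self.target_class} records need a target size")
        elif not self.target_size > 0:
            raise ValueError("target_size must be > 0")


def class_area_comparison(records: list[SynapseMorphometryRecord]) -> pd.DataFrame:
    """Per-class junction-area summary plus pairwise two-sided Mann-Whitney
    U tests (exact when both groups have n ≤ 8 and no ties, normal
    approximation otherwise, scipy's default switching rule).

    Returns a summary frame (index = class) with mean/sd/n columns and a
    ``pairwise`` attribute mapping (class_a, class_b) → (U, p).
    """
    groups = {
        c: np.array([r.junction_area for r in records if r.target_class == c])
        for c in _CLASSES
    }
    groups = {c: v for c, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("need at least two represented target classes")
    summary = pd.DataFrame(
        {
            "mean_area_um2": {c: float(v.mean()) for c, v in groups.items()},
            "sd_area_um2": {
                c: float(v.std(ddof=1)) if v.size > 1 else 0.0
                for c, v in groups.items()
            },
            "n": {c: int(v.size) for c, v in groups.items()},
        }
    )
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(groups, 2):
        res = sstats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))
    summary.attrs["pairwise"] = pairwise
    return summary


def area_target_regression(
    records: list[SynapseMorphometryRecord],
    target_class: str,
    cell_type: str | None = None,
) -> dict[str, float]:
    """OLS regression of junction area on target size within one class
    (optionally restricted to one cell type): returns slope, intercept,
    Pearson r, p-value and n."""
    if target_class == "soma":
        raise ValueError("somatic synapses have no size covariate")
    sel = [
        r
        for r in records
        if r.target_class == target_class
        and (cell_type is None or r.cell_type == cell_type)
    ]
    if len(sel) < 3:
        raise ValueError(f"need >= 3 {target_class} records, got {len(sel)}")
    x = np.array([r.target_size for r in sel])
    y = np.array([r.junction_area for r in sel])
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no variance in target size")
    res = sstats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "n": len(sel),
    }


def bouton_volume_regression(
    records: list[SynapseMorphometryRecord],
) -> dict[str, float]:
    """OLS regression of junction area on bouton volume across all records
    that carry one."""
    sel = [r for r in records if r.bouton_volume is not None]
    if len(sel) < 3:
        raise ValueError("need >= 3 records with bouton volumes")
    x = np.array([r.bouton_volume for r in sel])
    y = np.array([r.junction_area for r in sel])
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no variance in bouton volume")
    res = sstats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p_value": float(res.pvalue),
        "n": len(sel),
    }


def basket_terminal_proportion(per_pair_counts) -> pd.DataFrame:
    """Per-pair percentage of boutons that are soma-targeting basket
    terminals, plus the unweighted mean ± sd across pairs.

    ``per_pair_counts``: iterable of (basket_terminals, total_boutons) or a
    DataFrame with those columns (and optionally a ``pair`` column). The
    across-pair spread is the population sd (the convention of the summary
    row it reproduces). Returns a frame with a ``percent`` column and mean/
    sd in ``attrs``.
    """
    if isinstance(per_pair_counts, pd.DataFrame):
        df = per_pair_counts.copy()
    else:
        df = pd.DataFrame(
            list(per_pair_counts), columns=["basket_terminals", "total_boutons"]
        )
    if (df["total_boutons"] <= 0).any():
        raise ValueError("total bouton counts must be > 0")
    df["percent"] = 100.0 * df["basket_terminals"] / df["total_boutons"]
    df.attrs["mean_percent"] = float(df["percent"].mean())
    df.attrs["sd_percent"] = (
        float(df["percent"].std(ddof=0)) if len(df) > 1 else 0.0
    )
    return df


@dataclass
class ShollProfile:
    """Intersection counts of a neurite tree with concentric spheres."""

    radii: np.ndarray
    counts: np.ndarray
    center: np.ndarray


def _tree_segments(m: Morphology, kinds: tuple[str, ...]) -> np.ndarray:
    """(n, 2, 3) array of 3D segments from the stored section polylines."""
    segs = []
    for sec in m:
        if sec.kind not in kinds:
            continue
        if sec.points is None or len(sec.points) < 2:
            raise ValueError(
                f"section {sec.id} has no 3D polyline; Sholl analysis needs "
                "coordinates (read the morphology from SWC or generate with "
                "coordinates)"
            )
        pts = sec.points[:, :3]
        segs.append(np.stack([pts[:-1], pts[1:]], axis=1))
    if not segs:
        raise ValueError(f"no sections of kinds {kinds} with coordinates")
    return np.concatenate(segs, axis=0)


def sholl_intersections(
    axon_tree: Morphology,
    center,
    radii,
    kinds: tuple[str, ...] = ("axon",),
) -> ShollProfile:
    """Count neurite crossings of each sphere centred on ``center``.

    Exact per-segment counting: for each straight segment the quadratic
    |p0 + t·(p1−p0) − c|² = r² is solved and roots with t ∈ [0, 1) are
    counted (half-open, so a crossing at a shared vertex counts once).
    """
    radii = np.asarray(list(radii), dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    center = np.asarray(center, dtype=float)
    segs = _tree_segments(axon_tree, kinds)
    a = segs[:, 0, :] - center
    u = segs[:, 1, :] - segs[:, 0, :]
    uu = np.einsum("ij,ij->i", u, u)
    au = np.einsum("ij,ij->i", a, u)
    aa = np.einsum("ij,ij->i", a, a)
    counts = np.zeros(len(radii), dtype=int)
    for k, r in enumerate(radii):
        cc = aa - r * r
        n = 0
        for i in range(len(segs)):
            if uu[i] == 0:
                continue
            disc = au[i] ** 2 - uu[i] * cc[i]
            if disc < 0:
                continue
            sq = np.sqrt(disc)
            for root in ((-au[i] - sq) / uu[i], (-au[i] + sq) / uu[i]):
                if 0.0 <= root < 1.0:
                    n += 1
            if disc == 0:  # tangent point counted once, not twice
                n -= 1 if 0.0 <= -au[i] / uu[i] < 1.0 else 0
        counts[k] = n
    return ShollProfile(radii=radii, counts=counts, center=center)
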