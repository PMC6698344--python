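"""Voxel-wise group-contrast statistical maps with cluster-extent control.

For two diagnostic groups the per-voxel statistic is the two-sample t on
the (age-residualized) annualized change maps, tested one-sided in both
directions: volume decrease (atrophy) and increase (expansion).  Voxels
below an uncorrected p threshold (default 0.005) are grouped into
connected components and components not exceeding the extent threshold k
(default 100 voxels, strict) are discarded — a cheap guard against
scattered false positives in lieu of a family-wise correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .confounds import fit_age_model, residualize
from .morphometry import JacobianMap

__all__ = [
    "ContrastSpec",
    "StatMap",
    "voxelwise_ttest",
    "cluster_threshold",
    "signature_contrasts",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Definition of one two-group contrast and its thresholds."""

    group_a: str
    group_b: str
    p_threshold: float = 0.005
    k_threshold: int = 100          # clusters must be strictly larger than k
    connectivity: int = 18          # 6, 18 or 26 neighbours
    equal_variance: bool = True     # pooled t (Welch when False)

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.k_threshold < 0:
            raise ValueError("k_threshold must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """t/p volumes for one contrast, plus signed cluster-thresholded masks.

    ``p_pos`` is the one-sided p for group_a > group_b at each voxel and
    ``p_neg`` for group_a < group_b.  After clustering, ``sig_mask_pos``
    and ``sig_mask_neg`` mark the surviving voxels per direction and
    ``clusters`` tabulates each surviving component.
    """

    t_values: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    df: float
    spec: ContrastSpec
    degenerate: np.ndarray                      # voxels with zero pooled variance
    sig_mask_pos: Optional[np.ndarray] = None
    sig_mask_neg: Optional[np.ndarray] = None
    clusters: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for p in (self.p_pos, self.p_neg):
            if p.min() < 0 or p.max() > 1:
                raise ValueError("p values out of [0, 1]")
        if self.sig_mask_pos is not None and self.sig_mask_neg is not None:
            if np.any(self.sig_mask_pos & self.sig_mask_neg):
                raise ValueError("positive and negative masks must be disjoint")


def voxelwise_ttest(
    maps_a: Sequence[JacobianMap] | np.ndarray,
    maps_b: Sequence[JacobianMap] | np.ndarray,
    spec: ContrastSpec,
) -> StatMap:
    """Per-voxel two-sample t (group_a minus group_b), one-sided both ways.

    Pooled-variance t by default (Welch with ``equal_variance=False``).
    Voxels where the pooled variance vanishes get t = 0 (p = 0.5) and are
    flagged in ``degenerate``.
    """
    A = _stack(maps_a)
    B = _stack(maps_b)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError(f"grids differ: {A.shape[1:]} vs {B.shape[1:]}")
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 maps per group")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    if spec.equal_variance:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = float(na + nb - 2)
        df_map = df
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df_map = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = float(np.nanmean(df_map))
    degenerate = se2 == 0
    t = np.zeros_like(ma)
    np.divide(ma - mb, np.sqrt(se2), out=t, where=~degenerate)
    p_pos = np.where(degenerate, 0.5, stats.t.sf(t, df_map))
    p_neg = np.where(degenerate, 0.5, stats.t.cdf(t, df_map))
    return StatMap(
        t_values=t, p_pos=p_pos, p_neg=p_neg, df=df, spec=spec, degenerate=degenerate
    )


def _stack(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        arr = np.asarray(maps, dtype=float)
        if arr.ndim != 4:
            raise ValueError("array input must be 4-D (maps, x, y, z)")
        return arr
    return np.stack([m.values for m in maps]).astype(float)


def _label_components(mask: np.ndarray, connectivity: int):
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    return ndimage.label(mask, structure=structure)


def cluster_threshold(stat: StatMap, spec: Optional[ContrastSpec] = None) -> StatMap:
    """Apply p thresholds per direction and remove small clusters.

    Supra-threshold voxels (one-sided p < p_threshold, requiring the t
    sign to match the direction) are grouped into connected components;
    components with size <= k_threshold are discarded ("k > 100" is a
    strict inequality).  The cluster table lists label, direction, size,
    peak |t| and peak voxel, sorted by size descending (ties by peak |t|).
    """
    spec = spec or stat.spec
    rows = []
    masks = {}
    for direction, pvals, sign in (("pos", stat.p_pos, 1), ("neg", stat.p_neg, -1)):
        supra = (pvals < spec.p_threshold) & (np.sign(stat.t_values) == sign)
        labels, n = _label_components(supra, spec.connectivity)
        keep = np.zeros_like(supra)
        for lab in range(1, n + 1):
            comp = labels == lab
            size = int(comp.sum())
            if size <= spec.k_threshold:
                continue
            keep |= comp
            tvals = np.where(comp, stat.t_values, 0.0)
            flat_peak = int(np.argmax(np.abs(tvals)))
            peak_ijk = np.unravel_index(flat_peak, stat.t_values.shape)
            rows.append(
                {
                    "direction": direction,
                    "size": size,
                    "peak_t": float(stat.t_values[peak_ijk]),
                    "peak_i": peak_ijk[0],
                    "peak_j": peak_ijk[1],
                    "peak_k": peak_ijk[2],
                }
            )
        masks[direction] = keep
    table = pd.DataFrame(rows, columns=["direction", "size", "peak_t", "peak_i", "peak_j", "peak_k"])
    if len(table):
        table = table.sort_values(
            by=["size", "peak_t"],
            key=lambda c: c.abs() if c.name == "peak_t" else c,
            ascending=False,
        ).reset_index(drop=True)
    table.insert(0, "label", range(1, len(table) + 1))
    return replace(
        stat, spec=spec, sig_mask_pos=masks["pos"], sig_mask_neg=masks["neg"], clusters=table
    )


def signature_contrasts(
    dataset,
    contrasts: Sequence[tuple[str, str]] = (("PreAD", "Ctrl"), ("MCI_AD", "Ctrl")),
    spec: Optional[ContrastSpec] = None,
    residualize_age: bool = True,
    keep_mean: bool = True,
) -> dict[tuple[str, str], StatMap]:
    """Group-difference signature maps on annualized, age-residualized maps.

    The normal-aging regression is fitted on control maps only, every map
    is residualized with it, and each requested contrast is run with both
    one-sided directions and cluster-extent thresholding.  The returned
    maps are signed: the negative direction of (PreAD, Ctrl) marks faster
    volume loss in PreAD (atrophy), the positive direction expansion.
    """
    from .morphometry import annualize

    annualized = []
    for pair, jmap in zip(dataset.pairs, dataset.maps):
        if jmap.is_annualized:
            annualized.append(jmap)
        else:
            annualized.append(annualize(jmap, pair.dt))

    if residualize_age:
        ctrl_idx = [i for i, g in enumerate(dataset.pair_groups) if g.value == "Ctrl"]
        model = fit_age_model(
            [annualized[i] for i in ctrl_idx],
            [dataset.pairs[i].mean_age for i in ctrl_idx],
        )
        annualized = [
            residualize(m, p.mean_age, model, keep_mean=keep_mean)
            for m, p in zip(annualized, dataset.pairs)
        ]

    by_group: dict[str, list[JacobianMap]] = {}
    for g, m in zip(dataset.pair_groups, annualized):
        by_group.setdefault(g.value, []).append(m)

    out = {}
    for group_a, group_b in contrasts:
        cspec = replace(spec, group_a=group_a, group_b=group_b) if spec else ContrastSpec(group_a, group_b)
        stat = voxelwise_ttest(by_group[group_a], by_group[group_b], cspec)
        out[(group_a, group_b)] = cluster_threshold(stat)
    return out
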