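"""RD probability maps, target areas (TAs) and Dice comparison.

Per-run tip-frequency maps are combined voxelwise and normalized by the
maximum count, giving the relative frequency with which each voxel was
visited by an RD tip.  Runs whose RD anchored to a PV opening are excluded
(those anchors are artefacts of vein clipping).  Voxels above the
normalized-probability cutoff (default 0.2; alternatively mean + 2 SD of
the nonzero values) form the TAs as 26-connected components — the
candidate ablation targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .tissue import LABEL_BORDER_ZONE, LABEL_DENSE, LABEL_HEALTHY, TissueModel
from .tracking import TipFrequencyMap

__all__ = [
    "RDProbabilityMap",
    "TargetAreaSet",
    "TA_THRESHOLD_DEFAULT",
    "combine_maps",
    "extract_tas",
    "dice",
    "ta_stats",
]

#: Default cutoff on the max-normalized tip probability.
TA_THRESHOLD_DEFAULT = 0.2

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RDProbabilityMap:
    values: np.ndarray  # in [0, 1]
    n_runs: int
    dx: float
    normalization: str = "max"  # or "mean_sd"

    def threshold_value(self, threshold: float | str = TA_THRESHOLD_DEFAULT) -> float:
        """Resolve a cutoff: a number, or 'mean_sd' for mean + 2 SD of the
        nonzero normalized probabilities."""
        if isinstance(threshold, str):
            if threshold != "mean_sd":
                raise ValueError(f"unknown threshold mode '{threshold}'")
            nz = self.values[self.values > 0]
            if nz.size == 0:
                return 1.0
            return float(nz.mean() + 2.0 * nz.std())
        return float(threshold)


@dataclass
class TargetAreaSet:
    labels: np.ndarray  # 0 background, 1..n_tas component ids
    n_tas: int
    threshold: float
    dx: float

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def volumes_mm3(self) -> np.ndarray:
        if self.n_tas == 0:
            return np.zeros(0)
        return np.bincount(self.labels.reshape(-1))[1:] * self.dx**3


def combine_maps(
    freq_maps: list[TipFrequencyMap],
    final_regions: list[str] | None = None,
    exclude_pv_runs: bool = True,
    normalization: str = "max",
) -> RDProbabilityMap:
    """Combine per-run tip-frequency maps into one normalized probability map.

    With ``exclude_pv_runs`` (default), any run whose RD stabilized at a PV
    opening is dropped entirely before summation.  Raises when nothing was
    recorded (no RDs to map).
    """
    if not freq_maps:
        raise ValueError("no frequency maps to combine")
    if final_regions is not None and len(final_regions) != len(freq_maps):
        raise ValueError("final_regions must align with freq_maps")
    total = np.zeros_like(freq_maps[0].counts, dtype=np.float64)
    n_used = 0
    for i, fm in enumerate(freq_maps):
        if exclude_pv_runs and final_regions is not None and final_regions[i] == "pv":
            continue
        total += fm.counts
        n_used += 1
    m = total.max()
    if m <= 0:
        raise ValueError("no RDs recorded: combined tip-frequency map is all zero")
    return RDProbabilityMap(
        values=total / m, n_runs=n_used, dx=freq_maps[0].dx, normalization=normalization
    )


def extract_tas(
    pmap: RDProbabilityMap, threshold: float | str = TA_THRESHOLD_DEFAULT
) -> TargetAreaSet:
    """Threshold the probability map and label 26-connected components."""
    thr = pmap.threshold_value(threshold)
    mask = pmap.values > thr
    labels, n = ndimage.label(mask, structure=_CONN26)
    return TargetAreaSet(labels=labels, n_tas=int(n), threshold=thr, dx=pmap.dx)


def dice(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two voxel masks (1.0 if both empty)."""
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def ta_stats(tas: TargetAreaSet, tissue: TissueModel) -> pd.DataFrame:
    """Per-TA volumes (% of wall) and tissue-class breakdown.

    One row per TA plus a 'total' row; columns give volume in mm^3, volume
    as % of the wall, and the % of TA voxels on dense / border-zone /
    healthy tissue — the basis of the burden-vs-target-size comparison.
    """
    wall_vol = tissue.wall_volume_mm3()
    rows = []
    for ta_id in range(1, tas.n_tas + 1):
        m = tas.labels == ta_id
        n = int(m.sum())
        rows.append(
            {
                "ta_id": ta_id,
                "volume_mm3": n * tas.dx**3,
                "volume_percent_wall": 100.0 * n * tas.dx**3 / wall_vol if wall_vol else 0.0,
                "dense_percent": 100.0 * int((m & (tissue.labels == LABEL_DENSE)).sum()) / n,
                "bz_percent": 100.0 * int((m & (tissue.labels == LABEL_BORDER_ZONE)).sum()) / n,
                "healthy_percent": 100.0 * int((m & (tissue.labels == LABEL_HEALTHY)).sum()) / n,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "ta_id", "volume_mm3", "volume_percent_wall",
            "dense_percent", "bz_percent", "healthy_percent",
        ],
    )
    total_mask = tas.mask
    n_tot = int(total_mask.sum())
    total = {
        "ta_id": "total",
        "volume_mm3": n_tot * tas.dx**3,
        "volume_percent_wall": 100.0 * n_tot * tas.dx**3 / wall_vol if wall_vol else 0.0,
        "dense_percent": (
            100.0 * int((total_mask & (tissue.labels == LABEL_DENSE)).sum()) / n_tot if n_tot else 0.0
        ),
        "bz_percent": (
            100.0 * int((total_mask & (tissue.labels == LABEL_BORDER_ZONE)).sum()) / n_tot
            if n_tot
            else 0.0
        ),
        "healthy_percent": (
            100.0 * int((total_mask & (tissue.labels == LABEL_HEALTHY)).sum()) / n_tot
            if n_tot
            else 0.0
        ),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
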