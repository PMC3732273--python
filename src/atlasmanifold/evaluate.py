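"""Segmentation and volumetry statistics.

Dice's similarity index, foreground volumes, paired manual-vs-automated
differences, group effect sizes and Bland-Altman agreement quantities.
Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .volume_io import LabelMap

__all__ = [
    "dice",
    "volume_mm3",
    "mean_difference",
    "GroupVolumeStats",
    "effect_sizes",
    "BlandAltman",
    "bland_altman",
    "paired_t",
]


def dice(a: LabelMap, b: LabelMap) -> float:
    """Dice's similarity index 2|A∩B| / (|A| + |B|) between two label maps."""
    a.grid.require_match(b.grid)
    na, nb = a.foreground_count, b.foreground_count
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (na + nb)


def volume_mm3(a: LabelMap) -> float:
    """Foreground volume in cubic millimetres."""
    return a.foreground_count * a.grid.voxel_volume_mm3


def _paired(manual: Sequence[float], automated: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    m = np.asarray(manual, dtype=np.float64)
    a = np.asarray(automated, dtype=np.float64)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError(f"paired vectors must share one length, got {m.shape} and {a.shape}")
    return m, a


def mean_difference(manual: Sequence[float], automated: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample SD of the paired differences manual_i - automated_i."""
    m, a = _paired(manual, automated)
    diffs = m - a
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return float(diffs.mean()), sd


@dataclass(frozen=True)
class GroupVolumeStats:
    """Summary volume statistics for one diagnostic group."""

    label: str
    n: int
    mean_mm3: float
    sd_mm3: float

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("group must have n >= 1")
        if self.sd_mm3 < 0:
            raise ValueError("SD must be >= 0")

    @classmethod
    def from_volumes(cls, label: str, volumes: Sequence[float]) -> "GroupVolumeStats":
        v = np.asarray(volumes, dtype=np.float64)
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(label=label, n=v.size, mean_mm3=float(v.mean()), sd_mm3=sd)


def effect_sizes(
    cn: GroupVolumeStats, mci: GroupVolumeStats, ad: GroupVolumeStats
) -> Tuple[float, float]:
    """Effect sizes of MCI and AD volume loss relative to controls.

    es_mci = (mu_MCI - mu_CN) / sigma_MCI and es_ad = (mu_AD - mu_CN) /
    sigma_AD: the group-mean shift from controls in units of the affected
    group's SD.  Negative values indicate atrophy relative to controls.
    """
    if mci.sd_mm3 <= 0 or ad.sd_mm3 <= 0:
        raise ValueError("effect sizes require positive group SDs")
    es_mci = (mci.mean_mm3 - cn.mean_mm3) / mci.sd_mm3
    es_ad = (ad.mean_mm3 - cn.mean_mm3) / ad.sd_mm3
    return float(es_mci), float(es_ad)


@dataclass(frozen=True)
class BlandAltman:
    """Paired-agreement summary: per-pair means/differences and 1.96-SD limits."""

    means: np.ndarray
    diffs: np.ndarray
    mean_diff: float
    lower_limit: float
    upper_limit: float


def bland_altman(manual: Sequence[float], automated: Sequence[float]) -> BlandAltman:
    """Bland-Altman quantities for automated-vs-manual agreement.

    Differences are automated - manual (plotted against the pair average);
    limits of agreement are mean difference +/- 1.96 * SD of differences.
    """
    m, a = _paired(manual, automated)
    diffs = a - m
    means = 0.5 * (a + m)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    return BlandAltman(
        means=means,
        diffs=diffs,
        mean_diff=mean_diff,
        lower_limit=mean_diff - 1.96 * sd,
        upper_limit=mean_diff + 1.96 * sd,
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-tailed paired t-test: statistic and p-value.

    t = mean(a - b) / (SD(a - b) / sqrt(n)) with n - 1 degrees of freedom.
    """
    x, y = _paired(a, b)
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    diffs = x - y
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined: zero variance of differences")
    t = float(diffs.mean() / (sd / np.sqrt(n)))
    pval = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, pval
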