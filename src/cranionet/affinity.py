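"""Standardization and Q-mode correlation distances between samples.

Biodistance analysis of summary craniometric data proceeds in two
steps.  Each sample's mean measurement vector is first z-scored
measurement-by-measurement:

    z_c = (mean_c - grand_mean_c) / ref_sd_c

where the grand mean is the unweighted mean over the *comparative*
(modern) population samples' means and the reference SD comes from a
single designated reference sample (the Jomon sample plays this role in
the motivating analysis — a hunter-gatherer series large enough to
estimate dispersion reliably).  Focal ancient samples are standardized
against this reference but excluded from the grand mean.

Similarity between two samples is then the *Q-mode correlation*: the
Pearson product-moment correlation computed across the 13 standardized
measurements of the pair.  The dissimilarity ``1 - r`` lies in [0, 2]
and feeds the split-network construction.  No pairwise deletion is
performed: every sample must carry the complete battery (the sanctioned
fill-in path for a missing basion-bregma height is
:func:`~cranionet.measurements.impute_m17`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .measurements import BATTERY_13, PopulationSample

__all__ = [
    "StandardizationReference",
    "build_reference",
    "standardize",
    "standardize_all",
    "qmode_correlation",
    "distance_matrix",
    "CompletenessError",
    "DegenerateProfileError",
]


class CompletenessError(ValueError):
    """A sample lacks a battery measurement required for analysis."""


class DegenerateProfileError(ValueError):
    """A profile has zero variance across the battery; r is undefined."""


@dataclass(frozen=True)
class StandardizationReference:
    """Grand means and reference SDs for a measurement battery."""

    battery: tuple[str, ...]
    grand_mean: Mapping[str, float]
    ref_sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for code in self.battery:
            if code not in self.grand_mean:
                raise CompletenessError(f"no grand mean for {code}")
            if code not in self.ref_sd:
                raise CompletenessError(f"no reference SD for {code}")
            if not self.ref_sd[code] > 0:
                raise ValueError(f"reference SD for {code} must be > 0")


def build_reference(
    comparative: Sequence[PopulationSample],
    ref_sample: PopulationSample,
    battery: Sequence[str] = BATTERY_13,
) -> StandardizationReference:
    """Build the standardization reference from a comparative panel.

    ``grand_mean[c]`` is the unweighted mean of the comparative samples'
    means for measurement ``c`` (each sample counts once, regardless of
    its n); ``ref_sd[c]`` is ``ref_sample``'s SD.
    """
    if not comparative:
        raise ValueError("need at least one comparative sample")
    battery = tuple(battery)
    for s in comparative:
        for code in battery:
            if code not in s.stats:
                raise CompletenessError(
                    f"comparative sample {s.sample_id!r} lacks {code}"
                )
    grand_mean = {
        code: float(np.mean([s.mean(code) for s in comparative])) for code in battery
    }
    ref_sd: dict[str, float] = {}
    for code in battery:
        if code not in ref_sample.stats:
            raise CompletenessError(
                f"reference sample {ref_sample.sample_id!r} lacks {code}"
            )
        sd = ref_sample.sd(code)
        if sd is None or not sd > 0:
            raise ValueError(
                f"reference sample {ref_sample.sample_id!r} has no positive SD for {code}"
            )
        ref_sd[code] = float(sd)
    return StandardizationReference(battery=battery, grand_mean=grand_mean, ref_sd=ref_sd)


def standardize(
    sample: PopulationSample, ref: StandardizationReference
) -> pd.Series:
    """Z-score one sample's mean profile against the reference.

    Returns a Series named after the sample, indexed by battery code.
    """
    values = []
    for code in ref.battery:
        if code not in sample.stats:
            raise CompletenessError(f"sample {sample.sample_id!r} lacks {code}")
        values.append(
            (sample.mean(code) - ref.grand_mean[code]) / ref.ref_sd[code]
        )
    z = pd.Series(values, index=list(ref.battery), name=sample.sample_id, dtype=float)
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError(f"non-finite standardized value for {sample.sample_id!r}")
    return z


def standardize_all(
    samples: Iterable[PopulationSample], ref: StandardizationReference
) -> pd.DataFrame:
    """Standardize many samples; rows are samples, columns the battery."""
    rows = [standardize(s, ref) for s in samples]
    if not rows:
        raise ValueError("no samples to standardize")
    return pd.DataFrame(rows)


def qmode_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation across the battery values of two profiles."""
    if list(a.index) != list(b.index):
        raise ValueError("profiles are on different batteries")
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    for name, v in ((a.name, x), (b.name, y)):
        if np.ptp(v) == 0:
            raise DegenerateProfileError(
                f"profile {name!r} has zero variance across the battery"
            )
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def distance_matrix(profiles: pd.DataFrame) -> DistanceMatrix:
    """Build the ``1 - r`` distance matrix over standardized profiles.

    Rows of ``profiles`` are samples; the Pearson correlation is taken
    across battery values for every pair.  Entries lie in [0, 2]; values
    above 1 (negative correlations) are kept as-is, since the network
    construction downstream tolerates them.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 profiles for a useful distance matrix")
    if profiles.index.has_duplicates:
        raise ValueError("duplicate sample ids in profile table")
    X = profiles.to_numpy(dtype=float)
    spans = np.ptp(X, axis=1)
    for sid, span in zip(profiles.index, spans):
        if span == 0:
            raise DegenerateProfileError(
                f"profile {sid!r} has zero variance across the battery"
            )
    r = np.corrcoef(X)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    # correlation rounding can leave tiny negatives on duplicate profiles
    d[(d < 0) & (d > -1e-12)] = 0.0
    return DistanceMatrix(d, [str(i) for i in profiles.index])
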