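"""Synthetic craniometric populations with known two-cluster structure.

The generator emulates the statistical shape of a worldwide database of
female population means: two "layers" (mega-clusters) of populations
whose mean profiles differ along a fixed contrast — layer 1 with a
broader face and longer vault (positive on bizygomatic/bimaxillary
breadth and cranial length, negative on facial and nasal height) — plus
a per-population multiplicative *size factor* that mimics overall
cranial-size variation between small- and large-bodied populations.

Population ``p`` of cluster ``c`` has true mean vector

    mu_p = s_p * (base_mean + sign_c * contrast_scale * within_sd (*) contrast)

with ``s_p`` the size factor, ``sign_c`` +1 for layer 1 and -1 for
layer 2, and ``(*)`` elementwise multiplication.  Individuals are drawn
independently per measurement from Normal(mu_p, within_sd); there is no
cross-measurement covariance beyond the shared size factor.  A
reference population (the Jomon role: SD donor for standardization) is
drawn from the uncontrasted base mean at size factor 1.

Defaults put base means and within-population SDs at the magnitudes of
real female cranial tables (e.g. M1 about 180 +/- 6 mm, M54 about
26 +/- 1.5 mm), use a 32-population comparative panel (16 per layer),
and separate the layers by one within-population SD on the contrast
measurements — the textbook magnitude of regional craniometric
differences, large enough to be recoverable yet small enough that
overall cranial size remains the dominant axis of variation (as it is
in real worldwide panels, where PC1 is the size axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .measurements import (
    CranialSpecimen,
    Flag,
    PopulationSample,
    aggregate_specimens,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PopulationTruth",
    "generate",
    "generate_ancient_singletons",
    "DEFAULT_BASE_MEAN",
    "DEFAULT_WITHIN_SD",
    "DEFAULT_CONTRAST",
]

#: Baseline female mean profile (mm), Table-2-like magnitudes.
DEFAULT_BASE_MEAN: dict[str, float] = {
    "M1": 180.0, "M8": 135.0, "M9": 95.0, "M10": 112.0, "M17": 135.0,
    "M43": 110.0, "M45": 135.0, "M46": 100.0, "M48": 62.0, "M51": 41.0,
    "M52": 33.0, "M54": 26.0, "M55": 46.0,
}

#: Within-population SDs (mm), matching observed SD magnitudes.
DEFAULT_WITHIN_SD: dict[str, float] = {
    "M1": 6.0, "M8": 5.0, "M9": 4.0, "M10": 4.5, "M17": 5.5,
    "M43": 4.0, "M45": 5.0, "M46": 4.5, "M48": 3.5, "M51": 1.8,
    "M52": 1.5, "M54": 1.5, "M55": 2.5,
}

#: Layer-1 contrast direction: broader face and longer vault, lower
#: facial/nasal heights.  Zero on measurements that do not discriminate.
DEFAULT_CONTRAST: dict[str, float] = {
    "M1": 1.0, "M45": 1.0, "M46": 1.0, "M48": -1.0, "M55": -1.0,
}

CLUSTER_SIGN = {"layer1": 1.0, "layer2": -1.0}


class ConfigError(ValueError):
    """An impossible generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic two-layer world."""

    seed: int = 0
    n_populations_per_cluster: int = 16
    individuals_per_population: int = 30
    base_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MEAN))
    within_pop_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WITHIN_SD))
    cluster_contrast: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    contrast_scale: float = 1.0
    size_factor_range: tuple[float, float] = (0.88, 1.05)
    missing_rate: float = 0.0
    reference_population_size: int = 30

    def __post_init__(self) -> None:
        battery = tuple(self.base_mean)
        for code in battery:
            if code not in self.within_pop_sd:
                raise ConfigError(f"within_pop_sd missing {code}")
            if not self.within_pop_sd[code] > 0:
                raise ConfigError(f"within_pop_sd[{code}] must be > 0")
        if self.contrast_scale < 0:
            raise ConfigError("contrast_scale must be >= 0")
        lo, hi = self.size_factor_range
        if not (0.5 < lo <= hi < 1.5):
            raise ConfigError("size_factor_range must lie within (0.5, 1.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_populations_per_cluster < 1:
            raise ConfigError("need at least one population per cluster")
        if self.individuals_per_population < 2:
            raise ConfigError(
                "individuals_per_population must be >= 2 (sample SDs are needed)"
            )
        if self.reference_population_size < 2:
            raise ConfigError("reference_population_size must be >= 2")

    @property
    def battery(self) -> tuple[str, ...]:
        return tuple(self.base_mean)


@dataclass(frozen=True)
class PopulationTruth:
    sample_id: str
    cluster: str
    size_factor: float
    true_mean: dict[str, float]


@dataclass(frozen=True)
class GroundTruth:
    populations: tuple[PopulationTruth, ...]

    def cluster_of(self, sample_id: str) -> str:
        for p in self.populations:
            if p.sample_id == sample_id:
                return p.cluster
        raise KeyError(sample_id)

    def size_factor_of(self, sample_id: str) -> float:
        for p in self.populations:
            if p.sample_id == sample_id:
                return p.size_factor
        raise KeyError(sample_id)


def _true_mean(config: GeneratorConfig, cluster: str, size_factor: float) -> dict[str, float]:
    sign = CLUSTER_SIGN[cluster]
    return {
        c: size_factor
        * (
            config.base_mean[c]
            + sign
            * config.contrast_scale
            * config.within_pop_sd[c]
            * config.cluster_contrast.get(c, 0.0)
        )
        for c in config.battery
    }


def _draw_specimens(
    rng: np.random.Generator,
    config: GeneratorConfig,
    mean: Mapping[str, float],
    n: int,
    id_prefix: str,
    site: str,
    missing_rate: float,
) -> list[CranialSpecimen]:
    battery = config.battery
    specimens = []
    for i in range(n):
        values: dict[str, float] = {}
        for code in battery:
            v = rng.normal(mean[code], config.within_pop_sd[code])
            if missing_rate > 0 and rng.random() < missing_rate:
                continue
            values[code] = float(v)
        specimens.append(
            CranialSpecimen(
                specimen_id=f"{id_prefix}-{i + 1:03d}",
                site=site,
                sex_label="F",
                values=values,
            )
        )
    return specimens


def generate(
    config: GeneratorConfig,
) -> tuple[list[CranialSpecimen], list[PopulationSample], PopulationSample, GroundTruth]:
    """Generate the synthetic comparative world.

    Returns individual specimens, the aggregated population samples,
    the reference (SD-donor) sample, and the ground truth.  Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    specimens: list[CranialSpecimen] = []
    samples: list[PopulationSample] = []
    truths: list[PopulationTruth] = []
    lo, hi = config.size_factor_range
    for cluster in ("layer1", "layer2"):
        for k in range(config.n_populations_per_cluster):
            sid = f"{cluster}_pop{k + 1:02d}"
            s = float(rng.uniform(lo, hi)) if hi > lo else lo
            mean = _true_mean(config, cluster, s)
            sp = _draw_specimens(
                rng, config, mean, config.individuals_per_population,
                id_prefix=sid, site=sid, missing_rate=config.missing_rate,
            )
            specimens.extend(sp)
            samples.append(
                aggregate_specimens(sp, sample_id=sid, group_tag=cluster)
            )
            truths.append(
                PopulationTruth(sample_id=sid, cluster=cluster, size_factor=s, true_mean=mean)
            )
    # reference sample: uncontrasted base mean, size factor 1, no missingness
    ref_mean = {c: config.base_mean[c] for c in config.battery}
    ref_specimens = _draw_specimens(
        rng, config, ref_mean, config.reference_population_size,
        id_prefix="reference", site="reference", missing_rate=0.0,
    )
    reference = aggregate_specimens(ref_specimens, sample_id="reference", group_tag="reference")
    specimens.extend(ref_specimens)
    return specimens, samples, reference, GroundTruth(tuple(truths))


def generate_ancient_singletons(
    config: GeneratorConfig,
    cluster_label: str,
    k: int,
    missing_m17: bool = False,
) -> list[CranialSpecimen]:
    """Draw ``k`` single ancient crania from one cluster's distribution.

    Each is emitted as an individual specimen (an n = 1 sample carries
    no SD).  With ``missing_m17`` the basion-bregma height is withheld
    and an auricular-basion height (ABH) consistent with it is provided
    instead, so the regression-imputation path can be exercised.
    """
    if cluster_label not in CLUSTER_SIGN:
        raise ConfigError(f"unknown cluster label {cluster_label!r}")
    if k < 0:
        raise ConfigError("k must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    lo, hi = config.size_factor_range
    out: list[CranialSpecimen] = []
    for i in range(k):
        s = float(rng.uniform(lo, hi)) if hi > lo else lo
        mean = _true_mean(config, cluster_label, s)
        sp = _draw_specimens(
            rng, config, mean, 1,
            id_prefix=f"ancient_{cluster_label}_{i + 1}",
            site=f"ancient_{cluster_label}",
            missing_rate=0.0,
        )[0]
        if missing_m17 and "M17" in sp.values:
            # back out the ABH that the packaged regression would need
            m17 = sp.values.pop("M17")
            sp.flags.pop("M17")
            sp.values["ABH"] = (m17 - 14.26) / 1.05
            sp.flags["ABH"] = Flag.OBSERVED
        out.append(sp)
    return out
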