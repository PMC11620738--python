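"""Seeded generators for measurement tables and phenotype count tables.

Controls are drawn around the depth-attenuation line with Gaussian residuals
on the log-ratio scale; polarity reporters add a latent three-state mixture
(normal / reversed / symmetric) whose polarized states shift the true log
ratio by ``+/- effect_size``.  Phenotype tables are multinomial draws over
distal-tip-cell outcome categories, with the double-posterior ("dpd") outcome
counted as both structures present.

Only intensity *ratios* matter downstream; absolute intensities are drawn
log-normal around 100 arbitrary units purely so that tables look realistic.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .measurements_io import (
    LOG_BASE,
    Cell,
    CellPairMeasurement,
    PhenotypeRecord,
    Region,
    Reporter,
)

__all__ = [
    "ZDistribution",
    "GenotypeProfile",
    "DTC_OUTCOMES",
    "simulate_control",
    "simulate_reporter",
    "simulate_phenotype_table",
]

#: Outcome categories for a phenotype table draw.
DTC_OUTCOMES = (
    "both_present",
    "anterior_missing",
    "posterior_missing",
    "both_missing",
    "dpd",
)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class ZDistribution:
    """Distribution of the signed focal-plane distance.

    ``kind`` is ``"uniform"`` (params: low, high) or ``"normal"``
    (params: mean, sd).  Default spans the regression's working range.
    """

    kind: str = "uniform"
    a: float = -3.0
    b: float = 3.0

    def __post_init__(self):
        if self.kind not in ("uniform", "normal"):
            raise ConfigError(f"unknown z distribution kind {self.kind!r}")
        if self.kind == "uniform" and not self.a < self.b:
            raise ConfigError("uniform z distribution needs a < b")
        if self.kind == "normal" and self.b <= 0:
            raise ConfigError("normal z distribution needs sd > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=n)
        return rng.normal(self.a, self.b, size=n)


@dataclass(frozen=True)
class GenotypeProfile:
    """Generative parameters for one genotype/cell/temperature condition."""

    genotype: str = "wild_type"
    cell: Cell = Cell.Z1
    temperature_c: float = 22.5
    p_normal: float = 0.0
    p_reversed: float = 0.0
    p_symmetric: float = 1.0
    effect_size: float = 0.0
    noise_sd: float = 0.0613
    attenuation_slope: float = -0.034
    attenuation_intercept: float = 0.0148
    z_distribution: ZDistribution = field(default_factory=ZDistribution)
    dtc_outcome_probs: dict | None = None
    log_base: float = LOG_BASE
    #: distal intensity ~ lognormal: base ** Normal(intensity_log_mean, intensity_log_sd)
    intensity_log_mean: float = 2.0
    intensity_log_sd: float = 0.2

    def __post_init__(self):
        object.__setattr__(self, "cell", Cell(self.cell))
        probs = (self.p_normal, self.p_reversed, self.p_symmetric)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ConfigError(f"class mixture must sum to 1, got {probs}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if self.dtc_outcome_probs is not None:
            extra = set(self.dtc_outcome_probs) - set(DTC_OUTCOMES)
            if extra:
                raise ConfigError(f"unknown outcome categories: {sorted(extra)}")
            vals = [self.dtc_outcome_probs.get(k, 0.0) for k in DTC_OUTCOMES]
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > _PROB_TOL:
                raise ConfigError("dtc_outcome_probs must sum to 1")

    def with_mixture(
        self, p_normal: float, p_reversed: float, p_symmetric: float
    ) -> "GenotypeProfile":
        return replace(
            self, p_normal=p_normal, p_reversed=p_reversed, p_symmetric=p_symmetric
        )


def _emit_measurements(
    profile: GenotypeProfile,
    reporter: Reporter,
    z: np.ndarray,
    true_log_ratio: np.ndarray,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[CellPairMeasurement]:
    n = len(z)
    distal = profile.log_base ** rng.normal(
        profile.intensity_log_mean, profile.intensity_log_sd, size=n
    )
    proximal = distal * profile.log_base**true_log_ratio
    return [
        CellPairMeasurement(
            animal_id=f"{id_prefix}{i:05d}",
            genotype=profile.genotype,
            temperature_c=profile.temperature_c,
            cell=profile.cell,
            reporter=reporter,
            intensity_proximal=float(proximal[i]),
            intensity_distal=float(distal[i]),
            z_distance_um=float(z[i]),
        )
        for i in range(n)
    ]


def simulate_control(
    n: int, profile: GenotypeProfile, seed: int
) -> list[CellPairMeasurement]:
    """Symmetric-control pairs: true log ratio is the attenuation line plus noise."""
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    z = profile.z_distribution.draw(rng, n)
    y = (
        profile.attenuation_intercept
        + profile.attenuation_slope * z
        + rng.normal(0.0, profile.noise_sd, size=n)
    )
    return _emit_measurements(profile, Reporter.control_nls, z, y, rng, "ctrl")


def simulate_reporter(
    n: int, profile: GenotypeProfile, seed: int
) -> tuple[list[CellPairMeasurement], list[str]]:
    """Polarity-reporter pairs plus the latent truth labels.

    Each pair draws a latent class from ``(p_normal, p_reversed, p_symmetric)``
    contributing ``+effect_size``, ``-effect_size`` or 0 to the true log ratio
    on top of the same attenuation trend and noise as controls.  The truth
    labels are returned separately so a pipeline under test cannot read them
    from the measurement table.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    z = profile.z_distribution.draw(rng, n)
    classes = rng.choice(
        ["normal", "reversed", "symmetric"],
        size=n,
        p=[profile.p_normal, profile.p_reversed, profile.p_symmetric],
    )
    offset = np.where(
        classes == "normal",
        profile.effect_size,
        np.where(classes == "reversed", -profile.effect_size, 0.0),
    )
    y = (
        profile.attenuation_intercept
        + profile.attenuation_slope * z
        + offset
        + rng.normal(0.0, profile.noise_sd, size=n)
    )
    measurements = _emit_measurements(profile, Reporter.pop1, z, y, rng, "rep")
    return measurements, [str(c) for c in classes]


def simulate_phenotype_table(
    profiles: Sequence[GenotypeProfile], n_per_genotype: int, seed: int
) -> tuple[list[PhenotypeRecord], dict[str, dict[str, int]]]:
    """Multinomial phenotype draws per genotype, tallied into penetrance records.

    The anterior-missing count is ``anterior_missing + both_missing`` (same
    logic for posterior); ``dpd`` animals count as having both structures
    present.  Returns the records (percent rounded to one decimal, with the
    true ``count_missing`` attached) and the raw outcome tallies per genotype.
    """
    if n_per_genotype < 1:
        raise ConfigError("n_per_genotype must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PhenotypeRecord] = []
    truth: dict[str, dict[str, int]] = {}
    for profile in profiles:
        if profile.dtc_outcome_probs is None:
            raise ConfigError(
                f"profile {profile.genotype!r} lacks dtc_outcome_probs"
            )
        probs = [profile.dtc_outcome_probs.get(k, 0.0) for k in DTC_OUTCOMES]
        counts = rng.multinomial(n_per_genotype, probs)
        tally = dict(zip(DTC_OUTCOMES, (int(c) for c in counts)))
        truth[profile.genotype] = tally
        missing = {
            Region.anterior: tally["anterior_missing"] + tally["both_missing"],
            Region.posterior: tally["posterior_missing"] + tally["both_missing"],
        }
        for region, count in missing.items():
            records.append(
                PhenotypeRecord(
                    genotype=profile.genotype,
                    region=region,
                    pct_missing=round(100.0 * count / n_per_genotype, 1),
                    n=n_per_genotype,
                    count_missing=count,
                )
            )
    return records, truth
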