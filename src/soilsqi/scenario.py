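"""Scenario specification for the synthetic saline–alkaline field trial.

The default scenario emulates a four-treatment revegetation experiment on
severely saline–alkaline soil: an unplanted control (CK) and plots planted
with tall wheatgrass (GF), chicory (JA) and alfalfa (CP), three replicate
plots each.  Soil chemistry defaults are the published treatment means and
standard deviations for the six indicators (SOM, AN, AP, AK, pH, EC);
community defaults encode the reported richness fold-changes vs the control
and dominant-phylum proportions for bacteria and fungi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

INDICATORS = ["SOM", "AN", "AP", "AK", "pH", "EC"]
TREATMENTS = ["CK", "GF", "JA", "CP"]
DOMAINS = ["bacteria", "fungi"]

#: Treatment-mean soil chemistry (SOM g/kg, AN mg/kg, AP mg/kg, AK mg/kg,
#: pH unitless, EC mS/m) for the default scenario.
CHEMISTRY_MEANS = pd.DataFrame(
    [
        [25.76, 50.09, 1.52, 172.67, 8.37, 6.70],
        [24.69, 44.04, 15.95, 197.33, 8.41, 1.92],
        [35.14, 77.19, 15.64, 265.00, 8.27, 1.95],
        [29.60, 65.71, 11.87, 117.33, 8.51, 1.81],
    ],
    index=TREATMENTS,
    columns=INDICATORS,
)

#: Replicate-level standard deviations matching CHEMISTRY_MEANS.
CHEMISTRY_SDS = pd.DataFrame(
    [
        [2.27, 5.32, 0.56, 25.03, 0.38, 1.94],
        [1.80, 0.75, 0.03, 6.66, 0.04, 0.05],
        [3.63, 4.53, 0.97, 6.35, 0.15, 0.18],
        [3.56, 2.20, 0.25, 3.79, 0.02, 0.018],
    ],
    index=TREATMENTS,
    columns=INDICATORS,
)

#: Chao1-richness fold-change targets vs the control: bacterial richness
#: +50.43/55.09/45.24 % and fungal richness +118.07/138.91/136.95 % in
#: GF/JA/CP respectively.
RICHNESS_MULTIPLIER = pd.DataFrame(
    {
        "bacteria": [1.0, 1.5043, 1.5509, 1.4524],
        "fungi": [1.0, 2.1807, 2.3891, 2.3695],
    },
    index=TREATMENTS,
)

# Dominant-phylum percentages per treatment.  The printed bacterial
# percentages exceed 100 for the planted treatments, so profiles are stored
# renormalized with an "Other" bucket absorbing any remainder (CK sums to
# exactly 100, leaving control Pseudomonadota at its printed 20 %).
_BACTERIAL_RAW = pd.DataFrame(
    {
        "Pseudomonadota": [20.0, 22.0, 28.0, 30.0],
        "Actinomycetota": [19.0, 28.0, 29.0, 24.0],
        "Acidobacteriota": [4.0, 39.0, 28.0, 30.0],
        "Chloroflexi": [24.0, 29.0, 24.0, 24.0],
    },
    index=TREATMENTS,
)
_FUNGAL_RAW = pd.DataFrame(
    {
        "Ascomycota": [85.0, 76.0, 73.0, 78.0],
        "Mortierellomycota": [11.0, 12.0, 20.0, 13.0],
        "Basidiomycota": [3.0, 10.0, 5.0, 6.0],
    },
    index=TREATMENTS,
)


def _normalize_profile(raw: pd.DataFrame) -> pd.DataFrame:
    prof = raw.copy()
    prof["Other"] = (100.0 - prof.sum(axis=1)).clip(lower=0.0)
    return prof.div(prof.sum(axis=1), axis=0)


PHYLUM_PROFILES = {
    "bacteria": _normalize_profile(_BACTERIAL_RAW),
    "fungi": _normalize_profile(_FUNGAL_RAW),
}


@dataclass(frozen=True)
class CorrelatedBlock:
    """A planted block of OTUs sharing one latent Gaussian factor.

    ``sign`` +1 plants an all-positive block; -1 alternates member loadings
    so that adjacent members correlate negatively.  ``rho`` is the latent
    within-block correlation and ``sigma`` the relative amplitude of the
    factor on the abundance scale.
    """

    size: int
    sign: int = 1
    rho: float = 0.995
    sigma: float = 0.45

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("correlated block needs size >= 2")
        if self.sign not in (-1, 1):
            raise ValueError("block sign must be +1 or -1")
        if not 0.0 < self.rho <= 1.0:
            raise ValueError("block rho must lie in (0, 1]")

    def member_signs(self) -> list[int]:
        if self.sign == 1:
            return [1] * self.size
        return [1 if k % 2 == 0 else -1 for k in range(self.size)]


DEFAULT_BLOCKS = {
    "bacteria": [CorrelatedBlock(8, 1), CorrelatedBlock(6, -1)],
    "fungi": [CorrelatedBlock(6, 1), CorrelatedBlock(5, -1)],
}


@dataclass
class ScenarioSpec:
    """Parameters of the synthetic field-trial scenario.

    All defaults reproduce the study conditions; any field may be overridden
    (e.g. from a YAML config) for sensitivity runs.
    """

    treatments: Sequence[str] = field(default_factory=lambda: list(TREATMENTS))
    replicates_per_treatment: int = 3
    chemistry_means: pd.DataFrame = field(default_factory=lambda: CHEMISTRY_MEANS.copy())
    chemistry_sds: pd.DataFrame = field(default_factory=lambda: CHEMISTRY_SDS.copy())
    richness_multiplier: pd.DataFrame = field(
        default_factory=lambda: RICHNESS_MULTIPLIER.copy()
    )
    n_otus_base: dict = field(default_factory=lambda: {"bacteria": 300, "fungi": 150})
    library_size: int = 20000
    phylum_profiles: dict = field(
        default_factory=lambda: {d: PHYLUM_PROFILES[d].copy() for d in DOMAINS}
    )
    correlated_block_spec: dict = field(
        default_factory=lambda: {d: list(DEFAULT_BLOCKS[d]) for d in DOMAINS}
    )
    concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def control(self) -> str:
        return self.treatments[0]

    @property
    def domains(self) -> list[str]:
        return list(self.n_otus_base)

    def validate(self) -> None:
        if self.replicates_per_treatment < 2:
            raise ValueError("replicates_per_treatment must be >= 2")
        if len(set(self.treatments)) != len(self.treatments):
            raise ValueError("treatments: duplicate labels")
        for df, name in ((self.chemistry_means, "chemistry_means"),
                         (self.chemistry_sds, "chemistry_sds")):
            missing = set(self.treatments) - set(df.index)
            if missing:
                raise ValueError(f"{name}: missing treatments {sorted(missing)}")
        if (self.chemistry_sds.loc[list(self.treatments)] < 0).any().any():
            raise ValueError("chemistry_sds: negative standard deviation")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        for domain in self.domains:
            if self.n_otus_base[domain] < 1:
                raise ValueError(f"n_otus_base[{domain}] must be positive")
            mult = self.richness_multiplier[domain]
            if abs(mult.loc[self.control] - 1.0) > 1e-9:
                raise ValueError(
                    f"richness_multiplier[{domain}]: control fold-change must be 1"
                )
            if (mult.loc[list(self.treatments)] < 1.0 - 1e-9).any():
                raise ValueError(
                    f"richness_multiplier[{domain}]: fold-changes must be >= 1"
                )
            prof = self.phylum_profiles[domain].loc[list(self.treatments)]
            if (prof < 0).any().any():
                raise ValueError(f"phylum_profiles[{domain}]: negative entry")
            bad = (prof.sum(axis=1) - 1.0).abs() > 1e-9
            if bad.any():
                raise ValueError(
                    f"phylum_profiles[{domain}]: rows not summing to 1 for "
                    f"{list(prof.index[bad])}"
                )

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=int(seed))

    @classmethod
    def flat(cls, seed: int = 0, **kwargs) -> "ScenarioSpec":
        """A scenario with no treatment-level community structure.

        All richness multipliers are 1 and every treatment shares the mean
        phylum profile, so planted correlated blocks are the only source of
        OTU covariation.  Used to audit network recovery, where
        treatment-driven covariation would otherwise count as real signal.
        """
        spec = cls(seed=seed, **kwargs)
        spec.richness_multiplier = pd.DataFrame(
            1.0, index=spec.richness_multiplier.index,
            columns=spec.richness_multiplier.columns,
        )
        flat_profiles = {}
        for domain, prof in spec.phylum_profiles.items():
            mean = prof.mean(axis=0)
            flat_profiles[domain] = pd.DataFrame(
                np.tile(mean.values, (len(prof), 1)),
                index=prof.index, columns=prof.columns,
            )
        spec.phylum_profiles = flat_profiles
        spec.validate()
        return spec

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "ScenarioSpec":
        """Build a spec from plain-python overrides of the defaults.

        Matrix-valued fields accept nested mappings ({treatment: {column:
        value}}) which are merged onto the default tables.
        """
        spec = cls()
        if not overrides:
            return spec
        known = set(spec.__dataclass_fields__)
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        for key, value in overrides.items():
            current = getattr(spec, key)
            if isinstance(current, pd.DataFrame) and isinstance(value, dict):
                updated = current.copy()
                for row, cols in value.items():
                    for col, v in cols.items():
                        updated.loc[row, col] = v
                setattr(spec, key, updated)
            elif key == "correlated_block_spec":
                blocks = {
                    dom: [b if isinstance(b, CorrelatedBlock) else CorrelatedBlock(**b)
                          for b in doms]
                    for dom, doms in value.items()
                }
                spec.correlated_block_spec = blocks
            elif key == "phylum_profiles" and isinstance(value, dict) and any(
                isinstance(v, dict) for v in value.values()
            ):
                spec.phylum_profiles = {
                    dom: pd.DataFrame(v).pipe(
                        lambda df: df.div(df.sum(axis=1), axis=0)
                    ) if isinstance(v, dict) else v
                    for dom, v in value.items()
                }
            else:
                setattr(spec, key, value)
        spec.validate()
        return spec

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return cls.from_dict(overrides)
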