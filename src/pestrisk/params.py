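"""Species parameter sets for the mechanistic ecoclimatic model.

The parameter mnemonics follow the CLIMEX convention: DV0..DV3 bound the
trapezoidal temperature growth response, SM0..SM3 the soil-moisture response,
and each stress mechanism has a threshold / weekly accumulation-rate pair.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

PARAMETER_KEYS = (
    "DV0", "DV1", "DV2", "DV3",
    "SM0", "SM1", "SM2", "SM3",
    "TTCS", "THCS",
    "TTHS", "THHS",
    "SMDS", "HDS",
    "SMWS", "HWS",
    "TTHW", "MTHW", "PHW",
)


@dataclass(frozen=True)
class SpeciesParameters:
    """Thresholds and weekly stress rates for one species.

    Temperature thresholds are deg C; soil-moisture thresholds are fractions of
    bucket capacity (values above 1 denote moisture above field capacity);
    rates are week^-1.
    """

    DV0: float  # lower temperature threshold
    DV1: float  # lower optimum temperature
    DV2: float  # upper optimum temperature
    DV3: float  # upper temperature threshold
    SM0: float  # lower soil-moisture threshold (wilting point)
    SM1: float  # lower optimal soil moisture
    SM2: float  # upper optimal soil moisture
    SM3: float  # upper soil-moisture threshold
    TTCS: float  # cold-stress temperature threshold (weekly tmin)
    THCS: float  # cold-stress accumulation rate
    TTHS: float  # heat-stress temperature threshold (weekly tavg)
    THHS: float  # heat-stress accumulation rate
    SMDS: float  # dry-stress soil-moisture threshold
    HDS: float   # dry-stress accumulation rate
    SMWS: float  # wet-stress soil-moisture threshold
    HWS: float   # wet-stress accumulation rate
    TTHW: float  # hot-wet temperature threshold (weekly tavg)
    MTHW: float  # hot-wet soil-moisture threshold
    PHW: float   # hot-wet accumulation rate

    def __post_init__(self) -> None:
        if not (self.DV0 <= self.DV1 <= self.DV2 <= self.DV3):
            raise ValueError("temperature thresholds must satisfy DV0 <= DV1 <= DV2 <= DV3")
        if not (self.SM0 <= self.SM1 <= self.SM2):
            raise ValueError("soil-moisture thresholds must satisfy SM0 <= SM1 <= SM2")
        if self.SM3 < self.SM2:
            raise ValueError("SM3 must be >= SM2")
        for rate in ("THCS", "THHS", "HDS", "HWS", "PHW"):
            if getattr(self, rate) < 0:
                raise ValueError(f"stress rate {rate} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "SpeciesParameters":
        return replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesParameters":
        data = yaml.safe_load(Path(path).read_text())
        missing = [k for k in PARAMETER_KEYS if k not in data]
        if missing:
            raise ValueError(f"parameter file missing keys: {missing}")
        extra = [k for k in data if k not in PARAMETER_KEYS]
        if extra:
            raise ValueError(f"parameter file has unknown keys: {extra}")
        return cls(**{k: float(data[k]) for k in PARAMETER_KEYS})


def sweetgum_parameters() -> SpeciesParameters:
    """Published parameter set for the host tree Liquidambar styraciflua.

    American sweetgum is a humid-subtropical tree: growth optimum 16-32 deg C,
    soil-moisture optimum 0.5-0.75 of capacity, hardy to roughly -29 deg C,
    and limited in hot-wet tropical climates.
    """
    return SpeciesParameters(
        DV0=10.0, DV1=16.0, DV2=32.0, DV3=38.0,
        SM0=0.1, SM1=0.5, SM2=0.75, SM3=1.5,
        TTCS=-28.9, THCS=0.9,
        TTHS=40.0, THHS=0.2,
        SMDS=0.1, HDS=0.01,
        SMWS=1.8, HWS=0.1,
        TTHW=28.0, MTHW=2.8, PHW=0.05,
    )


# Alternative values reported in the narrative description of the fitting
# process, where it disagrees with the tabulated final parameter set. Apply
# with sweetgum_parameters().replace(**SWEETGUM_TEXT_VARIANTS) if desired.
SWEETGUM_TEXT_VARIANTS = {
    "SM3": 1.8,
    "HDS": 0.001,
    "HWS": 0.001,
    "MTHW": 1.8,
}
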