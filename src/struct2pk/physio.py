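"""Rat physiology and tissue composition tables.

Both tables ship as versioned CSV files with citation headers under
``struct2pk/data``. The physiology table carries organ volumes and regional
blood flows per kg body weight; the composition table carries the
fractional water/lipid/protein make-up each distribution model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: perfused tissue compartments of the whole-body model (blood handled apart)
TISSUES = (
    "adipose", "bone", "brain", "gut", "heart",
    "kidney", "liver", "lung", "muscle", "skin", "spleen",
)
#: tissues whose venous outflow drains into the portal vein / liver
PORTAL_TISSUES = ("gut", "spleen")

DEFAULT_BODY_WEIGHT_G = 250.0
DEFAULT_HEMATOCRIT = 0.45
#: mg microsomal protein per g liver
DEFAULT_MPPGL = 45.0


def _data_path(name: str):
    return resources.files("struct2pk.data").joinpath(name)


@dataclass
class PhysiologyTable:
    """Organ volumes [mL/kg] and blood flows [mL/min/kg] for one species."""

    table: pd.DataFrame  # indexed by tissue
    body_weight_g: float = DEFAULT_BODY_WEIGHT_G
    hematocrit: float = DEFAULT_HEMATOCRIT

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.table.index)
        if missing:
            raise ValueError(f"physiology table missing tissues: {sorted(missing)}")
        if (self.table["volume_ml_per_kg"] <= 0).any():
            raise ValueError("all tissue volumes must be positive")
        flows = self.table["flow_ml_per_min_kg"]
        systemic = [t for t in TISSUES if t != "lung"]
        if (flows.loc[systemic] <= 0).any():
            raise ValueError("all organ blood flows must be positive")
        co = float(flows.loc[systemic].sum())
        if not np.isclose(flows.loc["lung"], co, rtol=1e-6):
            raise ValueError(
                "lung (pulmonary) flow must equal the cardiac output, "
                f"the sum of systemic organ flows ({co:.4g})"
            )

    @classmethod
    def default_rat(cls) -> "PhysiologyTable":
        df = pd.read_csv(_data_path("rat_physiology.csv"), comment="#").set_index("tissue")
        return cls(table=df)

    def volume(self, tissue: str) -> float:
        return float(self.table.loc[tissue, "volume_ml_per_kg"])

    def flow(self, tissue: str) -> float:
        return float(self.table.loc[tissue, "flow_ml_per_min_kg"])

    @property
    def cardiac_output(self) -> float:
        """Sum of systemic organ flows, mL/min/kg."""
        return float(sum(self.flow(t) for t in TISSUES if t != "lung"))

    @property
    def hepatic_blood_flow(self) -> float:
        """Total liver inflow (hepatic artery + portal), mL/min/kg."""
        return float(self.flow("liver") + sum(self.flow(t) for t in PORTAL_TISSUES))

    @property
    def liver_mass_g_per_kg(self) -> float:
        # liver density taken as 1 g/mL
        return self.volume("liver")

    @property
    def plasma_volume(self) -> float:
        blood = self.volume("arterial_blood") + self.volume("venous_blood")
        return blood * (1.0 - self.hematocrit)


@dataclass
class TissueComposition:
    """Fractional tissue composition rows keyed by tissue, plus plasma."""

    table: pd.DataFrame  # indexed by tissue, includes a 'plasma' row

    REQUIRED = ("f_water_ec", "f_water_ic", "f_nl", "f_np", "ap_mg_per_g", "albumin_ratio", "f_protein")

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.table.index)
        if missing:
            raise ValueError(f"composition table missing tissues: {sorted(missing)}")
        if "plasma" not in self.table.index:
            raise ValueError("composition table requires a 'plasma' row")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"composition table missing column {col!r}")
        if (self.table[list(self.REQUIRED)] < 0).any().any():
            raise ValueError("composition fractions must be nonnegative")
        volumetric = ["f_water_ec", "f_water_ic", "f_nl", "f_np"]
        if (self.table[volumetric].sum(axis=1) > 1.0 + 1e-9).any():
            raise ValueError("per-tissue volumetric fractions must sum to <= 1")

    @classmethod
    def default_rat(cls) -> "TissueComposition":
        df = pd.read_csv(_data_path("tissue_composition.csv"), comment="#").set_index("tissue")
        return cls(table=df)

    @property
    def plasma(self) -> pd.Series:
        return self.table.loc["plasma"]

    def row(self, tissue: str) -> pd.Series:
        return self.table.loc[tissue]

    def with_plasma_mimic(self, name: str = "plasma_mimic", f_protein: float | None = None) -> "TissueComposition":
        """Return a copy with an added synthetic tissue composed like plasma.

        All water is extracellular (plasma has no intracellular space), lipid
        fractions equal plasma's, there is no acidic phospholipid, and the
        albumin ratio is 1 so that binding matches plasma binding exactly.
        ``f_protein`` can be overridden for methods that model protein
        binding through a tissue protein fraction.
        """
        mimic = self.plasma.copy()
        if f_protein is not None:
            mimic["f_protein"] = f_protein
        df = self.table.copy()
        df.loc[name] = mimic
        return TissueComposition(table=df)
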