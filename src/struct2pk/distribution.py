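"""Tissue-to-plasma partition coefficients and hepatic clearance conversions.

Five published tissue-distribution methods are implemented on top of a
shared rat tissue-composition table:

* Poulin & Theil (J Pharm Sci 2002): octanol:water partitioning over
  neutral lipid / phospholipid / water fractions with an unbound-tissue
  correction; adipose uses a vegetable-oil:water logD.
* Berezhkovskiy (J Pharm Sci 2004): the corrected form that moves the
  unbound-fraction terms onto the aqueous phases.
* Rodgers & Rowland (J Pharm Sci 2005/2006): ionization-aware, with an
  acidic-phospholipid association term for moderate-to-strong bases and an
  extracellular-protein term for acids, neutrals and weak bases.
* Schmitt (Toxicol In Vitro 2008): membrane-affinity based composition over
  water, neutral lipid, neutral/acidic phospholipid and protein. Some of
  the original interaction constants are proprietary to the reference
  implementation; the constants used here are documented approximations.
* "PK-Sim standard" (Willmann et al.): lipophilicity- and fu-driven
  partitioning over lumped lipid, water and protein. The vendor's exact
  cellular equations are only partially published; this is a documented
  approximation with the same inputs and qualitative behavior.

Clearance utilities invert and apply the well-stirred liver model and scale
microsomal intrinsic clearance to whole-body and liver-specific values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physio import TISSUES, DEFAULT_MPPGL, PhysiologyTable, TissueComposition

KP_METHODS = ("poulin_theil", "berezhkovskiy", "rodgers_rowland", "schmitt", "pksim_standard")

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELL = 7.22
#: blood-cell composition used to back out the acidic-phospholipid
#: association constant (Rodgers & Rowland 2005): intracellular water,
#: neutral lipid, neutral phospholipid fractions and acidic phospholipid
#: content [mg/g].
BLOOD_CELL = {"f_water_ic": 0.603, "f_nl": 0.0017, "f_np": 0.0029, "ap_mg_per_g": 0.5}
DEFAULT_HEMATOCRIT = 0.45

#: default hepatic blood flow for a rat, mL/min/kg
QH_RAT = 55.2
#: default rat liver mass, g per kg body weight (density 1 g/mL)
LIVER_G_PER_KG = 40.0

# Schmitt-style interaction constants (documented approximations)
_SCHMITT_ALPHA_NL = 0.001   # ion partitioning into neutral lipids
_SCHMITT_BETA_NP = 0.3      # ion partitioning into neutral phospholipids
_SCHMITT_GAMMA_AP = 20.0    # cation affinity enhancement for acidic phospholipids
_SCHMITT_PROT_A = 0.163     # protein-binding regression intercept
_SCHMITT_PROT_B = 0.0221    # protein-binding regression slope


@dataclass
class IonizationState:
    ionization_class: str  # neutral | acid | base | zwitterion
    fraction_acid_ionized: float
    fraction_base_ionized: float

    @property
    def fraction_ionized(self) -> float:
        """Fraction of molecules carrying at least one charge."""
        return 1.0 - (1.0 - self.fraction_acid_ionized) * (1.0 - self.fraction_base_ionized)


@dataclass
class ParameterSet:
    """Mechanistic-model inputs for one compound.

    Units: cl_invivo mL/min/kg (plasma), clint_microsomal µL/min/mg
    microsomal protein, fu fraction in (0, 1], mw g/mol; logp and pKa
    unitless. At least one clearance input must be present to simulate.
    """

    fu: float
    logp: float
    mw: float
    n_halogens: int = 0
    cl_invivo: float | None = None
    clint_microsomal: float | None = None
    pka_acid: float | None = None
    pka_base: float | None = None
    ionization_class: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.fu <= 1.0):
            raise ValueError(f"fu must lie in (0, 1], got {self.fu}")
        if self.cl_invivo is not None and self.cl_invivo <= 0:
            raise ValueError(f"cl_invivo must be > 0, got {self.cl_invivo}")
        # zero microsomal CLint is admissible: a metabolically stable compound
        if self.clint_microsomal is not None and self.clint_microsomal < 0:
            raise ValueError(f"clint_microsomal must be >= 0, got {self.clint_microsomal}")
        if self.n_halogens < 0:
            raise ValueError("n_halogens must be >= 0")
        derived = classify_ionization(self.pka_acid, self.pka_base).ionization_class
        if not self.ionization_class:
            self.ionization_class = derived
        elif self.ionization_class != derived:
            # honour an explicit flag, but it must be achievable with the pKas given
            if self.ionization_class == "base" and self.pka_base is None:
                warnings.warn(
                    "compound flagged as base without a basic pKa; "
                    "falling back to neutral distribution equations"
                )
                self.ionization_class = "neutral"

    @property
    def ionization(self) -> IonizationState:
        return classify_ionization(self.pka_acid, self.pka_base)


@dataclass
class KpVector:
    """Per-tissue tissue:plasma partition coefficients for one method."""

    method: str
    kp: pd.Series  # indexed by tissue, unitless, > 0

    def __post_init__(self) -> None:
        if self.method not in KP_METHODS:
            raise ValueError(f"unknown distribution method {self.method!r}")
        values = np.asarray(self.kp, dtype=float)
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            bad = self.kp[~np.isfinite(self.kp) | (self.kp <= 0)].index.tolist()
            raise ValueError(f"Kp must be finite and > 0; offending tissues: {bad}")

    def __getitem__(self, tissue: str) -> float:
        return float(self.kp.loc[tissue])


def classify_ionization(
    pka_acid: float | None, pka_base: float | None, ph: float = PH_PLASMA
) -> IonizationState:
    """Henderson–Hasselbalch ionization at the given pH (monoprotic each).

    Classification: acid when an acidic pKa <= 7 is present (and no basic
    pKa >= 7), base symmetrically, zwitterion when both, otherwise neutral.
    """
    fa = 1.0 / (1.0 + 10.0 ** (pka_acid - ph)) if pka_acid is not None else 0.0
    fb = 1.0 / (1.0 + 10.0 ** (ph - pka_base)) if pka_base is not None else 0.0
    acidic = pka_acid is not None and pka_acid <= 7.0
    basic = pka_base is not None and pka_base >= 7.0
    if acidic and basic:
        klass = "zwitterion"
    elif acidic:
        klass = "acid"
    elif basic:
        klass = "base"
    else:
        klass = "neutral"
    return IonizationState(klass, fa, fb)


# ---------------------------------------------------------------------------
# shared helpers

def _tissue_names(comp: TissueComposition) -> list[str]:
    return [t for t in comp.table.index if t != "plasma"]


def _fu_tissue_poulin(fu: float) -> float:
    # interstitial binding assumed half the plasma binding
    return 1.0 / (1.0 + 0.5 * (1.0 - fu) / fu)


def _resolve_fu_t(fu_tissue, tissue: str, default: float) -> float:
    if fu_tissue is None:
        return default
    if isinstance(fu_tissue, dict):
        return float(fu_tissue.get(tissue, default))
    return float(fu_tissue)


def _log_d74(params: ParameterSet) -> float:
    """logD at pH 7.4 from logP and the monoprotic pKas."""
    ion = classify_ionization(params.pka_acid, params.pka_base)
    neutral = (1.0 - ion.fraction_acid_ionized) * (1.0 - ion.fraction_base_ionized)
    neutral = max(neutral, 1e-12)
    return params.logp + np.log10(neutral)


def _vegetable_oil_d(params: ParameterSet) -> float:
    # Poulin & Theil regression from olive oil:water data
    return 10.0 ** (1.115 * _log_d74(params) - 1.35)


# ---------------------------------------------------------------------------
# Poulin & Theil / Berezhkovskiy

def kp_poulin_theil(
    params: ParameterSet, comp: TissueComposition, fu_tissue=None
) -> KpVector:
    """Poulin & Theil (2002) partition coefficients.

    Non-adipose tissues partition by octanol:water P over neutral lipid,
    phospholipid and water fractions with a plasma/tissue unbound-fraction
    correction; adipose uses the vegetable-oil:water distribution
    coefficient at pH 7.4 and unity tissue binding. ``fu_tissue`` overrides
    the computed unbound tissue fraction (scalar or per-tissue mapping),
    e.g. when measured tissue binding is available.
    """
    if params.fu <= 0:
        raise ValueError("fu must be positive for Poulin-Theil partitioning")
    p_oct = 10.0 ** params.logp
    d_veg = _vegetable_oil_d(params)
    pl = comp.plasma
    fw_p = pl["f_water_ec"] + pl["f_water_ic"]
    kp = {}
    for tissue in _tissue_names(comp):
        row = comp.row(tissue)
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        solvent = d_veg if tissue == "adipose" else p_oct
        num = solvent * (row["f_nl"] + 0.3 * row["f_np"]) + (fw_t + 0.7 * row["f_np"])
        den = solvent * (pl["f_nl"] + 0.3 * pl["f_np"]) + (fw_p + 0.7 * pl["f_np"])
        fu_t = 1.0 if tissue == "adipose" else _fu_tissue_poulin(params.fu)
        fu_t = _resolve_fu_t(fu_tissue, tissue, fu_t)
        kp[tissue] = (num / den) * (params.fu / fu_t)
    return KpVector("poulin_theil", pd.Series(kp))


def kp_berezhkovskiy(
    params: ParameterSet, comp: TissueComposition, fu_tissue=None
) -> KpVector:
    """Berezhkovskiy (2004) corrected partition coefficients.

    Same composition terms as Poulin-Theil, but the unbound fractions divide
    the aqueous terms of tissue and plasma instead of scaling the whole
    ratio; identical to Poulin-Theil when fu = 1.
    """
    if params.fu <= 0:
        raise ValueError("fu must be positive for Berezhkovskiy partitioning")
    p_oct = 10.0 ** params.logp
    d_veg = _vegetable_oil_d(params)
    pl = comp.plasma
    fw_p = pl["f_water_ec"] + pl["f_water_ic"]
    den_lipid = None
    kp = {}
    for tissue in _tissue_names(comp):
        row = comp.row(tissue)
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        solvent = d_veg if tissue == "adipose" else p_oct
        fu_t = 1.0 if tissue == "adipose" else _fu_tissue_poulin(params.fu)
        fu_t = _resolve_fu_t(fu_tissue, tissue, fu_t)
        num = solvent * (row["f_nl"] + 0.3 * row["f_np"]) + (fw_t + 0.7 * row["f_np"]) / fu_t
        den = solvent * (pl["f_nl"] + 0.3 * pl["f_np"]) + (fw_p + 0.7 * pl["f_np"]) / params.fu
        kp[tissue] = num / den
    return KpVector("berezhkovskiy", pd.Series(kp))


# ---------------------------------------------------------------------------
# Rodgers & Rowland

def _rr_base_branch(params: ParameterSet) -> bool:
    return params.pka_base is not None and params.pka_base >= 7.0


def kp_rodgers_rowland(
    params: ParameterSet,
    comp: TissueComposition,
    bp: float = 1.0,
    hematocrit: float = DEFAULT_HEMATOCRIT,
) -> KpVector:
    """Rodgers & Rowland (2005/2006) partition coefficients.

    Moderate-to-strong bases (basic pKa >= 7) bind acidic phospholipids
    driven by the fraction ionized at intracellular pH 7.0, with the
    association constant backed out of blood-cell partitioning (from the
    blood:plasma ratio ``bp``). Acids, neutrals and weak bases instead bind
    extracellular proteins scaled by the tissue:plasma albumin ratio, with
    the association constant backed out of fu. Computed internally as Kpu
    and converted to Kp via fu.
    """
    fu = params.fu
    p_oct = 10.0 ** params.logp
    pl = comp.plasma
    fw_p = pl["f_water_ec"] + pl["f_water_ic"]

    def pterm(f_nl: float, f_np: float) -> float:
        return p_oct * f_nl + (0.3 * p_oct + 0.7) * f_np

    kp = {}
    if _rr_base_branch(params):
        pka = params.pka_base
        x_iw = 10.0 ** (pka - PH_INTRACELLULAR)
        y_p = 10.0 ** (pka - PH_PLASMA)
        x_bc = 10.0 ** (pka - PH_BLOOD_CELL)
        kpu_bc = (hematocrit - 1.0 + bp) / (hematocrit * fu)
        ka_ap = (
            kpu_bc
            - ((1.0 + x_bc) / (1.0 + y_p)) * BLOOD_CELL["f_water_ic"]
            - pterm(BLOOD_CELL["f_nl"], BLOOD_CELL["f_np"]) / (1.0 + y_p)
        ) * (1.0 + y_p) / (BLOOD_CELL["ap_mg_per_g"] * x_bc)
        ka_ap = max(ka_ap, 0.0)
        for tissue in _tissue_names(comp):
            row = comp.row(tissue)
            kpu = (
                row["f_water_ec"]
                + ((1.0 + x_iw) / (1.0 + y_p)) * row["f_water_ic"]
                + (ka_ap * row["ap_mg_per_g"] * x_iw) / (1.0 + y_p)
                + pterm(row["f_nl"], row["f_np"]) / (1.0 + y_p)
            )
            kp[tissue] = kpu * fu
    else:
        x = y = 0.0
        if params.pka_acid is not None:
            x += 10.0 ** (PH_INTRACELLULAR - params.pka_acid)
            y += 10.0 ** (PH_PLASMA - params.pka_acid)
        if params.pka_base is not None:  # weak base, pKa < 7
            x += 10.0 ** (params.pka_base - PH_INTRACELLULAR)
            y += 10.0 ** (params.pka_base - PH_PLASMA)
        ka_pr = max(0.0, 1.0 / fu - fw_p - pterm(pl["f_nl"], pl["f_np"]) / (1.0 + y))
        for tissue in _tissue_names(comp):
            row = comp.row(tissue)
            kpu = (
                row["f_water_ec"]
                + ((1.0 + x) / (1.0 + y)) * row["f_water_ic"]
                + pterm(row["f_nl"], row["f_np"]) / (1.0 + y)
                + ka_pr * row["albumin_ratio"]
            )
            kp[tissue] = kpu * fu
    return KpVector("rodgers_rowland", pd.Series(kp))


# ---------------------------------------------------------------------------
# Schmitt

def _schmitt_species_fractions(params: ParameterSet) -> tuple[float, float, float, float]:
    ion = classify_ionization(params.pka_acid, params.pka_base)
    fa, fb = ion.fraction_acid_ionized, ion.fraction_base_ionized
    f_neutral = (1.0 - fa) * (1.0 - fb)
    f_anion = fa * (1.0 - fb)
    f_cation = fb * (1.0 - fa)
    f_zwit = fa * fb
    return f_neutral, f_anion, f_cation, f_zwit


def schmitt_affinities(params: ParameterSet) -> dict[str, float]:
    """Constituent affinities of the Schmitt-style composition model."""
    p_oct = 10.0 ** params.logp
    f_n, f_an, f_cat, f_zw = _schmitt_species_fractions(params)
    k_np = p_oct * (f_n + _SCHMITT_BETA_NP * (f_an + f_cat + f_zw))
    k_nl = p_oct * (f_n + _SCHMITT_ALPHA_NL * (1.0 - f_n))
    k_ap = p_oct * (f_n + _SCHMITT_BETA_NP * f_an + _SCHMITT_GAMMA_AP * (f_cat + f_zw))
    k_prot = _SCHMITT_PROT_A + _SCHMITT_PROT_B * k_np
    return {"k_nl": k_nl, "k_np": k_np, "k_ap": k_ap, "k_prot": k_prot}


def kp_schmitt(params: ParameterSet, comp: TissueComposition) -> KpVector:
    """Schmitt (2008)-style membrane-affinity partition coefficients.

    The membrane affinity of the neutral species is taken from logP;
    ionized species partition into neutral lipids and phospholipids with
    reduced affinity, and cations bind acidic phospholipids with enhanced
    affinity. Tissue protein binding follows the published affinity
    regression; the plasma side is anchored to the measured fu (plasma
    affinity = 1/fu). Interaction constants are documented approximations.
    """
    aff = schmitt_affinities(params)
    kp = {}
    for tissue in _tissue_names(comp):
        row = comp.row(tissue)
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        f_ap = row["ap_mg_per_g"] / 1000.0
        affinity = (
            fw_t
            + aff["k_nl"] * row["f_nl"]
            + aff["k_np"] * row["f_np"]
            + aff["k_ap"] * f_ap
            + aff["k_prot"] * row["f_protein"]
        )
        kp[tissue] = params.fu * affinity
    return KpVector("schmitt", pd.Series(kp))


# ---------------------------------------------------------------------------
# PK-Sim standard (documented approximation)

def kp_pksim_standard(params: ParameterSet, comp: TissueComposition) -> KpVector:
    """Lipophilicity/fu-driven partitioning over lumped lipid, water, protein.

    The protein association constant is backed out of plasma binding
    (1/fu = plasma water + P*plasma lipid + K_protein*plasma protein), then
    applied to each tissue's protein fraction. This is an approximation of
    the vendor's partially published cellular model and is labeled as such.
    """
    p_oct = 10.0 ** params.logp
    pl = comp.plasma
    fw_p = pl["f_water_ec"] + pl["f_water_ic"]
    f_l_p = pl["f_nl"] + pl["f_np"] + pl["ap_mg_per_g"] / 1000.0
    k_prot = max(0.0, (1.0 / params.fu - fw_p - p_oct * f_l_p) / pl["f_protein"])
    kp = {}
    for tissue in _tissue_names(comp):
        row = comp.row(tissue)
        fw_t = row["f_water_ec"] + row["f_water_ic"]
        f_l_t = row["f_nl"] + row["f_np"] + row["ap_mg_per_g"] / 1000.0
        kp[tissue] = params.fu * (fw_t + p_oct * f_l_t + k_prot * row["f_protein"])
    return KpVector("pksim_standard", pd.Series(kp))


_KP_DISPATCH = {
    "poulin_theil": kp_poulin_theil,
    "berezhkovskiy": kp_berezhkovskiy,
    "rodgers_rowland": kp_rodgers_rowland,
    "schmitt": kp_schmitt,
    "pksim_standard": kp_pksim_standard,
}


def compute_kp(method: str, params: ParameterSet, comp: TissueComposition | None = None, **kwargs) -> KpVector:
    """Partition coefficients under the named distribution method."""
    if method not in _KP_DISPATCH:
        raise ValueError(f"unknown distribution method {method!r}; choose from {KP_METHODS}")
    comp = comp if comp is not None else TissueComposition.default_rat()
    return _KP_DISPATCH[method](params, comp, **kwargs)


def plasma_mimic_kp(method: str, params: ParameterSet, comp: TissueComposition | None = None) -> float:
    """Kp of a synthetic tissue composed exactly like plasma (fu_t = fu_p).

    Each method sees a tissue whose water, lipid and binding match plasma's
    in the quantities that method consumes; the returned value is 1 up to
    floating-point error and serves as a symmetry check.
    """
    comp = comp if comp is not None else TissueComposition.default_rat()
    name = "plasma_mimic"
    if method == "schmitt":
        aff = schmitt_affinities(params)
        pl = comp.plasma
        fw_p = pl["f_water_ec"] + pl["f_water_ic"]
        f_prot = (
            1.0 / params.fu - fw_p - aff["k_nl"] * pl["f_nl"] - aff["k_np"] * pl["f_np"]
        ) / aff["k_prot"]
        mimic_comp = comp.with_plasma_mimic(name, f_protein=f_prot)
        return compute_kp(method, params, mimic_comp)[name]
    mimic_comp = comp.with_plasma_mimic(name)
    if method in ("poulin_theil", "berezhkovskiy"):
        return compute_kp(method, params, mimic_comp, fu_tissue={name: params.fu})[name]
    return compute_kp(method, params, mimic_comp)[name]


def kp_table(
    params_by_id: dict[str, ParameterSet],
    methods=KP_METHODS,
    comp: TissueComposition | None = None,
) -> pd.DataFrame:
    """Long-format Kp export: one row per (compound, method, tissue)."""
    comp = comp if comp is not None else TissueComposition.default_rat()
    rows = []
    for cid, params in params_by_id.items():
        for method in methods:
            for tissue, value in compute_kp(method, params, comp).kp.items():
                rows.append(
                    {"compound_id": cid, "method": method, "tissue": tissue, "kp": float(value)}
                )
    return pd.DataFrame(rows)


def vdss_from_kp(kp: KpVector, phys: PhysiologyTable | None = None) -> float:
    """Steady-state distribution volume implied by the Kp vector, mL/kg.

    Vdss = plasma volume + sum over tissues of Vt * Kp_t. The spread of
    this quantity across the five methods for one compound is the model's
    distribution-assumption variability.
    """
    phys = phys if phys is not None else PhysiologyTable.default_rat()
    vd = phys.plasma_volume
    for tissue in TISSUES:
        vd += phys.volume(tissue) * kp[tissue]
    return float(vd)


# ---------------------------------------------------------------------------
# clearance conversions

def wellstirred_cl_to_clint(
    cl_plasma: float, fu: float, qh: float = QH_RAT, bp: float = 1.0
) -> float:
    """Invert the well-stirred liver model: plasma CL -> intrinsic CL.

    CLh = Qh*fu_b*CLint / (Qh + fu_b*CLint) solved for CLint, with blood
    clearance CL_b = CL_plasma/bp and fu_b = fu/bp. All clearances in
    mL/min/kg. Requires CL_b strictly below hepatic blood flow Qh.
    """
    if cl_plasma <= 0 or fu <= 0 or qh <= 0 or bp <= 0:
        raise ValueError("all well-stirred inputs must be positive")
    cl_blood = cl_plasma / bp
    fu_b = fu / bp
    if cl_blood >= qh:
        raise ValueError(
            f"clearance exceeds hepatic blood flow ({cl_blood:.3g} >= {qh:.3g}); "
            "well-stirred inversion undefined"
        )
    return qh * cl_blood / (fu_b * (qh - cl_blood))


def clint_to_cl(clint: float, fu: float, qh: float = QH_RAT, bp: float = 1.0) -> float:
    """Forward well-stirred equation: intrinsic CL -> hepatic plasma CL.

    Bounded above by bp*Qh; the round trip with
    :func:`wellstirred_cl_to_clint` is the identity.
    """
    if clint < 0 or fu <= 0 or qh <= 0 or bp <= 0:
        raise ValueError("all well-stirred inputs must be positive")
    fu_b = fu / bp
    cl_blood = qh * fu_b * clint / (qh + fu_b * clint)
    return cl_blood * bp


def scale_microsomal_clint(
    clint_microsomal: float,
    mppgl: float = DEFAULT_MPPGL,
    liver_g_per_kg: float = LIVER_G_PER_KG,
) -> dict[str, float]:
    """Scale microsomal intrinsic clearance to whole-body and liver-specific.

    whole_body [mL/min/kg] = CLint[µL/min/mg] * MPPGL[mg/g] * liver[g/kg] / 1000;
    specific [1/min] = whole_body / liver volume per kg (liver density 1 g/mL).
    """
    if clint_microsomal < 0 or mppgl <= 0 or liver_g_per_kg <= 0:
        raise ValueError("scaling inputs must be positive (CLint may be zero)")
    whole_body = clint_microsomal * mppgl * liver_g_per_kg / 1000.0
    specific = whole_body / liver_g_per_kg
    return {"whole_body": whole_body, "specific": specific}
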