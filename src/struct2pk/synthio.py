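"""Synthetic compound libraries and "observed" rat IV profiles.

Measured rat PK data of the kind this pipeline consumes are almost always
proprietary, so the generator emulates them: a drug-like library built from
a shipped base-structure list (optionally decorated by aryl halogenation /
methylation), with "measured" parameters tied to computed structure
descriptors plus lognormal noise, masked to realistic per-measurement
availability; and observed concentration-time profiles produced by the
whole-body PBPK model under a designated truth distribution method with
multiplicative lognormal residual error. Everything is deterministic for a
given seed, and the emitted CSV schemas are exactly the ones the pipeline
reads, so end-to-end runs need no external data.

What the generator does NOT emulate: real assay-specific bias, correlated
measurement error across parameters, chemistry-series clustering, and
non-hepatic elimination; see the methods note for the consequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import (
    CompoundRecord,
    compute_logp,
    compute_mw,
    count_aromatic_rings,
    count_halogens,
    standardize_smiles,
)
from .distribution import ParameterSet, compute_kp
from .physio import PhysiologyTable, TissueComposition
from .simulate import (
    DEFAULT_TIMES,
    ConcentrationProfile,
    SimulationConfig,
    build_pbpk,
    simulate_pbpk,
)

#: marginal measurement availability, emulating a realistic discovery
#: dataset where in vivo CL is common and Fu is sparse
DEFAULT_COMPLETENESS = {
    "cl_invivo": 0.83,
    "vdss": 0.83,
    "clint": 0.71,
    "pka_acid": 0.72,
    "pka_base": 0.51,
    "fu": 0.30,
    "profile": 0.62,
}

#: log-linear truth coefficients: intercept + slopes on
#: (logP, MW/100, n_halogens, aromatic rings), natural-log scale
DEFAULT_COEFFS = {
    "cl_invivo": (2.3, 0.30, -0.15, 0.05, 0.10),
    "vdss": (6.2, 0.45, -0.05, 0.10, 0.15),
    # CLint intercept sits low on purpose: scaled microsomal clearance
    # understates total in vivo clearance, as liver microsomes miss
    # non-oxidative and extrahepatic elimination
    "clint": (2.2, 0.45, -0.10, 0.08, 0.12),
    # fu uses a logit-scale linear model (lipophilic compounds bind more)
    "fu_logit": (1.2, -0.85, -0.10, -0.15, -0.20),
}

_ACID_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_BASE_SMARTS = Chem.MolFromSmarts("[NX3;H2,H1,H0;!$(NC=O);!$(N=*);!$(N-a);!$(NS=O)]")

_MAX_CL_FRACTION_OF_QH = 0.85


@dataclass
class SynthConfig:
    """Study-condition knobs of the synthetic dataset."""

    n_compounds: int = 500
    seed: int = 0
    completeness: dict = field(default_factory=lambda: dict(DEFAULT_COMPLETENESS))
    p_complete: float = 0.12  # fraction with every measurement AND a profile
    coeffs: dict = field(default_factory=lambda: dict(DEFAULT_COEFFS))
    param_noise_sd: float = 0.2  # residual sd of the log-scale truth models
    truth_method: str = "rodgers_rowland"
    times: tuple = DEFAULT_TIMES
    profile_noise_sd: float = 0.2  # lognormal sd on observed concentrations
    decorate: bool = True

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("n_compounds must be >= 10")
        for key, rate in self.completeness.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"completeness rate for {key} must lie in [0, 1]")


@dataclass
class SynthLibrary:
    """A generated library: masked records plus the unmasked truth table."""

    records: list[CompoundRecord]
    truth: pd.DataFrame  # indexed by compound_id; true parameters + descriptors
    profile_ids: set[str]
    config: SynthConfig

    def true_parameter_set(self, compound_id: str) -> ParameterSet:
        row = self.truth.loc[compound_id]
        return ParameterSet(
            fu=float(row["fu"]),
            logp=float(row["logp"]),
            mw=float(row["mw"]),
            n_halogens=int(row["n_halogens"]),
            cl_invivo=float(row["cl_invivo"]),
            clint_microsomal=float(row["clint"]),
            pka_acid=None if pd.isna(row["pka_acid"]) else float(row["pka_acid"]),
            pka_base=None if pd.isna(row["pka_base"]) else float(row["pka_base"]),
        )


def _base_structures() -> list[str]:
    text = resources.files("struct2pk.data").joinpath("drug_smiles.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def _decorations(smiles: str) -> list[str]:
    """Aryl-halogenated / methylated variants of one structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return []
    sites = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]
    variants = []
    for site in sites[:2]:
        for symbol in ("F", "Cl", "C"):
            rw = Chem.RWMol(mol)
            new_idx = rw.AddAtom(Chem.Atom(symbol))
            rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
            try:
                candidate = rw.GetMol()
                Chem.SanitizeMol(candidate)
            except Exception:
                continue
            variants.append(Chem.MolToSmiles(candidate))
    return variants


def _structure_pool(config: SynthConfig, rng: np.random.Generator) -> list[str]:
    base = _base_structures()
    pool = list(base)
    if config.decorate:
        for smiles in base:
            pool.extend(_decorations(smiles))
    # dedupe on standardized form, preserving order
    seen, unique = set(), []
    for s in pool:
        try:
            std = standardize_smiles(s)
        except Exception:
            continue
        if std not in seen:
            seen.add(std)
            unique.append(std)
    if config.n_compounds > len(unique):
        raise ValueError(
            f"n_compounds={config.n_compounds} exceeds decorated-structure capacity {len(unique)}"
        )
    order = rng.permutation(len(unique))
    return [unique[i] for i in order[: config.n_compounds]]


def _linear_truth(coef, logp, mw, n_hal, n_ar) -> float:
    a0, a1, a2, a3, a4 = coef
    return a0 + a1 * logp + a2 * mw / 100.0 + a3 * n_hal + a4 * n_ar


def generate_library(
    config: SynthConfig | None = None,
    phys: PhysiologyTable | None = None,
    comp: TissueComposition | None = None,
) -> SynthLibrary:
    """Generate a compound library with structure-correlated true parameters.

    True log CL / log CLint / logit Fu are linear in (logP, MW, halogen
    count, aromatic rings) plus Gaussian noise; pKas are assigned from
    functional-group pattern matches; true Vdss is the PBPK-implied volume
    under the truth distribution method times lognormal noise, keeping the
    1-compartment scenario consistent with the generated profiles.
    Measurements are then masked: a seeded ~``p_complete`` subset keeps
    everything (and a profile), the rest follow the marginal completeness
    rates. Deterministic per seed.
    """
    config = config or SynthConfig()
    phys = phys or PhysiologyTable.default_rat()
    comp = comp or TissueComposition.default_rat()
    rng = np.random.default_rng(config.seed)
    structures = _structure_pool(config, rng)
    qh = phys.hepatic_blood_flow
    cl_cap = _MAX_CL_FRACTION_OF_QH * qh

    rows = []
    records = []
    profile_ids: set[str] = set()
    for i, smiles in enumerate(structures):
        cid = f"SYN{i:04d}"
        logp = compute_logp(smiles)
        mw = compute_mw(smiles)
        n_hal = count_halogens(smiles)
        n_ar = count_aromatic_rings(smiles)
        mol = Chem.MolFromSmiles(smiles)
        has_acid = mol.HasSubstructMatch(_ACID_SMARTS)
        has_base = mol.HasSubstructMatch(_BASE_SMARTS)
        # every molecule has a most-acidic and most-basic pKa; functional
        # groups decide whether it is pharmacologically relevant (<= 7 acid,
        # >= 7 base) or far from physiological pH
        if has_acid:
            pka_acid = float(np.clip(rng.normal(4.5, 1.0), 2.5, 7.0))
        else:
            pka_acid = float(np.clip(rng.normal(11.5, 1.0), 8.5, 14.0))
        if has_base:
            pka_base = float(np.clip(rng.normal(8.8, 1.0), 7.1, 10.5))
        else:
            pka_base = float(np.clip(rng.normal(2.5, 1.0), 0.5, 5.0))

        sd = config.param_noise_sd
        cl = float(np.exp(_linear_truth(config.coeffs["cl_invivo"], logp, mw, n_hal, n_ar) + rng.normal(0, sd)))
        cl = float(np.clip(cl, 0.5, cl_cap))
        fu_logit = _linear_truth(config.coeffs["fu_logit"], logp, mw, n_hal, n_ar) + rng.normal(0, 2.5 * sd)
        fu = float(np.clip(1.0 / (1.0 + np.exp(-fu_logit)), 0.01, 1.0))

        vdss = float(
            np.exp(_linear_truth(config.coeffs["vdss"], logp, mw, n_hal, n_ar) + rng.normal(0, sd))
        )
        clint_micro = float(
            np.exp(_linear_truth(config.coeffs["clint"], logp, mw, n_hal, n_ar) + rng.normal(0, sd))
        )

        complete = rng.random() < config.p_complete
        rates = config.completeness
        denom = max(1.0 - config.p_complete, 1e-12)

        def adjusted(rate: float) -> float:
            return max(0.0, (rate - config.p_complete) / denom)

        masks = {
            key: True if complete else rng.random() < adjusted(rates[key])
            for key in ("cl_invivo", "vdss", "clint", "pka_acid", "pka_base", "fu")
        }
        has_profile = True if complete else rng.random() < adjusted(rates["profile"])
        if has_profile:
            profile_ids.add(cid)

        truth_row = {
            "compound_id": cid,
            "smiles": smiles,
            "logp": logp,
            "mw": mw,
            "n_halogens": n_hal,
            "n_aromatic_rings": n_ar,
            "cl_invivo": cl,
            "vdss": vdss,
            "clint": clint_micro,
            "pka_acid": pka_acid,
            "pka_base": pka_base,
            "fu": fu,
            "has_profile": has_profile,
        }
        rows.append(truth_row)
        measured = {}
        for key in ("cl_invivo", "vdss", "clint", "fu"):
            if masks[key]:
                measured[key] = truth_row[key]
        for key in ("pka_acid", "pka_base"):
            if masks[key] and not np.isnan(truth_row[key]):
                measured[key] = truth_row[key]
        records.append(CompoundRecord(compound_id=cid, smiles_raw=smiles, smiles_std=smiles, measured=measured))

    truth = pd.DataFrame(rows).set_index("compound_id")
    return SynthLibrary(records=records, truth=truth, profile_ids=profile_ids, config=config)


def generate_observed_profiles(
    library: SynthLibrary,
    truth_method: str | None = None,
    noise_sd: float | None = None,
    times=None,
    compound_ids=None,
    seed: int | None = None,
    phys: PhysiologyTable | None = None,
    comp: TissueComposition | None = None,
) -> list[ConcentrationProfile]:
    """Simulate "observed" 1 mg/kg IV profiles for library compounds.

    Each compound is run through the PBPK model with its TRUE (unmasked)
    parameters under the truth distribution method, then multiplicative
    lognormal error exp(N(0, noise_sd^2)) is applied per sample.
    """
    cfg = library.config
    truth_method = truth_method or cfg.truth_method
    noise_sd = cfg.profile_noise_sd if noise_sd is None else noise_sd
    times = np.asarray(times if times is not None else cfg.times, dtype=float)
    ids = sorted(compound_ids if compound_ids is not None else library.profile_ids)
    phys = phys or PhysiologyTable.default_rat()
    comp = comp or TissueComposition.default_rat()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    profiles = []
    for cid in ids:
        params = library.true_parameter_set(cid)
        kp = compute_kp(truth_method, params, comp)
        config = SimulationConfig(
            model="pbpk", distribution_method=truth_method, clearance_mode="invivo_cl", times=tuple(times)
        )
        try:
            system = build_pbpk(params, kp, phys, config, compound_id=cid)
            profile = simulate_pbpk(system, times)
        except Exception as exc:
            raise RuntimeError(f"truth simulation failed for {cid}: {exc}") from exc
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(times))) if noise_sd > 0 else 1.0
        profiles.append(
            ConcentrationProfile(cid, config.dose, times, profile.concentrations * noise)
        )
    return profiles


def profiles_to_frame(profiles: list[ConcentrationProfile]) -> pd.DataFrame:
    """Long-format observed-profile table (the pipeline's CSV schema)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)


def profiles_from_frame(df: pd.DataFrame) -> list[ConcentrationProfile]:
    profiles = []
    for cid, sub in df.groupby("compound_id", sort=True):
        sub = sub.sort_values("time_h")
        profiles.append(
            ConcentrationProfile(
                str(cid),
                float(sub["dose_mg_per_kg"].iloc[0]),
                sub["time_h"].to_numpy(),
                sub["conc_mg_per_L"].to_numpy(),
            )
        )
    return profiles
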