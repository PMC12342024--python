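"""Plasma concentration-time simulation: 1-compartment and whole-body PBPK.

The 1-compartment model is the closed-form mono-exponential IV bolus
solution. The PBPK model is a perfusion-limited whole-body rat model:
eleven perfused tissues plus arterial and venous blood pools, the lung
bridging venous to arterial blood, gut and spleen draining through the
portal vein into the liver, and hepatic elimination acting on the unbound
liver outflow concentration (well-stirred liver). The system is linear, so
AUC to infinity is also available exactly from a linear solve.

Internal units: time min, volumes mL/kg, flows mL/min/kg, concentrations
mg/mL. Reported profiles use hours and mg/L (venous plasma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .distribution import (
    KpVector,
    ParameterSet,
    clint_to_cl,
    scale_microsomal_clint,
    wellstirred_cl_to_clint,
)
from .physio import DEFAULT_MPPGL, PORTAL_TISSUES, TISSUES, PhysiologyTable

#: sparse rat sampling design, h
DEFAULT_TIMES = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 24.0)
#: dense grid for AUC extrapolation work, h
DENSE_TIMES = tuple(np.round(np.geomspace(0.02, 24.0, 60), 5))

CLEARANCE_MODES = ("invivo_cl", "microsomal_clint")


@dataclass
class ConcentrationProfile:
    """A dose-annotated IV plasma concentration-time series."""

    compound_id: str
    dose: float  # mg/kg
    times: np.ndarray  # h, strictly increasing, >= 0
    concentrations: np.ndarray  # mg/L, >= 0
    route: str = "iv_bolus"
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(self.times) and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        # tolerate solver-level negative round-off only
        scale = float(np.max(self.concentrations, initial=0.0))
        if np.any(self.concentrations < -(1e-6 * scale + 1e-9)):
            raise ValueError("concentrations must be nonnegative")
        self.concentrations = np.clip(self.concentrations, 0.0, None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_id,
                "time_h": self.times,
                "conc_mg_per_L": self.concentrations,
                "dose_mg_per_kg": self.dose,
            }
        )


@dataclass
class SimulationConfig:
    """Scenario description for one simulation run."""

    model: str = "pbpk"  # one_compartment | pbpk
    distribution_method: str | None = None  # required iff model == pbpk
    clearance_mode: str = "invivo_cl"
    dose: float = 1.0  # mg/kg
    duration_h: float = 24.0
    times: tuple = DEFAULT_TIMES
    rtol: float = 1e-8
    atol: float = 1e-10
    bp: float = 1.0  # blood:plasma concentration ratio
    mppgl: float = DEFAULT_MPPGL

    def __post_init__(self) -> None:
        if self.model not in ("one_compartment", "pbpk"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "pbpk" and not self.distribution_method:
            raise ValueError("distribution_method is required for the pbpk model")
        if self.clearance_mode not in CLEARANCE_MODES:
            raise ValueError(f"unknown clearance_mode {self.clearance_mode!r}")


def simulate_1cmt(cl: float, vdss: float, dose: float, times) -> ConcentrationProfile:
    """Closed-form 1-compartment IV bolus profile.

    C(t) = (dose/Vdss) * exp(-(CL/Vdss) t). cl in mL/min/kg, vdss in mL/kg,
    dose in mg/kg, times in h; concentrations returned in mg/L.
    """
    if cl <= 0 or vdss <= 0 or dose <= 0:
        raise ValueError("cl, vdss and dose must all be positive")
    times = np.asarray(times, dtype=float)
    k_per_h = cl / vdss * 60.0
    c0_mg_per_l = dose / vdss * 1000.0
    conc = c0_mg_per_l * np.exp(-k_per_h * times)
    return ConcentrationProfile("", dose, times, conc)


@dataclass
class PbpkSystem:
    """A built whole-body PBPK ODE system for one compound.

    ``matrix`` is the full linear operator dy/dt = M y over the state
    vector [tissue concentrations..., arterial, venous, eliminated amount].
    """

    compound_id: str
    params: ParameterSet
    kp: KpVector
    phys: PhysiologyTable
    config: SimulationConfig
    matrix: np.ndarray = field(init=False, repr=False)
    states: tuple = field(init=False)
    specific_clearance: float = field(init=False)  # 1/min, per liver volume

    def __post_init__(self) -> None:
        cfg = self.config
        missing = [t for t in TISSUES if t not in self.kp.kp.index]
        if missing:
            raise ValueError(f"Kp missing for tissues: {missing}")
        self.specific_clearance = self._resolve_specific_clearance()
        self.states = tuple(TISSUES) + ("arterial_blood", "venous_blood", "eliminated")
        self.matrix = self._build_matrix()

    def _resolve_specific_clearance(self) -> float:
        cfg, params, phys = self.config, self.params, self.phys
        v_liver = phys.volume("liver")
        if cfg.clearance_mode == "invivo_cl":
            if params.cl_invivo is None:
                raise ValueError(f"{self.compound_id}: cl_invivo required for invivo_cl mode")
            clint_wb = wellstirred_cl_to_clint(
                params.cl_invivo, params.fu, qh=phys.hepatic_blood_flow, bp=cfg.bp
            )
            return clint_wb / v_liver
        if params.clint_microsomal is None:
            raise ValueError(f"{self.compound_id}: clint_microsomal required for microsomal_clint mode")
        return scale_microsomal_clint(
            params.clint_microsomal, mppgl=cfg.mppgl, liver_g_per_kg=phys.liver_mass_g_per_kg
        )["specific"]

    @property
    def cl_plasma(self) -> float:
        """Hepatic plasma clearance implied by the configured CLint, mL/min/kg."""
        clint_wb = self.specific_clearance * self.phys.volume("liver")
        return clint_to_cl(clint_wb, self.params.fu, qh=self.phys.hepatic_blood_flow, bp=self.config.bp)

    def _build_matrix(self) -> np.ndarray:
        phys, kp, cfg = self.phys, self.kp, self.config
        bp = cfg.bp
        fu_b = self.params.fu / bp
        idx = {name: i for i, name in enumerate(self.states)}
        n = len(self.states)
        m = np.zeros((n, n))
        v = {t: phys.volume(t) for t in TISSUES}
        q = {t: phys.flow(t) for t in TISSUES}
        co = phys.cardiac_output
        v_art = phys.volume("arterial_blood")
        v_ven = phys.volume("venous_blood")
        out = {t: bp / kp[t] for t in TISSUES}  # venous-equivalent blood conc per tissue conc
        ia, iv = idx["arterial_blood"], idx["venous_blood"]

        for t in TISSUES:
            if t == "lung":
                continue
            i = idx[t]
            m[i, ia] += q[t] / v[t]
            m[i, i] -= q[t] * out[t] / v[t]
            m[ia, ia] -= q[t] / v_art
        # portal drainage into the liver
        ili = idx["liver"]
        q_liver_total = q["liver"]
        for t in PORTAL_TISSUES:
            m[ili, idx[t]] += q[t] * out[t] / v["liver"]
            q_liver_total += q[t]
        # the liver row built above saw only the hepatic artery inflow; its
        # outflow must carry the full (artery + portal) flow
        m[ili, ili] -= (q_liver_total - q["liver"]) * out["liver"] / v["liver"]
        # hepatic elimination on unbound outflow concentration
        elim_rate = self.specific_clearance * v["liver"] * fu_b * out["liver"]  # mL/min/kg * (1/Kp)
        m[ili, ili] -= elim_rate / v["liver"]
        m[idx["eliminated"], ili] += elim_rate
        # lung bridges venous -> arterial
        ilu = idx["lung"]
        m[ilu, iv] += co / v["lung"]
        m[ilu, ilu] -= co * out["lung"] / v["lung"]
        m[ia, ilu] += co * out["lung"] / v_art
        # venous pool collects systemic outflows
        for t in TISSUES:
            if t in ("lung", "liver", *PORTAL_TISSUES):
                continue
            m[iv, idx[t]] += q[t] * out[t] / v_ven
        m[iv, ili] += q_liver_total * out["liver"] / v_ven
        m[iv, iv] -= co / v_ven
        return m

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(self.states))
        y0[self.states.index("venous_blood")] = self.config.dose / self.phys.volume("venous_blood")
        return y0

    def auc_infinity(self) -> float:
        """Exact venous-plasma AUC to infinity, h*mg/L, from a linear solve."""
        n_conc = len(self.states) - 1  # drop the eliminated-amount state
        m = self.matrix[:n_conc, :n_conc]
        y0 = self.initial_state()[:n_conc]
        integral = np.linalg.solve(m, -y0)  # mg*min/mL per compartment
        auc_blood = integral[self.states.index("venous_blood")]
        return float(auc_blood / self.config.bp * 1000.0 / 60.0)


def build_pbpk(
    params: ParameterSet,
    kp: KpVector,
    phys: PhysiologyTable | None = None,
    config: SimulationConfig | None = None,
    compound_id: str = "",
) -> PbpkSystem:
    """Assemble the perfusion-limited whole-body ODE system for one compound."""
    phys = phys if phys is not None else PhysiologyTable.default_rat()
    config = config if config is not None else SimulationConfig(distribution_method=kp.method)
    return PbpkSystem(compound_id=compound_id, params=params, kp=kp, phys=phys, config=config)


def _integrate(system: PbpkSystem, times_h: np.ndarray) -> np.ndarray:
    cfg = system.config
    t_eval = np.asarray(times_h, dtype=float) * 60.0
    t_span = (0.0, float(max(t_eval[-1], 1e-6)))
    mat = system.matrix
    sol = solve_ivp(
        lambda t, y: mat @ y,
        t_span,
        system.initial_state(),
        method="LSODA",
        t_eval=t_eval,
        rtol=cfg.rtol,
        atol=cfg.atol,
        jac=lambda t, y: mat,
    )
    if not sol.success:
        raise RuntimeError(
            f"PBPK solver failed for compound {system.compound_id!r}: {sol.message}; "
            f"params={system.params!r}"
        )
    return sol.y


def simulate_pbpk(system: PbpkSystem, times=None) -> ConcentrationProfile:
    """Integrate the system and report the venous plasma profile."""
    times_h = np.asarray(times if times is not None else system.config.times, dtype=float)
    y = _integrate(system, times_h)
    cv_blood = y[system.states.index("venous_blood")]
    conc = cv_blood / system.config.bp * 1000.0  # mg/L plasma
    return ConcentrationProfile(system.compound_id, system.config.dose, times_h, conc)


def simulate_states(system: PbpkSystem, times=None) -> pd.DataFrame:
    """Full state trajectories (tissue concentrations mg/mL, eliminated mg/kg)."""
    times_h = np.asarray(times if times is not None else system.config.times, dtype=float)
    y = _integrate(system, times_h)
    df = pd.DataFrame(y.T, columns=list(system.states))
    df.insert(0, "time_h", times_h)
    return df


def mass_balance_error(system: PbpkSystem, times=None) -> float:
    """Worst relative deviation of (tissue amounts + eliminated) from the dose."""
    states = simulate_states(system, times)
    phys = system.phys
    total = states["eliminated"].to_numpy().copy()
    for t in TISSUES:
        total += states[t].to_numpy() * phys.volume(t)
    total += states["arterial_blood"].to_numpy() * phys.volume("arterial_blood")
    total += states["venous_blood"].to_numpy() * phys.volume("venous_blood")
    return float(np.max(np.abs(total - system.config.dose) / system.config.dose))
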