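"""Temperature-pressure relaxation surfaces and derived glass-transition
quantities.

The structural relaxation time tau_alpha(T) at ambient pressure follows the
Vogel-Fulcher-Tammann (VFT) law

    tau(T) = tau_inf * exp[ B / (T - T0) ],

and the joint (T, p) dependence follows the modified Avramov equation, an
entropy-based surface

    tau(T, p) = tau_inf * exp{ ln(tau_g/tau_inf) *
                               [(T_r/T) * (1 + p/Pi)^(beta/alpha0)]^alpha0 }

with tau_g = tau(T_g) fixed to 100 s (the dielectric T_g definition),
reference temperature T_r close to T_g, pressure scale Pi, and exponents
alpha0 (fragility-like) and beta (pressure sensitivity).  The surface
carries a closed-form glass-transition line

    T_g(p) = T_r * (1 + p/Pi)^(beta/alpha0)

along which tau = tau_g exactly (the 100 s isochrone).  From the fitted
surface the pressure coefficient dTg/dp, the steepness (fragility) index
m = dlog10(tau)/d(Tg/T)|_Tg and the activation volume

    dV_alpha = ln(10) * R * T * (d log10 tau / d p)_T        [cm^3/mol]

are derived by finite differences; at T = Tg these obey the isochrone
identity dV_alpha = ln(10) * R * m * (dTg/dp).

All pressures are MPa internally; dTg/dp is reported in K/GPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq

R_GAS = 8.31446  # J mol^-1 K^-1
LOG10_TAU_G = 2.0  # tau_g = 100 s defines Tg
DP_MPA = 1.0  # pressure step for finite differences
DT_K = 0.01  # temperature step for finite differences
SURFACE_SEED = 4321


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RelaxationMap:
    """Records of (T, p, tau_alpha) feeding the VFT and surface fits."""

    temperature_K: np.ndarray
    pressure_MPa: np.ndarray
    tau_alpha_s: np.ndarray
    sigma_log10tau: np.ndarray | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.pressure_MPa = np.asarray(self.pressure_MPa, dtype=float)
        self.tau_alpha_s = np.asarray(self.tau_alpha_s, dtype=float)
        n = len(self.temperature_K)
        if not (len(self.pressure_MPa) == len(self.tau_alpha_s) == n):
            raise ValueError("ragged relaxation map")
        if np.any(self.tau_alpha_s <= 0):
            raise ValueError("tau_alpha must be positive")
        pairs = set(zip(self.temperature_K.tolist(), self.pressure_MPa.tolist()))
        if len(pairs) != n:
            raise ValueError("duplicate (T, p) records")
        if self.sigma_log10tau is not None:
            self.sigma_log10tau = np.asarray(self.sigma_log10tau, dtype=float)

    def ambient(self, p_ambient_MPa: float = 0.1, atol: float = 1e-9) -> "RelaxationMap":
        sel = np.abs(self.pressure_MPa - p_ambient_MPa) <= atol
        return RelaxationMap(
            self.temperature_K[sel], self.pressure_MPa[sel], self.tau_alpha_s[sel],
            None if self.sigma_log10tau is None else self.sigma_log10tau[sel],
            self.sample_id,
        )


@dataclass(frozen=True)
class VFTParams:
    log10_tau_inf: float
    B_K: float
    T0_K: float

    def log10_tau(self, T_K) -> np.ndarray | float:
        T = np.asarray(T_K, dtype=float)
        return self.log10_tau_inf + self.B_K / (np.log(10.0) * (T - self.T0_K))


@dataclass(frozen=True)
class AvramovParams:
    log10_tau_inf: float
    T_r_K: float
    Pi_MPa: float
    alpha0: float
    beta_exp: float
    log10_tau_g: float = LOG10_TAU_G
    meta: dict = field(default_factory=dict, compare=False)  # C_p0, C, Z, alpha_p, V_m

    def __post_init__(self) -> None:
        if self.Pi_MPa <= 0 or self.T_r_K <= 0 or self.alpha0 <= 0 or self.beta_exp < 0:
            raise ValueError("invalid Avramov parameters")

    def log10_tau(self, T_K, p_MPa) -> np.ndarray | float:
        T = np.asarray(T_K, dtype=float)
        p = np.asarray(p_MPa, dtype=float)
        span = self.log10_tau_g - self.log10_tau_inf  # decades from tau_inf to tau_g
        x = (self.T_r_K / T) ** self.alpha0 * (1.0 + p / self.Pi_MPa) ** self.beta_exp
        return self.log10_tau_inf + span * x

    def tg_closed_form(self, p_MPa) -> np.ndarray | float:
        """Glass-transition line Tg(p) = T_r*(1+p/Pi)^(beta/alpha0)."""
        p = np.asarray(p_MPa, dtype=float)
        return self.T_r_K * (1.0 + p / self.Pi_MPa) ** (self.beta_exp / self.alpha0)


@dataclass
class PressureCoefficients:
    tg_of_p: pd.DataFrame  # columns p_MPa, Tg_K
    dtg_dp_KperGPa: float
    steepness_m: float


@dataclass
class ActivationVolumeCurve:
    points: pd.DataFrame  # columns temperature_K, pressure_MPa, tg_over_t, dv_cm3mol


# ---------------------------------------------------------------------------
# VFT fit (ambient pressure)
# ---------------------------------------------------------------------------

def fit_vft(rmap: RelaxationMap, p_ambient_MPa: float = 0.1) -> VFTParams:
    """Least squares of the VFT law on log10(tau) over the ambient isobar."""
    amb = rmap.ambient(p_ambient_MPa) if np.ptp(rmap.pressure_MPa) > 1e-9 else rmap
    T, y = amb.temperature_K, np.log10(amb.tau_alpha_s)
    if len(T) < 6:
        raise ValueError("need at least 6 ambient-pressure records for VFT")
    w = (1.0 / np.clip(amb.sigma_log10tau, 1e-6, None)
         if amb.sigma_log10tau is not None else np.ones_like(y))

    params = lmfit.Parameters()
    params.add("log10_tau_inf", value=-12.0, min=-30.0, max=2.0)
    params.add("B_K", value=2000.0, min=1.0, max=1e6)
    params.add("T0_K", value=0.8 * T.min(), min=0.0, max=T.min() - 1e-6)

    def residual(p):
        v = VFTParams(p["log10_tau_inf"].value, p["B_K"].value, p["T0_K"].value)
        return w * (v.log10_tau(T) - y)

    res = lmfit.minimize(residual, params, method="least_squares",
                         ftol=1e-14, xtol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError("VFT fit did not converge")
    return VFTParams(res.params["log10_tau_inf"].value,
                     res.params["B_K"].value, res.params["T0_K"].value)


# ---------------------------------------------------------------------------
# Tg
# ---------------------------------------------------------------------------

def tg_from_curve(params: VFTParams | AvramovParams, p_MPa: float = 0.1,
                  bracket_K: tuple[float, float] = (50.0, 1000.0)) -> float:
    """Solve tau(T; p) = 100 s by bracketed root finding (tolerance 1e-6 K)."""
    if isinstance(params, VFTParams):
        def g(T): return params.log10_tau(T) - LOG10_TAU_G
        lo = max(bracket_K[0], params.T0_K + 1e-3)
    else:
        def g(T): return params.log10_tau(T, p_MPa) - params.log10_tau_g
        lo = bracket_K[0]
    hi = bracket_K[1]
    if g(lo) * g(hi) > 0:
        raise ValueError("tau(T) does not cross 100 s inside the bracket")
    return float(brentq(g, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Avramov surface fit
# ---------------------------------------------------------------------------

def fit_avramov_surface(
    rmap: RelaxationMap,
    meta: dict | None = None,
    fit_T_r: bool = True,
    n_starts: int = 5,
) -> AvramovParams:
    """Global weighted least squares of the modified Avramov surface.

    tau_g is held at 100 s (the Tg definition).  Initial values come from a
    VFT fit of the ambient isobar (T_r from the VFT Tg, alpha0 from the VFT
    steepness); a small deterministic multi-start guards against local
    minima in the (Pi, beta) direction.
    """
    pressures = np.unique(np.round(rmap.pressure_MPa, 6))
    if len(pressures) < 2:
        raise ValueError("surface fit needs >= 2 pressures; use fit_vft for one isobar")
    if len(np.unique(np.round(rmap.temperature_K, 6))) < 8:
        raise ValueError("surface fit needs >= 8 temperatures")
    if len(rmap.temperature_K) < 12:
        raise ValueError("surface fit needs >= 12 records")

    T, p, y = rmap.temperature_K, rmap.pressure_MPa, np.log10(rmap.tau_alpha_s)
    w = (1.0 / np.clip(rmap.sigma_log10tau, 1e-6, None)
         if rmap.sigma_log10tau is not None else np.ones_like(y))

    # VFT-informed initial values on the lowest isobar
    p0 = pressures.min()
    vft = fit_vft(rmap, p_ambient_MPa=p0)
    tg0 = tg_from_curve(vft)
    m0 = steepness_index(vft)
    lti0 = min(vft.log10_tau_inf, -6.0)
    a0 = max(m0 / (LOG10_TAU_G - lti0), 0.5)

    base = lmfit.Parameters()
    base.add("log10_tau_inf", value=lti0, min=-30.0, max=0.0)
    base.add("T_r_K", value=tg0, min=0.3 * tg0, max=3.0 * tg0, vary=fit_T_r)
    base.add("log10_Pi", value=3.0, min=1.0, max=6.0)  # Pi in MPa
    base.add("alpha0", value=a0, min=0.2, max=50.0)
    base.add("beta_exp", value=a0, min=1e-3, max=100.0)

    def residual(q):
        av = AvramovParams(q["log10_tau_inf"].value, q["T_r_K"].value,
                           10.0 ** q["log10_Pi"].value, q["alpha0"].value,
                           q["beta_exp"].value)
        return w * (av.log10_tau(T, p) - y)

    rng = np.random.default_rng(SURFACE_SEED)
    best = None
    for start in range(max(1, n_starts)):
        q = base.copy()
        if start > 0:
            q["log10_Pi"].value = float(np.clip(3.0 + rng.normal(0, 0.6), 1.1, 5.9))
            q["beta_exp"].value = float(np.clip(a0 * np.exp(rng.normal(0, 0.5)),
                                                1e-3, 99.0))
        try:
            res = lmfit.minimize(residual, q, method="least_squares",
                                 ftol=1e-14, xtol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("surface fit failed from every start")

    q = best.params
    return AvramovParams(q["log10_tau_inf"].value, q["T_r_K"].value,
                         10.0 ** q["log10_Pi"].value, q["alpha0"].value,
                         q["beta_exp"].value, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def tg_pressure_curve(params: AvramovParams,
                      p_grid_MPa: Sequence[float] | np.ndarray) -> pd.DataFrame:
    """Closed-form glass-transition line Tg(p) along the 100 s isochrone."""
    p = np.asarray(p_grid_MPa, dtype=float)
    return pd.DataFrame({"p_MPa": p, "Tg_K": params.tg_closed_form(p)})


def dtg_dp(params: AvramovParams, p_MPa: float = 0.1,
           dp_MPa: float = DP_MPA) -> float:
    """Pressure coefficient of Tg at ``p_MPa`` (central difference), K/GPa."""
    lo = max(p_MPa - dp_MPa, -params.Pi_MPa * 0.999)
    hi = p_MPa + dp_MPa
    slope = (params.tg_closed_form(hi) - params.tg_closed_form(lo)) / (hi - lo)
    return float(slope * 1000.0)  # K/MPa -> K/GPa


def steepness_index(params: VFTParams | AvramovParams, p_MPa: float = 0.1,
                    dx: float = 1e-4) -> float:
    """Fragility m = dlog10(tau)/d(Tg/T) at T = Tg(p)."""
    tg = tg_from_curve(params, p_MPa) if not isinstance(params, VFTParams) \
        else tg_from_curve(params)

    def logtau_of_x(x):  # x = Tg/T
        T = tg / x
        if isinstance(params, VFTParams):
            return params.log10_tau(T)
        return params.log10_tau(T, p_MPa)

    return float((logtau_of_x(1.0 + dx) - logtau_of_x(1.0 - dx)) / (2.0 * dx))


def activation_volume(params: AvramovParams, T_K: float, p_MPa: float = 0.1,
                      dp_MPa: float = DP_MPA) -> float:
    """Activation volume dV = ln(10)*R*T*(dlog10 tau/dp)_T in cm^3/mol.

    The slope is a central finite difference on the fitted surface; with p
    in MPa, 1 J/MPa = 1 cm^3, so dV = ln(10)*8.31446*T*slope numerically.
    """
    lo = max(p_MPa - dp_MPa, -params.Pi_MPa * 0.999)
    hi = p_MPa + dp_MPa
    slope = (params.log10_tau(T_K, hi) - params.log10_tau(T_K, lo)) / (hi - lo)
    return float(np.log(10.0) * R_GAS * T_K * slope)


def activation_volume_curve(params: AvramovParams,
                            tg_over_t: Sequence[float] | np.ndarray,
                            p_MPa: float = 0.1) -> ActivationVolumeCurve:
    """dV_alpha along a Tg/T scan at fixed pressure (the Fig-6b style curve)."""
    x = np.asarray(tg_over_t, dtype=float)
    tg = tg_from_curve(params, p_MPa)
    T = tg / x
    dv = np.array([activation_volume(params, t, p_MPa) for t in T])
    return ActivationVolumeCurve(points=pd.DataFrame({
        "temperature_K": T, "pressure_MPa": p_MPa, "tg_over_t": x,
        "dv_cm3mol": dv,
    }))


def pressure_coefficients(params: AvramovParams,
                          p_grid_MPa: Sequence[float] | np.ndarray,
                          ) -> PressureCoefficients:
    return PressureCoefficients(
        tg_of_p=tg_pressure_curve(params, p_grid_MPa),
        dtg_dp_KperGPa=dtg_dp(params),
        steepness_m=steepness_index(params),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_relaxation_map(path, sample_id: str | None = None) -> RelaxationMap:
    """TSV columns: temperature_K pressure_MPa tau_alpha_s [sigma_log10tau] [sample_id]."""
    df = pd.read_csv(path, sep="\t")
    if sample_id is not None and "sample_id" in df.columns:
        df = df[df["sample_id"] == sample_id]
    sig = df["sigma_log10tau"].to_numpy() if "sigma_log10tau" in df.columns else None
    sid = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else ""
    return RelaxationMap(df["temperature_K"].to_numpy(),
                         df["pressure_MPa"].to_numpy(),
                         df["tau_alpha_s"].to_numpy(), sig, sid)


def write_relaxation_map(rmap: RelaxationMap, path) -> None:
    df = pd.DataFrame({
        "temperature_K": rmap.temperature_K,
        "pressure_MPa": rmap.pressure_MPa,
        "tau_alpha_s": rmap.tau_alpha_s,
    })
    if rmap.sigma_log10tau is not None:
        df["sigma_log10tau"] = rmap.sigma_log10tau
    df["sample_id"] = rmap.sample_id
    df.to_csv(path, sep="\t", index=False)


def surface_summary(params: AvramovParams) -> dict:
    d = asdict(params)
    d["tg_ambient_K"] = tg_from_curve(params, 0.1)
    d["dtg_dp_KperGPa"] = dtg_dp(params)
    d["steepness_m"] = steepness_index(params)
    d["dv_at_tg_cm3mol"] = activation_volume(params, d["tg_ambient_K"], 0.1)
    return d
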