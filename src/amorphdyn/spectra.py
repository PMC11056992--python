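"""Havriliak-Negami modelling of broadband dielectric loss spectra.

A loss spectrum epsilon''(f) of a supercooled liquid is modelled as the
superposition of a dc-conductivity wing and one or two Havriliak-Negami
(HN) relaxation processes,

    eps''(omega) = sigma_dc / (eps0 * omega)
                   + sum_k Im[ -delta_eps_k / (1 + (i omega tau_k)^alpha_k)^beta_k ]

with omega = 2*pi*f and the physics sign convention eps* = eps' - i*eps''
(so eps'' >= 0).  alpha and beta are the symmetric and asymmetric
broadening exponents; alpha = beta = 1 recovers the Debye process.

The loss peak of an HN process does not sit at 1/(2*pi*tau_HN); the
structural relaxation time tau_alpha = 1/omega_max is obtained from the
Kremer-Schoenhals closed form (:func:`hn_peak_time`), which is verified
against a numerical peak finder in the test suite.

Fitting is weighted least squares on log10(eps'') — uniform weight per
point equalises data spanning many decades — with bounded trust-region
optimisation (lmfit) and a small deterministic multi-start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

# bounds used by fit_spectrum
ALPHA_MIN = 0.05
TAU_BOUNDS = (1e-12, 1e6)
MULTISTART_SEED = 1234
N_STARTS = 5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HNProcess:
    """One Havriliak-Negami relaxation process."""

    delta_eps: float
    tau_hn_s: float
    alpha_shape: float
    beta_shape: float
    label: str = "structural"  # or "secondary"

    def __post_init__(self) -> None:
        if not (self.delta_eps > 0):
            raise ValueError("delta_eps must be positive")
        if not (self.tau_hn_s > 0):
            raise ValueError("tau_hn_s must be positive")
        if not (0.0 < self.alpha_shape <= 1.0):
            raise ValueError("alpha_shape must lie in (0, 1]")
        if not (0.0 < self.beta_shape <= 1.0):
            raise ValueError("beta_shape must lie in (0, 1]")


@dataclass(frozen=True)
class SpectrumModel:
    """dc-conductivity plus 1-2 HN processes describing one loss spectrum."""

    processes: tuple[HNProcess, ...]
    sigma_dc: float = 0.0
    eps_inf: float = 1.0  # enters only the complex/storage output

    def __post_init__(self) -> None:
        if len(self.processes) < 1:
            raise ValueError("at least one HN process required")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be nonnegative")


@dataclass
class LossSpectrum:
    """A frequency sweep of dielectric loss at one (T, p) state point."""

    frequency_hz: np.ndarray
    loss: np.ndarray
    temperature_K: float
    pressure_MPa: float
    sample_id: str = ""
    storage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.loss = np.asarray(self.loss, dtype=float)
        if self.frequency_hz.shape != self.loss.shape:
            raise ValueError("frequency and loss must have equal length")
        if len(self.frequency_hz) < 8:
            raise ValueError("need at least 8 points per spectrum")
        if np.any(self.frequency_hz <= 0) or np.any(np.diff(self.frequency_hz) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        if np.any(self.loss < 0):
            raise ValueError("loss must be nonnegative")
        if not (self.temperature_K > 0 and self.pressure_MPa > 0):
            raise ValueError("temperature and pressure must be positive")


@dataclass
class SpectrumFitResult:
    model: SpectrumModel
    param_stderr: dict[str, float | None]
    residual_rms: float
    converged: bool
    n_points_used: int
    condition: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {
            "condition": self.condition,
            "converged": bool(self.converged),
            "residual_rms": float(self.residual_rms),
            "n_points_used": int(self.n_points_used),
            "sigma_dc": self.model.sigma_dc,
            "processes": [asdict(p) for p in self.model.processes],
            "stderr": self.param_stderr,
        }
        return rec


@dataclass(frozen=True)
class ShapeMetrics:
    """Width metrics of the normalised loss peak, in decades of frequency."""

    f_max_hz: float
    fwhm_decades: float
    left_halfwidth_decades: float
    right_halfwidth_decades: float


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _hn_complex(process: HNProcess, omega: np.ndarray) -> np.ndarray:
    """delta_eps / (1 + (i*omega*tau)^alpha)^beta for eps* = eps' - i*eps''."""
    iot = (1j * omega * process.tau_hn_s) ** process.alpha_shape
    return process.delta_eps / (1.0 + iot) ** process.beta_shape


def evaluate_model(
    model: SpectrumModel,
    frequency_hz: Sequence[float] | np.ndarray,
    want: Literal["loss", "complex"] = "loss",
) -> np.ndarray:
    """Evaluate the model loss eps''(f) (or the full complex permittivity).

    For ``want="complex"`` the returned array is
    eps*(f) = eps_inf + sum_k HN_k - i*sigma_dc/(eps0*omega), i.e. the
    imaginary part is -eps''.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * np.pi * f
    hn = sum(_hn_complex(p, omega) for p in model.processes)
    if want == "complex":
        return model.eps_inf + hn - 1j * model.sigma_dc / (EPS0 * omega)
    if want == "loss":
        return -hn.imag + model.sigma_dc / (EPS0 * omega)
    raise ValueError(f"unknown output kind {want!r}")


# ---------------------------------------------------------------------------
# HN peak time (tau_alpha)
# ---------------------------------------------------------------------------

def hn_peak_time(process: HNProcess) -> float:
    """Loss-peak relaxation time tau_alpha = 1/omega_max of an HN process.

    Kremer-Schoenhals closed form:

        tau_alpha = tau_HN * [sin(pi*a/(2+2b))]^(-1/a) * [sin(pi*a*b/(2+2b))]^(1/a)

    For alpha = beta = 1 (Debye) this collapses to tau_alpha = tau_HN.
    """
    a, b = process.alpha_shape, process.beta_shape
    s1 = np.sin(np.pi * a / (2.0 + 2.0 * b))
    s2 = np.sin(np.pi * a * b / (2.0 + 2.0 * b))
    return float(process.tau_hn_s * s1 ** (-1.0 / a) * s2 ** (1.0 / a))


def hn_time_from_peak(tau_alpha_s: float, alpha_shape: float, beta_shape: float) -> float:
    """Invert :func:`hn_peak_time`: the tau_HN whose loss peak sits at tau_alpha."""
    a, b = alpha_shape, beta_shape
    s1 = np.sin(np.pi * a / (2.0 + 2.0 * b))
    s2 = np.sin(np.pi * a * b / (2.0 + 2.0 * b))
    return float(tau_alpha_s * s1 ** (1.0 / a) * s2 ** (-1.0 / a))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

# fit parameter vector layout: per process (log10 delta_eps, log10 tau,
# alpha, beta), then optionally log10 sigma_dc
_PAR_NAMES = ("log_de", "log_tau", "alpha", "beta")


def _hn_loss_real(omega: np.ndarray, de: float, tau: float, a: float,
                  b: float) -> np.ndarray:
    """HN loss in real arithmetic: with u = (omega tau)^a,
    1 + (i omega tau)^a = r e^{i phi}, the loss is de * r^-b * sin(b phi).
    Identical to the complex form but ~10x faster (no complex pow)."""
    u = (omega * tau) ** a
    c, s = np.cos(0.5 * np.pi * a), np.sin(0.5 * np.pi * a)
    re, im = 1.0 + u * c, u * s
    r2 = re * re + im * im
    phi = np.arctan2(im, re)
    return de * r2 ** (-0.5 * b) * np.sin(b * phi)


def _log_loss_from_vector(x: np.ndarray, omega: np.ndarray, n_processes: int,
                          include_conductivity: bool) -> np.ndarray:
    """log10 of the model loss, written on raw arrays for speed."""
    total = np.zeros_like(omega)
    for k in range(n_processes):
        total = total + _hn_loss_real(omega, 10.0 ** x[4 * k],
                                      10.0 ** x[4 * k + 1],
                                      x[4 * k + 2], x[4 * k + 3])
    if include_conductivity:
        total = total + 10.0 ** x[-1] / (EPS0 * omega)
    return np.log10(np.clip(total, 1e-300, None))


def _model_from_vector(x: np.ndarray, n_processes: int,
                       include_conductivity: bool) -> SpectrumModel:
    procs = []
    for k in range(n_processes):
        procs.append(HNProcess(
            delta_eps=10.0 ** x[4 * k],
            tau_hn_s=10.0 ** x[4 * k + 1],
            alpha_shape=min(float(x[4 * k + 2]), 1.0),
            beta_shape=min(float(x[4 * k + 3]), 1.0),
            label="structural" if k == 0 else "secondary",
        ))
    sigma = 10.0 ** x[-1] if include_conductivity else 0.0
    return SpectrumModel(processes=tuple(procs), sigma_dc=sigma)


def _guess_conductivity(f: np.ndarray, loss: np.ndarray) -> float:
    """sigma_dc estimate from the low-frequency end assuming a slope -1 wing."""
    k = max(3, len(f) // 10)
    sig = np.median(loss[:k] * EPS0 * 2.0 * np.pi * f[:k])
    return float(max(sig, 1e-30))


def _initial_vector(f: np.ndarray, loss: np.ndarray, n_processes: int,
                    include_conductivity: bool):
    """Peak-based initial values: tau from the observed maxima, delta_eps from
    peak height x2, sigma_dc from the low-frequency slope-(-1) wing.
    Returns (x0, lower, upper)."""
    sigma0 = _guess_conductivity(f, loss) if include_conductivity else 0.0
    omega = 2.0 * np.pi * f
    if include_conductivity:
        wing = sigma0 / (EPS0 * omega)
        resid = loss - wing
        # conductivity-dominated points cannot seed an HN peak: any tiny
        # error in the sigma estimate leaves a huge spurious remainder there
        resid[wing > 0.8 * loss] = 0.0
    else:
        resid = loss.copy()
    resid = np.clip(resid, 1e-12 * max(loss.max(), 1e-30), None)

    # successive prominent local maxima of the conductivity-free loss
    peaks: list[int] = []
    work = resid.copy()
    for _ in range(n_processes):
        i = int(np.argmax(work))
        peaks.append(i)
        # blank out +-1.5 decades around the located peak
        mask = np.abs(np.log10(f / f[i])) < 1.5
        work = np.where(mask, 0.0, work)
        if work.max() <= 0:
            break
    while len(peaks) < n_processes:
        # undetected secondary process: park it 3 decades above the first peak
        peaks.append(min(len(f) - 1, int(np.argmin(np.abs(f - f[peaks[0]] * 1e3)))))
    peaks.sort(key=lambda i: f[i])  # lowest frequency first = structural

    x0, lo, hi = [], [], []
    for i in peaks:
        tau0 = 1.0 / (2.0 * np.pi * f[i])
        de0 = max(2.0 * resid[i], 1e-6)
        x0 += [np.log10(de0), np.log10(tau0), 0.8, 0.7]
        lo += [-8.0, np.log10(TAU_BOUNDS[0]), ALPHA_MIN, ALPHA_MIN]
        hi += [8.0, np.log10(TAU_BOUNDS[1]), 1.0, 1.0]
    if include_conductivity:
        x0.append(np.log10(sigma0))
        lo.append(-30.0)
        hi.append(5.0)
    return np.array(x0), np.array(lo), np.array(hi)


def fit_spectrum(
    spectrum: LossSpectrum,
    n_processes: int = 1,
    include_conductivity: bool = True,
    window: tuple[float, float] | None = None,
    symmetric_secondary: bool = False,
    n_starts: int = N_STARTS,
) -> SpectrumFitResult:
    """Fit dc-conductivity + HN superposition to one loss spectrum.

    Least squares on log10(eps'') over ``window`` (an (f_lo, f_hi) range in
    Hz), bounded trust-region, with ``n_starts`` deterministically jittered
    restarts keeping the best residual.  ``symmetric_secondary`` pins the
    second process to beta = 1 (Cole-Cole shape).
    """
    if n_processes not in (1, 2):
        raise ValueError("n_processes must be 1 or 2")
    f, y = spectrum.frequency_hz, spectrum.loss
    if window is not None:
        lo, hi = window
        sel = (f >= lo) & (f <= hi)
        f, y = f[sel], y[sel]
    pos = y > 0
    f, y = f[pos], y[pos]
    n_par = 4 * n_processes + int(include_conductivity)
    if len(f) <= n_par:
        raise ValueError(f"{len(f)} usable points cannot constrain {n_par} parameters")
    logy = np.log10(y)
    omega = 2.0 * np.pi * f

    def residual(x: np.ndarray) -> np.ndarray:
        return _log_loss_from_vector(x, omega, n_processes,
                                     include_conductivity) - logy

    x0, lo, hi = _initial_vector(f, y, n_processes, include_conductivity)
    fixed_beta1 = symmetric_secondary and n_processes == 2
    if fixed_beta1:  # Cole-Cole secondary: pin beta of process 1 at 1
        x0[7] = 1.0
        lo[7] = 1.0 - 1e-12

    rng = np.random.default_rng(MULTISTART_SEED)
    best = None
    jitter_scale = np.zeros_like(x0)
    for k in range(n_processes):
        jitter_scale[4 * k:4 * k + 4] = (0.3, 0.3, 0.1, 0.1)
    if include_conductivity:
        jitter_scale[-1] = 0.2
    if fixed_beta1:
        jitter_scale[7] = 0.0
    for start in range(max(1, n_starts)):
        x_start = x0.copy()
        if start > 0:  # jitter around the heuristic start
            x_start = np.clip(x0 + rng.normal(0.0, 1.0, x0.shape)
                              * jitter_scale, lo + 1e-9, hi - 1e-12)
            if fixed_beta1:
                x_start[7] = 1.0
        try:
            res = least_squares(residual, x_start, bounds=(lo, hi),
                                method="trf", ftol=1e-10, xtol=1e-10,
                                gtol=1e-10)
        except Exception:
            continue
        confirmed = (best is not None
                     and res.cost <= best.cost * (1.0 + 1e-6))
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-24:  # essentially exact fit; restarts cannot improve
            break
        if confirmed:  # an independent start reproduced the best minimum
            break

    if best is None:
        raise RuntimeError("all optimizer starts failed")

    model = _model_from_vector(best.x, n_processes, include_conductivity)
    stderr = _propagate_stderr(best, n_processes, include_conductivity)
    rms = float(np.sqrt(2.0 * best.cost / len(f)))
    converged = bool(best.status > 0)
    return SpectrumFitResult(
        model=model,
        param_stderr=stderr,
        residual_rms=rms,
        converged=converged,
        n_points_used=len(f),
        condition={
            "temperature_K": spectrum.temperature_K,
            "pressure_MPa": spectrum.pressure_MPa,
            "sample_id": spectrum.sample_id,
        },
    )


def _propagate_stderr(res, n_processes: int,
                      include_conductivity: bool) -> dict[str, float | None]:
    """Parameter uncertainties from the Gauss-Newton covariance, mapped from
    the log-scale fit parameters onto the natural scale (None when the
    Jacobian is rank deficient at the solution)."""
    n, p = res.fun.size, res.x.size
    err = np.full(p, np.nan)
    if n > p:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.pinv(jtj) * (2.0 * res.cost / (n - p))
            err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    ln10 = np.log(10.0)

    def scaled(i, log_scale):
        if not np.isfinite(err[i]):
            return None
        return float(abs(10.0 ** res.x[i] * ln10 * err[i])) if log_scale \
            else float(err[i])

    out: dict[str, float | None] = {}
    for k in range(n_processes):
        out[f"delta_eps{k}"] = scaled(4 * k, True)
        out[f"tau_hn_s{k}"] = scaled(4 * k + 1, True)
        out[f"alpha{k}"] = scaled(4 * k + 2, False)
        out[f"beta{k}"] = scaled(4 * k + 3, False)
    if include_conductivity:
        out["sigma_dc"] = scaled(p - 1, True)
    return out


# ---------------------------------------------------------------------------
# shape metrics (TPS / isochronal superposition check)
# ---------------------------------------------------------------------------

def shape_metrics(
    spectrum_or_model: LossSpectrum | SpectrumModel,
    n_grid: int = 20001,
    f_range_hz: tuple[float, float] | None = None,
) -> ShapeMetrics:
    """Peak position and half-maximum widths of the normalised loss peak.

    Widths are measured on eps''/eps''_max at level 0.5, in decades of
    frequency, on a log-log interpolated curve.  The conductivity term is
    excluded when a model is supplied (peak shape of the relaxation alone).
    """
    if isinstance(spectrum_or_model, SpectrumModel):
        if f_range_hz is None:
            taus = [hn_peak_time(p) for p in spectrum_or_model.processes]
            f_c = 1.0 / (2.0 * np.pi * max(taus))
            f_range_hz = (f_c * 1e-6, f_c * 1e6)
        logf = np.linspace(np.log10(f_range_hz[0]), np.log10(f_range_hz[1]), n_grid)
        bare = SpectrumModel(processes=spectrum_or_model.processes, sigma_dc=0.0)
        logy = np.log10(evaluate_model(bare, 10.0 ** logf))
    else:
        logf = np.log10(spectrum_or_model.frequency_hz)
        y = spectrum_or_model.loss
        if np.any(y <= 0):
            raise ValueError("loss must be positive for shape analysis")
        dense = np.linspace(logf[0], logf[-1], n_grid)
        logy = np.interp(dense, logf, np.log10(y))
        logf = dense

    i_max = int(np.argmax(logy))
    if i_max == 0 or i_max == len(logy) - 1:
        raise ValueError("no interior loss maximum: spectrum is monotone in the window")
    level = logy[i_max] - np.log10(2.0)  # half maximum on the log scale

    def crossing(side: slice, reverse: bool) -> float:
        seg_y, seg_f = logy[side], logf[side]
        idx = np.nonzero(seg_y <= level)[0]
        if len(idx) == 0:
            raise ValueError("half-maximum level not reached inside the window")
        j = idx[-1] if reverse else idx[0]
        j2 = j + 1 if reverse else j - 1
        # linear interpolation in (log f, log eps'') between bracket points
        y0, y1 = seg_y[j], seg_y[j2]
        f0, f1 = seg_f[j], seg_f[j2]
        return f0 + (level - y0) * (f1 - f0) / (y1 - y0)

    left = crossing(slice(0, i_max + 1), reverse=True)
    right = crossing(slice(i_max, None), reverse=False)
    f_max = 10.0 ** logf[i_max]
    lw = logf[i_max] - left
    rw = right - logf[i_max]
    return ShapeMetrics(
        f_max_hz=float(f_max),
        fwhm_decades=float(lw + rw),
        left_halfwidth_decades=float(lw),
        right_halfwidth_decades=float(rw),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectra(path) -> list[LossSpectrum]:
    """Read loss spectra from CSV/TSV.

    Long format with columns ``frequency_hz, eps_imag[, eps_real],
    temperature_K, pressure_MPa, sample_id``; rows are grouped into one
    spectrum per (temperature_K, pressure_MPa, sample_id) condition.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"frequency_hz", "eps_imag", "temperature_K", "pressure_MPa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if "sample_id" not in df.columns:
        df["sample_id"] = ""
    df["sample_id"] = df["sample_id"].fillna("")
    out = []
    for (T, p, sid), g in df.groupby(["temperature_K", "pressure_MPa", "sample_id"],
                                     sort=True):
        g = g.sort_values("frequency_hz")
        out.append(LossSpectrum(
            frequency_hz=g["frequency_hz"].to_numpy(),
            loss=g["eps_imag"].to_numpy(),
            storage=g["eps_real"].to_numpy() if "eps_real" in g.columns else None,
            temperature_K=float(T), pressure_MPa=float(p), sample_id=str(sid),
        ))
    return out


def write_spectra(spectra: Sequence[LossSpectrum], path) -> None:
    frames = []
    for s in spectra:
        frames.append(pd.DataFrame({
            "frequency_hz": s.frequency_hz,
            "eps_imag": s.loss,
            "temperature_K": s.temperature_K,
            "pressure_MPa": s.pressure_MPa,
            "sample_id": s.sample_id,
        }))
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def write_fit_results(results: Sequence[SpectrumFitResult], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_record() for r in results], fh, indent=1)
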