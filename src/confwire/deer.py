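"""DEER (double electron-electron resonance) dipolar signal modeling and fitting.

The powder-averaged dipolar kernel is

    K(t, r) = ∫₀¹ cos[ω_dd(r) (1 − 3x²) t] dx,   ω_dd(r) = 2π·52.04 MHz·nm³ / r³,

with the standard nitroxide (free-electron g) dipolar constant; K(0, r) = 1.
The kernel is evaluated through Fresnel integrals, with direct numerical
quadrature available as an independent check.

The four-pulse signal model is a 3-D homogeneous (exponential) background
times the modulated form factor,

    V4(t) = exp(−k_bg·|t|) · [1 − λ + λ·∫ P(r) K(t, r) dr],

with modulation depth λ and a single-Gaussian distance distribution P(r)
(truncated to r > 0 and renormalized). The five-pulse protocol gains
sensitivity but carries an artifact echo resembling a time-shifted
four-pulse trace; it is modeled as

    V5(t) ∝ (1 − η)·V4(t) + η·V4(t − t_shift),

renormalized to V5(0) = 1. Joint fitting of a four- and five-pulse pair
shares (r0, σ) across both signals, which pins down the artifact
subtraction; confidence bands on P(r) come from first-order (delta-method)
error propagation of the fitted-parameter covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

# Dipolar frequency constant: nu_dd = 52.04 MHz at r = 1 nm (free-electron g).
NU_DIP_MHZ_NM3 = 52.04

FOUR_PULSE = "four-pulse"
FIVE_PULSE = "five-pulse"


@dataclass(frozen=True)
class GaussianPr:
    """Single-Gaussian distance distribution, truncated to r > 0."""

    r0: float  # mean spin-spin distance, Å
    sigma: float  # SD, Å

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.sigma <= 0:
            raise ValueError("r0 and sigma must be positive")

    def density(self, r: np.ndarray | float) -> np.ndarray | float:
        """Truncated-renormalized normal density at r (Å⁻¹)."""
        r = np.asarray(r, dtype=float)
        norm_const = stats.norm.cdf(self.r0 / self.sigma)
        out = np.where(r > 0, stats.norm.pdf(r, self.r0, self.sigma) / norm_const, 0.0)
        return out if out.ndim else float(out)

    def quadrature_grid(self, n: int = 201, width: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
        """(r values, normalized weights) for discretizing ∫P(r)K(t,r)dr."""
        lo = max(self.r0 - width * self.sigma, 1e-2)
        hi = self.r0 + width * self.sigma
        r = np.linspace(lo, hi, n)
        w = self.density(r)
        w = w / w.sum()
        return r, w


@dataclass
class DipolarSignal:
    """A dipolar evolution trace: time axis (µs) and real amplitudes, V(0)=1."""

    t: np.ndarray  # µs, strictly increasing; may include negative pre-zero points
    v: np.ndarray
    protocol: str = FOUR_PULSE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and V must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("amplitudes must be finite")
        if self.protocol not in (FOUR_PULSE, FIVE_PULSE):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass(frozen=True)
class DeerModel:
    """Forward-model parameters for one protocol.

    ``eta`` and ``t_shift`` describe the five-pulse artifact (amplitude
    fraction and time displacement); both are inert for four-pulse traces.
    """

    pr: GaussianPr
    lam: float = 0.3  # modulation depth, (0, 1)
    k_bg: float = 0.05  # background decay rate, µs⁻¹
    eta: float = 0.0  # artifact amplitude, [0, 1)
    t_shift: float = 0.0  # artifact time shift, µs

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("lam must be in [0, 1)")
        if self.k_bg < 0:
            raise ValueError("k_bg must be non-negative")
        if not (0.0 <= self.eta < 1.0):
            raise ValueError("eta must be in [0, 1)")


@dataclass
class DeerFitResult:
    """Joint-fit optimum: parameters, covariance, residuals, P(r) bands."""

    model: DeerModel  # four-pulse parameters (shared r0, sigma)
    model5: DeerModel | None  # five-pulse parameters, if a 5-pulse trace was fit
    param_names: tuple[str, ...]
    theta: np.ndarray
    covariance: np.ndarray
    residual_rms: float
    n_points: int
    bands: dict | None = None


# ---------------------------------------------------------------------------
# Kernel


def omega_dd(r: np.ndarray | float) -> np.ndarray | float:
    """Dipolar angular frequency in rad/µs for r in Å."""
    r_nm = np.asarray(r, dtype=float) / 10.0
    if np.any(r_nm <= 0):
        raise ValueError("r must be positive")
    out = 2.0 * np.pi * NU_DIP_MHZ_NM3 / r_nm**3
    return out if out.ndim else float(out)


def dipolar_kernel(t: np.ndarray | float, r: np.ndarray | float) -> np.ndarray:
    """Powder-averaged dipolar kernel K(t, r) via the Fresnel-integral route.

    Broadcasts ``t`` (µs) against ``r`` (Å); K(0, r) = 1 exactly.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w = np.atleast_1d(np.asarray(omega_dd(r), dtype=float))
    wt = np.abs(t[..., None] * w)  # (..., n_r), even in t
    out = np.ones_like(wt)
    nz = wt > 1e-12
    a = 3.0 * wt[nz]
    k = np.sqrt(2.0 * a / np.pi)
    s_f, c_f = special.fresnel(k)
    out[nz] = np.sqrt(np.pi / (2.0 * a)) * (np.cos(wt[nz]) * c_f + np.sin(wt[nz]) * s_f)
    return out


def dipolar_kernel_quadrature(t: float, r: float, n: int = 20001) -> float:
    """Direct numerical quadrature of the defining kernel integral.

    Independent slow route (composite Simpson over the powder angle
    variable); used to validate the Fresnel evaluation.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    from scipy.integrate import simpson

    x = np.linspace(0.0, 1.0, n)
    integrand = np.cos(omega_dd(r) * (1.0 - 3.0 * x**2) * t)
    return float(simpson(integrand, x=x))


# ---------------------------------------------------------------------------
# Forward models


def form_factor(pr: GaussianPr, t: np.ndarray, n_r: int = 91) -> np.ndarray:
    """Distance-averaged modulation ∫P(r)K(t,r)dr on a discretized grid."""
    r, w = pr.quadrature_grid(n=n_r)
    return dipolar_kernel(t, r) @ w


def _v4_unnormalized(model: DeerModel, t: np.ndarray, n_r: int = 91) -> np.ndarray:
    ff = form_factor(model.pr, t, n_r=n_r)
    return np.exp(-model.k_bg * np.abs(t)) * (1.0 - model.lam + model.lam * ff)


def simulate_signal(
    model: DeerModel,
    t: np.ndarray,
    protocol: str = FOUR_PULSE,
    n_r: int = 91,
) -> DipolarSignal:
    """Evaluate the forward model on a time axis, normalized to V(0) = 1."""
    t = np.asarray(t, dtype=float)
    if protocol == FOUR_PULSE:
        v = _v4_unnormalized(model, t, n_r=n_r)  # equals 1 at t = 0 by construction
        return DipolarSignal(t, v, FOUR_PULSE)
    if protocol == FIVE_PULSE:
        def u(tt: np.ndarray) -> np.ndarray:
            return (1.0 - model.eta) * _v4_unnormalized(model, tt, n_r=n_r) + model.eta * _v4_unnormalized(
                model, tt - model.t_shift, n_r=n_r
            )

        v = u(t) / u(np.zeros(1))[0]
        return DipolarSignal(t, v, FIVE_PULSE)
    raise ValueError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# I/O


def read_signal(path: str, protocol: str = FOUR_PULSE) -> DipolarSignal:
    """Read a two-column (t [µs], V) text trace; '#' lines are comments.

    Amplitudes are taken as-is: traces are expected to be roughly
    normalized (V(0) ≈ 1), and the fit carries a free amplitude scale, so
    an exact normalization is not required.
    """
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"expected two columns (t, V) in {path}")
    return DipolarSignal(data[:, 0], data[:, 1], protocol)


def write_signal(signal: DipolarSignal, path: str, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# protocol: {signal.protocol}\n# t_us\tV\n")
        for ti, vi in zip(signal.t, signal.v):
            fh.write(f"{ti:.6f}\t{vi:.8f}\n")


# ---------------------------------------------------------------------------
# Joint fitting

_BOUNDS = {
    "r0": (10.0, 120.0),
    "sigma": (0.05, 30.0),
    "lam4": (1e-4, 0.999),
    "k4": (0.0, 5.0),
    "a4": (0.5, 2.0),
    "lam5": (1e-4, 0.999),
    "k5": (0.0, 5.0),
    "eta": (0.0, 0.95),
    "t_shift": (0.0, 5.0),
    "a5": (0.5, 2.0),
}


def _theta_to_models(
    names: Sequence[str], theta: np.ndarray, fixed: dict[str, float]
) -> tuple[DeerModel, DeerModel | None]:
    p = dict(fixed)
    p.update(dict(zip(names, theta)))
    pr = GaussianPr(p["r0"], p["sigma"])
    m4 = DeerModel(pr, lam=p["lam4"], k_bg=p["k4"])
    m5 = None
    if "lam5" in p:
        m5 = DeerModel(pr, lam=p["lam5"], k_bg=p["k5"], eta=p["eta"], t_shift=p["t_shift"])
    return m4, m5


def fit_joint(
    signal4: DipolarSignal,
    signal5: DipolarSignal | None = None,
    init: DeerModel | None = None,
    fixed: dict[str, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    n_r: int = 91,
    band_r_axis: np.ndarray | None = None,
) -> DeerFitResult:
    """Simultaneous nonlinear least-squares fit of four-/five-pulse traces.

    The Gaussian distribution (r0, σ) is shared across both signals; each
    signal has its own modulation depth and background rate; the five-pulse
    trace additionally has artifact amplitude ``eta`` and shift ``t_shift``.
    ``fixed`` maps parameter names (r0, sigma, lam4, k4, lam5, k5, eta,
    t_shift) to frozen values. Trust-region least squares with ``n_starts``
    jittered restarts (seeded) guards against local minima; the parameter
    covariance comes from the Jacobian at the optimum and the residual
    variance. Non-convergence raises ``RuntimeError`` with diagnostics.

    The fit is invariant to a uniform rescaling of V: each trace carries a
    free amplitude-scale nuisance parameter (``a4``, ``a5``), so the V(0)=1
    normalization of the input need not be exact.
    """
    fixed = dict(fixed or {})
    # default start: mid-range nitroxide distance, moderate width
    init = init or DeerModel(GaussianPr(35.0, 3.0), lam=0.3, k_bg=0.05, eta=0.2, t_shift=0.0)
    all_names = ["r0", "sigma", "lam4", "k4", "a4"]
    init_vals = {
        "r0": init.pr.r0,
        "sigma": init.pr.sigma,
        "lam4": init.lam,
        "k4": init.k_bg,
        "a4": 1.0,
    }
    if signal5 is not None:
        all_names += ["lam5", "k5", "eta", "t_shift", "a5"]
        t_shift0 = init.t_shift if init.t_shift != 0.0 else float(signal5.t[-1]) * 0.85
        init_vals.update(
            {"lam5": init.lam, "k5": init.k_bg, "eta": max(init.eta, 0.05), "t_shift": t_shift0, "a5": 1.0}
        )
    free = [n for n in all_names if n not in fixed]
    if not free:
        raise ValueError("all parameters are fixed; nothing to fit")
    x0 = np.array([init_vals[n] for n in free])
    lo = np.array([_BOUNDS[n][0] for n in free])
    hi = np.array([_BOUNDS[n][1] for n in free])
    x0 = np.clip(x0, lo, hi)

    sig4 = DipolarSignal(signal4.t, signal4.v / signal4.v.max(), signal4.protocol)
    sig5 = None
    if signal5 is not None:
        sig5 = DipolarSignal(signal5.t, signal5.v / signal5.v.max(), signal5.protocol)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = dict(fixed)
        p.update(dict(zip(free, x)))
        m4, m5 = _theta_to_models(free, x, fixed)
        res = [p["a4"] * simulate_signal(m4, sig4.t, FOUR_PULSE, n_r=n_r).v - sig4.v]
        if sig5 is not None:
            res.append(p["a5"] * simulate_signal(m5, sig5.t, FIVE_PULSE, n_r=n_r).v - sig5.v)
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(n_starts, 1)):
        if start == 0:
            x_start = x0
        else:
            jitter = rng.uniform(0.85, 1.15, size=x0.size)
            x_start = np.clip(x0 * jitter + rng.normal(0, 0.01, size=x0.size), lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, x_start, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, x_scale="jac",
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("start %d failed: %s", start, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        detail = "no start converged" if best is None else (
            f"final residual {np.sqrt(2 * best.cost):.3g} after {best.nfev} evaluations"
        )
        raise RuntimeError(f"joint DEER fit did not converge: {detail}")

    n_pts = best.fun.size
    n_par = len(free)
    dof = max(n_pts - n_par, 1)
    s2 = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    try:
        cov_free = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        logger.warning("singular Jacobian; covariance from pseudo-inverse")
        cov_free = s2 * np.linalg.pinv(jtj)
    # embed into the full parameter ordering (fixed params have zero variance)
    cov = np.zeros((len(all_names), len(all_names)))
    pos = {n: i for i, n in enumerate(all_names)}
    for i, ni in enumerate(free):
        for j, nj in enumerate(free):
            cov[pos[ni], pos[nj]] = cov_free[i, j]
    theta_full = np.array([dict(zip(free, best.x)).get(n, fixed.get(n, init_vals[n])) for n in all_names])
    m4, m5 = _theta_to_models(free, best.x, fixed)
    result = DeerFitResult(
        model=m4,
        model5=m5,
        param_names=tuple(all_names),
        theta=theta_full,
        covariance=cov,
        residual_rms=float(np.sqrt(np.mean(best.fun**2))),
        n_points=n_pts,
    )
    if band_r_axis is not None:
        result.bands = delta_method_bands(result, band_r_axis)
    return result


def delta_method_bands(
    fit: DeerFitResult,
    r_axis: np.ndarray,
    level: float = 0.95,
) -> dict:
    """Pointwise confidence bands on P(r) by first-order error propagation.

    For each r, Var[P(r)] = ∇θP · Cov(r0, σ) · ∇θPᵀ with a numerical
    gradient; bands are the point estimate ± z(level)·SE, floored at zero
    (so their shape can be non-Gaussian even for a Gaussian P). Returns a
    dict with keys ``r``, ``p``, ``lower``, ``upper``, ``level``.
    """
    r_axis = np.asarray(r_axis, dtype=float)
    i_r0 = fit.param_names.index("r0")
    i_sg = fit.param_names.index("sigma")
    cov2 = fit.covariance[np.ix_([i_r0, i_sg], [i_r0, i_sg])]
    pr = fit.model.pr
    p = np.asarray(pr.density(r_axis))

    def density(r0: float, sg: float) -> np.ndarray:
        return np.asarray(GaussianPr(r0, sg).density(r_axis))

    h_r0 = max(1e-5 * pr.r0, 1e-7)
    h_sg = max(1e-5 * pr.sigma, 1e-7)
    g_r0 = (density(pr.r0 + h_r0, pr.sigma) - density(pr.r0 - h_r0, pr.sigma)) / (2 * h_r0)
    g_sg = (density(pr.r0, pr.sigma + h_sg) - density(pr.r0, pr.sigma - h_sg)) / (2 * h_sg)
    grad = np.stack([g_r0, g_sg], axis=1)  # (n_r, 2)
    var = np.einsum("ri,ij,rj->r", grad, cov2, grad)
    se = np.sqrt(np.maximum(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lower = np.maximum(p - z * se, 0.0)
    upper = p + z * se
    return {"r": r_axis, "p": p, "lower": lower, "upper": upper, "level": level}
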