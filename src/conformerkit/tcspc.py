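"""Ensemble/sub-ensemble TCSPC decay analysis for FRET distance distributions.

The donor fluorescence decay in the presence of an acceptor factorizes, under
the quasi-static homogeneous approximation, into the donor-only reference and
the FRET-induced donor decay

    f_DD(DA)(t) = f_DD(D0)(t) * eps_D(t),
    eps_D(t) = (1 - x_DOnly) * int p(R) exp(-t k0 (R0/R)^6) dR + x_DOnly,

where ``p(R)`` is the donor-acceptor distance distribution (here a one- or
two-component Gaussian mixture, or any tabulated density), ``R0`` the Forster
radius, ``k0 = 1/tau0`` the unquenched donor rate and ``x_DOnly`` the
FRET-inactive fraction.  The normalization is chosen so that ``eps_D(0) = 1``.
The FRET-sensitized acceptor decay is the convolution of the quenched donor
decay with the acceptor reference.  Measured histograms are modeled by
iterative reconvolution,

    g(t) = N_F * f(t) (x) IRF(t) + N_BG * IRF(t) + bg,

optionally multiplied by a smoothed room-light linearization curve.

The module also provides maximum-entropy (MEM) reconstruction of ``p(R)``
from a decay, burst-averaged lifetime moments, and static/dynamic FRET-lines
relating mean donor lifetime and FRET efficiency.

Units: times in ns, distances in angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import optimize, signal, stats

from .labels import DistanceDistribution

__all__ = [
    "DecayCurve",
    "FluorophoreReference",
    "GaussianMixtureDistance",
    "FretLine",
    "fret_induced_donor_decay",
    "donor_decay_with_fret",
    "acceptor_sensitized_decay",
    "instrument_model",
    "simulate_decay",
    "fit_decays",
    "support_plane_interval",
    "mem_reconstruct",
    "lifetime_moments",
    "static_fret_line",
    "dynamic_fret_line",
    "default_distance_grid",
]


def default_distance_grid() -> np.ndarray:
    """Distance quadrature grid: 0.5 A steps over [10, 150] A."""
    return np.arange(10.0, 150.0001, 0.5)


@dataclass
class DecayCurve:
    """TCSPC histogram on a uniform time grid (channel width in ns)."""

    t: np.ndarray
    counts: np.ndarray
    irf: np.ndarray = None
    linearization: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.counts = np.asarray(self.counts, float)
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.irf is not None:
            self.irf = np.asarray(self.irf, float)
            if self.irf.shape != self.t.shape:
                raise ValueError("IRF must share the counts grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def load(cls, path):
        """Read 2-4 column ASCII: time, counts[, IRF[, linearization]]."""
        data = np.loadtxt(path)
        irf = data[:, 2] if data.shape[1] > 2 else None
        lin = data[:, 3] if data.shape[1] > 3 else None
        return cls(t=data[:, 0], counts=data[:, 1], irf=irf, linearization=lin)

    def save(self, path):
        cols = [self.t, self.counts]
        if self.irf is not None:
            cols.append(self.irf)
        if self.linearization is not None:
            cols.append(self.linearization)
        np.savetxt(path, np.column_stack(cols), header="t_ns counts [irf] [lin]")

    def fit_range(self, fraction: float = 0.999) -> slice:
        """Channel range covering the IRF and ``fraction`` of the fluorescence."""
        csum = np.cumsum(self.counts)
        stop = int(np.searchsorted(csum, fraction * csum[-1])) + 1
        return slice(0, min(stop, len(self.t)))


@dataclass
class FluorophoreReference:
    """Multi-exponential donor or acceptor reference decay."""

    fractions: np.ndarray
    lifetimes: np.ndarray
    role: str = "donor"

    def __post_init__(self):
        self.fractions = np.atleast_1d(np.asarray(self.fractions, float))
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, float))
        if np.any(self.fractions < 0) or not np.isclose(self.fractions.sum(), 1.0):
            raise ValueError("species fractions must be non-negative and sum to 1")
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")

    def decay(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return np.sum(
            self.fractions[:, None] * np.exp(-t[None, :] / self.lifetimes[:, None]),
            axis=0,
        )

    @property
    def species_mean_lifetime(self) -> float:
        return float(self.fractions @ self.lifetimes)


@dataclass
class GaussianMixtureDistance:
    """Two-Gaussian donor-acceptor distance model with FRET-inactive fraction.

    Component widths ``w`` follow the ``exp(-2((R - mean)/w)^2)`` convention
    (sigma = w/2).  ``tau0`` is the unquenched donor lifetime (k0 = 1/tau0).
    """

    r1: float = 45.0
    r2: float = 60.0
    w: float = 12.0
    x1: float = 0.61
    x_donly: float = 0.0
    R0: float = 52.0
    tau0: float = 4.0

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("width must be positive")
        if not (0 <= self.x1 <= 1 and 0 <= self.x_donly <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("distances must be positive")

    def density(self, r_grid: np.ndarray | None = None) -> DistanceDistribution:
        r = default_distance_grid() if r_grid is None else np.asarray(r_grid, float)
        return DistanceDistribution.gaussian_mixture(
            [self.r1, self.r2], self.w, [self.x1, 1.0 - self.x1], r
        )


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def fret_induced_donor_decay(
    dist: "GaussianMixtureDistance | DistanceDistribution",
    t: np.ndarray,
    R0: float | None = None,
    tau0: float | None = None,
    x_donly: float | None = None,
) -> np.ndarray:
    """FRET-induced donor decay eps_D(t) for a distance distribution.

    ``eps_D(0) = 1``, eps_D is non-increasing and tends to ``x_DOnly`` at long
    times.  For a :class:`GaussianMixtureDistance`, ``R0``/``tau0``/``x_donly``
    default to the model's own values.
    """
    t = np.asarray(t, float)
    if isinstance(dist, GaussianMixtureDistance):
        R0 = dist.R0 if R0 is None else R0
        tau0 = dist.tau0 if tau0 is None else tau0
        x_donly = dist.x_donly if x_donly is None else x_donly
        dd = dist.density()
    else:
        if R0 is None or tau0 is None:
            raise ValueError("R0 and tau0 are required for a tabulated density")
        x_donly = 0.0 if x_donly is None else x_donly
        dd = dist
    if np.any(dd.p < 0):
        raise ValueError("distance density must be non-negative")
    k0 = 1.0 / tau0
    kret = k0 * (R0 / dd.r) ** 6
    w = dd.p / np.trapezoid(dd.p, dd.r)
    decay = np.trapezoid(
        w[None, :] * np.exp(-np.outer(t, kret)), dd.r, axis=1
    )
    return (1.0 - x_donly) * decay + x_donly


def donor_decay_with_fret(
    ref: FluorophoreReference, eps: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Quenched donor decay f_DD(DA) = f_DD(D0) * eps_D (pointwise)."""
    eps = np.asarray(eps, float)
    t = np.asarray(t, float)
    if eps.shape != t.shape:
        raise ValueError("eps_D and time grid must share their shape")
    return ref.decay(t) * eps


def acceptor_sensitized_decay(
    donor_fret: np.ndarray, acceptor: np.ndarray, dt: float
) -> np.ndarray:
    """FRET-sensitized acceptor decay: causal linear convolution, dt-scaled."""
    donor_fret = np.asarray(donor_fret, float)
    acceptor = np.asarray(acceptor, float)
    if donor_fret.shape != acceptor.shape:
        raise ValueError("curves must share their time grid")
    full = signal.fftconvolve(donor_fret, acceptor)
    return full[: len(donor_fret)] * dt


def instrument_model(
    f: np.ndarray,
    irf: np.ndarray,
    n_f: float,
    n_bg: float = 0.0,
    bg: float = 0.0,
    linearization: np.ndarray = None,
    irf_shift: float = 0.0,
) -> np.ndarray:
    """Measured-counts model g = N_F f(x)IRF + N_BG IRF + bg.

    The IRF is normalized to unit sum before reconvolution; ``irf_shift`` is a
    sub-channel time shift (in channels) applied by linear interpolation; the
    optional multiplicative linearization curve is applied last.
    """
    f = np.asarray(f, float)
    irf = np.asarray(irf, float)
    total = irf.sum()
    if total <= 0:
        raise ValueError("IRF must have positive total intensity")
    irf_n = irf / total
    if irf_shift != 0.0:
        x = np.arange(len(irf_n), dtype=float)
        irf_n = np.interp(x - irf_shift, x, irf_n, left=0.0, right=0.0)
    conv = signal.fftconvolve(f, irf_n)[: len(f)]
    g = n_f * conv + n_bg * irf_n + bg
    if linearization is not None:
        g = g * np.asarray(linearization, float)
    return g


def simulate_decay(
    model: GaussianMixtureDistance,
    donor_ref: FluorophoreReference,
    t: np.ndarray,
    irf: np.ndarray,
    total_counts: float = 2e7,
    bg_fraction: float = 1e-4,
    seed: int | None = None,
) -> DecayCurve:
    """Poisson-noise synthetic donor decay at a given photon budget."""
    t = np.asarray(t, float)
    eps = fret_induced_donor_decay(model, t)
    f = donor_decay_with_fret(donor_ref, eps, t)
    shape = instrument_model(f, irf, 1.0)
    bg_per_channel = total_counts * bg_fraction / len(t)
    n_f = (total_counts - bg_per_channel * len(t)) / shape.sum()
    expected = n_f * shape + bg_per_channel
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return DecayCurve(t=t, counts=counts, irf=np.asarray(irf, float))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_SHAREABLE = ("r1", "r2", "w", "x1", "x_donly")


def _decay_residuals(params, curves, donor_refs, bgs, windows, r_grid):
    res = []
    for i, curve in enumerate(curves):
        p = {
            name: (
                params[name].value
                if name in params
                else params[f"d{i}_{name}"].value
            )
            for name in _SHAREABLE
        }
        model = GaussianMixtureDistance(
            r1=p["r1"], r2=p["r2"], w=p["w"], x1=p["x1"], x_donly=p["x_donly"]
        )
        eps = fret_induced_donor_decay(model, curve.t)
        f = donor_decay_with_fret(donor_refs[i], eps, curve.t)
        shape = instrument_model(f, curve.irf, 1.0)
        win = windows[i]
        bg = bgs[i]
        data = curve.counts[win]
        m = shape[win]
        # photon-count scale is a linear nuisance -> analytic optimum
        n_f = max((data.sum() - bg * len(data)) / m.sum(), 0.0)
        g = n_f * m + bg
        res.append((g - data) / np.sqrt(np.maximum(data, 1.0)))
    return np.concatenate(res)


def fit_decays(
    curves: list[DecayCurve],
    donor_refs: "FluorophoreReference | list[FluorophoreReference]",
    initial: GaussianMixtureDistance | None = None,
    shared: tuple[str, ...] = (),
    backgrounds: "float | list[float]" = 0.0,
    vary: tuple[str, ...] = ("r1", "r2", "x1"),
    fit_fraction: float = 0.999,
) -> lmfit.minimizer.MinimizerResult:
    """Joint (global) fit of one or more donor decays.

    Parameters named in ``shared`` are optimized as one global value across
    all curves; the rest are per-curve (``d{i}_`` prefix).  Poisson weights
    ``sqrt(max(counts, 1))`` are used and each curve's fit window covers the
    IRF and ``fit_fraction`` of the fluorescence.  The photon-count scale N_F
    is profiled out analytically per evaluation.

    Returns the lmfit result; ``result.params`` carries values and standard
    errors, ``result.redchi`` the reduced chi-square.
    """
    if isinstance(donor_refs, FluorophoreReference):
        donor_refs = [donor_refs] * len(curves)
    if np.isscalar(backgrounds):
        backgrounds = [float(backgrounds)] * len(curves)
    initial = initial or GaussianMixtureDistance()
    windows = [c.fit_range(fit_fraction) for c in curves]
    bounds = {
        "r1": (20.0, 120.0),
        "r2": (20.0, 120.0),
        "w": (3.0, 40.0),
        "x1": (0.0, 1.0),
        "x_donly": (0.0, 1.0),
    }
    params = lmfit.Parameters()
    for name in _SHAREABLE:
        lo, hi = bounds[name]
        value = getattr(initial, name)
        if name in shared:
            params.add(name, value=value, min=lo, max=hi, vary=name in vary)
        else:
            for i in range(len(curves)):
                params.add(f"d{i}_{name}", value=value, min=lo, max=hi, vary=name in vary)
    grid = default_distance_grid()
    out = lmfit.minimize(
        _decay_residuals,
        params,
        args=(curves, donor_refs, backgrounds, windows, grid),
        method="leastsq",
    )
    return out


def support_plane_interval(
    result,
    residual_args: tuple,
    param_name: str,
    values: np.ndarray,
    confidence: float = 0.95,
) -> tuple[float, float, np.ndarray]:
    """1D support-plane (profile chi-square) interval for one parameter.

    The parameter is stepped over ``values`` and all other free parameters are
    re-optimized; the interval bounds are where the chi-square ratio crosses
    the F-test threshold ``1 + F_ppf(confidence; 1, dof)/dof``.
    """
    chi2 = np.empty(len(values))
    for j, v in enumerate(values):
        params = result.params.copy()
        params[param_name].set(value=float(v), vary=False)
        sub = lmfit.minimize(_decay_residuals, params, args=residual_args, method="leastsq")
        chi2[j] = sub.chisqr
    dof = result.nfree
    threshold = result.chisqr * (1.0 + stats.f.ppf(confidence, 1, dof) / dof)
    ok = chi2 <= threshold
    if not ok.any():
        raise RuntimeError("no profile point below the F-test threshold")
    return float(values[ok].min()), float(values[ok].max()), chi2


# ---------------------------------------------------------------------------
# maximum entropy reconstruction
# ---------------------------------------------------------------------------

def mem_reconstruct(
    curve: DecayCurve,
    donor_ref: FluorophoreReference,
    r_grid: np.ndarray | None = None,
    alphas: np.ndarray | None = None,
    R0: float = 52.0,
    tau0: float = 4.0,
    x_donly: float = 0.0,
    bg: float = 0.0,
    fit_fraction: float = 0.999,
) -> dict:
    """Maximum-entropy reconstruction of p(R_DA) from a donor decay.

    Maximizes ``alpha * S - chi^2/2`` over non-negative ``p`` on ``r_grid``,
    with entropy ``S = -sum p ln(p/m)`` against a flat prior ``m``; the photon
    scale is profiled analytically.  Returns the reconstruction for every
    alpha plus an L-curve (log entropy magnitude vs log misfit) with a
    maximum-curvature corner.
    """
    if alphas is None:
        alphas = np.logspace(-2, 4, 25)
    alphas = np.asarray(alphas, float)
    if np.any(alphas <= 0):
        raise ValueError("regularization strengths must be positive")
    r = default_distance_grid() if r_grid is None else np.asarray(r_grid, float)
    dr = r[1] - r[0]
    t = curve.t
    win = curve.fit_range(fit_fraction)
    data = curve.counts[win]
    sigma2 = np.maximum(data, 1.0)
    k0 = 1.0 / tau0
    kret = k0 * (R0 / r) ** 6
    base = donor_ref.decay(t)
    # forward matrix including optional IRF reconvolution
    A = base[:, None] * np.exp(-np.outer(t, kret)) * dr
    offset = base * x_donly
    if curve.irf is not None:
        irf_n = curve.irf / curve.irf.sum()
        A = np.apply_along_axis(
            lambda col: signal.fftconvolve(col, irf_n)[: len(t)], 0, A
        )
        offset = signal.fftconvolve(offset, irf_n)[: len(t)]
    A = A[win]
    offset = offset[win]

    m_prior = 1.0 / (len(r) * dr)  # flat prior, unit integral

    col_sum = A.sum(axis=0)

    def neg_q(u, alpha):
        p = np.exp(np.clip(u, -500.0, 50.0))  # guard against line-search overflow
        shape = A @ p + offset
        total = shape.sum()
        n_f = max(float(data.sum() / total), 1e-12)
        model = n_f * shape + bg
        rres = (model - data) / np.sqrt(sigma2)
        chi2 = float(rres @ rres)
        s_ent = -float(np.sum(p * np.log(p / m_prior)) * dr)
        # d chi2 / dp including the profiled photon-scale chain term
        rs = rres / np.sqrt(sigma2)
        grad_chi2_p = 2.0 * n_f * (A.T @ rs - float(rs @ shape) / total * col_sum)
        grad_s_p = -(np.log(p / m_prior) + 1.0) * dr
        grad_u = p * (0.5 * grad_chi2_p - alpha * grad_s_p)
        return 0.5 * chi2 - alpha * s_ent, grad_u

    results, misfits, entropies = [], [], []
    alphas_desc = np.sort(alphas)[::-1]
    u0 = np.full(len(r), np.log(m_prior))
    for alpha in alphas_desc:  # warm-start from smooth to sharp
        res = optimize.minimize(
            neg_q, u0, args=(alpha,), jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        u0 = res.x
        p_raw = np.exp(np.clip(res.x, -500.0, 50.0))
        p = p_raw / np.trapezoid(p_raw, r)
        shape = A @ p_raw + offset
        n_f = float(data.sum() / shape.sum())
        rres = (n_f * shape + bg - data) / np.sqrt(sigma2)
        misfits.append(float(rres @ rres))
        entropies.append(
            float(abs(np.sum(p_raw * np.log(p_raw / m_prior)) * dr)) + 1e-300
        )
        results.append(DistanceDistribution(r=r, p=p))
    x = np.log10(misfits)
    y = np.log10(entropies)
    la = np.log10(alphas_desc)
    dx, dy = np.gradient(x, la), np.gradient(y, la)
    ddx, ddy = np.gradient(dx, la), np.gradient(dy, la)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = (dx * ddy - dy * ddx) / np.where(denom > 0, denom, np.inf)
    idx = int(np.nanargmax(np.abs(curvature[1:-1])) + 1)
    return {
        "alphas": alphas_desc,
        "reconstructions": results,
        "log_misfit": x,
        "log_entropy": y,
        "corner_index": idx,
        "corner_alpha": float(alphas_desc[idx]),
        "best": results[idx],
    }


# ---------------------------------------------------------------------------
# moments and FRET-lines
# ---------------------------------------------------------------------------

def lifetime_moments(E: float, tau_d0_x: float, tau_da_F: float) -> dict:
    """Burst-averaged lifetime moments from E and the two mean lifetimes.

    ``<tau>_x = (1 - E) <tau_D(0)>_x`` and
    ``var(tau) = <tau>_F <tau>_x - <tau>_x^2``.
    """
    if not 0.0 <= E <= 1.0:
        raise ValueError("E must lie in [0, 1]")
    if tau_d0_x <= 0 or tau_da_F <= 0:
        raise ValueError("lifetimes must be positive")
    tau_x = (1.0 - E) * tau_d0_x
    var = tau_da_F * tau_x - tau_x**2
    return {"tau_x": tau_x, "var": var}


@dataclass
class FretLine:
    """Parametric (⟨tau_D(A)⟩_F, E) reference curve."""

    tau_f: np.ndarray
    efficiency: np.ndarray
    kind: str  # "static" | "dynamic"
    states: tuple = ()


def _state_integrals(donor_ref, kret_grid, p_weights):
    """(I0, I1) = (int f, int t f) for a donor quenched by a rate mixture."""
    x, tau = donor_ref.fractions, donor_ref.lifetimes
    rates = 1.0 / tau[None, :] + kret_grid[:, None]  # (R, i)
    I0 = float(np.sum(p_weights[:, None] * x[None, :] / rates))
    I1 = float(np.sum(p_weights[:, None] * x[None, :] / rates**2))
    return I0, I1


def _state_point(donor_ref, R0, tau0, distance, width=None):
    k0 = 1.0 / tau0
    if width is None:
        kret = np.array([k0 * (R0 / distance) ** 6])
        w = np.array([1.0])
    else:
        r = default_distance_grid()
        p = np.exp(-2.0 * ((r - distance) / width) ** 2)
        w = p / p.sum()
        kret = k0 * (R0 / r) ** 6
    I0, I1 = _state_integrals(donor_ref, kret, w)
    I0_ref = float(np.sum(donor_ref.fractions * donor_ref.lifetimes))
    E = 1.0 - I0 / I0_ref
    tau_f = I1 / I0
    return E, tau_f, (I0, I1)


def static_fret_line(
    donor_ref: FluorophoreReference,
    R0: float = 52.0,
    tau0: float = 4.0,
    distances: np.ndarray | None = None,
    width: float | None = None,
) -> FretLine:
    """Static FRET-line: (⟨tau⟩_F, E) parametrized by the DA distance.

    For an ideal single-exponential donor the line obeys
    ``E = 1 - ⟨tau⟩_F / tau0``.  ``width`` switches from delta-distance states
    to Gaussian-distributed states.
    """
    if distances is None:
        distances = np.linspace(0.3 * R0, 2.5 * R0, 200)
    E = np.empty(len(distances))
    tau_f = np.empty(len(distances))
    for i, d in enumerate(distances):
        E[i], tau_f[i], _ = _state_point(donor_ref, R0, tau0, d, width)
    return FretLine(tau_f=tau_f, efficiency=E, kind="static", states=tuple(distances[[0, -1]]))


def dynamic_fret_line(
    donor_ref: FluorophoreReference,
    state1: float,
    state2: float,
    R0: float = 52.0,
    tau0: float = 4.0,
    width: float | None = None,
    n_points: int = 101,
) -> FretLine:
    """Dynamic FRET-line: species mixing between two fixed distance states.

    Molecular mixing fraction xi runs from 0 to 1; photon averaging makes the
    curve bow away from the static line between its endpoints, which coincide
    with the two states' static-line points.
    """
    if state1 == state2:
        raise ValueError("dynamic line requires two distinct states")
    E1, tf1, (I0_1, I1_1) = _state_point(donor_ref, R0, tau0, state1, width)
    E2, tf2, (I0_2, I1_2) = _state_point(donor_ref, R0, tau0, state2, width)
    I0_ref = float(np.sum(donor_ref.fractions * donor_ref.lifetimes))
    xi = np.linspace(0.0, 1.0, n_points)
    I0 = xi * I0_1 + (1 - xi) * I0_2
    I1 = xi * I1_1 + (1 - xi) * I1_2
    E = 1.0 - I0 / I0_ref
    tau_f = I1 / I0
    return FretLine(tau_f=tau_f, efficiency=E, kind="dynamic", states=(state1, state2))
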