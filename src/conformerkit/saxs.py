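"""Small-angle X-ray scattering: forward models, reduction and model scoring.

Coarse bead models are scored against experimental curves through the Debye
formula

    I(q) = sum_ij b_i b_j sin(q r_ij) / (q r_ij),

with Guinier/Kratky utilities, concentration-series extrapolation to the
form factor at infinite dilution, the Percus-Yevick hard-sphere structure
factor for concentrated solutions, a reduced chi-square with analytically
fitted scale and offset, and a two-state ensemble fit recovering conformer
population fractions.

q is unit-tagged (1/A or 1/nm); intensities are arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


from .structure import CoarseStructure

__all__ = [
    "SaxsCurve",
    "EnsembleFit",
    "debye_scatter",
    "guinier_kratky",
    "extrapolate_form_factor",
    "py_structure_factor",
    "chi2_saxs",
    "two_state_fit",
    "shannon_channels",
]

_UNIT_SCALE = {"1/A": 1.0, "1/nm": 0.1}  # to 1/A


@dataclass
class SaxsCurve:
    """One scattering curve I(q) with uncertainties."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray = None
    q_unit: str = "1/A"
    concentration: float = None  # mg/mL

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.i = np.asarray(self.i, float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q_unit not in _UNIT_SCALE:
            raise ValueError("q_unit must be '1/A' or '1/nm'")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")

    def in_unit(self, q_unit: str) -> "SaxsCurve":
        """Convert the q axis between 1/A and 1/nm."""
        factor = _UNIT_SCALE[self.q_unit] / _UNIT_SCALE[q_unit]
        return replace(self, q=self.q * factor, q_unit=q_unit)

    @classmethod
    def load_dat(cls, path, q_unit="1/A", concentration=None):
        """Read a SASBDB-style 3-column .dat file (header tolerant)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 2:
                    continue
                try:
                    vals = [float(p) for p in parts[:3]]
                except ValueError:
                    continue
                if len(vals) == 2:
                    vals.append(np.nan)
                rows.append(vals)
        data = np.array(rows)
        sigma = data[:, 2]
        sigma = None if np.all(np.isnan(sigma)) else sigma
        return cls(q=data[:, 0], i=data[:, 1], sigma=sigma, q_unit=q_unit,
                   concentration=concentration)

    def save_dat(self, path):
        sigma = self.sigma if self.sigma is not None else np.zeros_like(self.q)
        np.savetxt(
            path,
            np.column_stack([self.q, self.i, sigma]),
            header=f"q ({self.q_unit})  I(q)  sigma",
        )


def debye_scatter(
    structure: CoarseStructure,
    q: np.ndarray,
    q_unit: str = "1/A",
    n_hist_bins: int = 4096,
    bead_form_factor: float | None = None,
) -> SaxsCurve:
    """Debye-formula scattering of a bead model.

    Exact pairwise evaluation for small models; larger models use a fine
    pair-distance histogram (``n_hist_bins`` bins), whose binning error is
    negligible against the 1% agreement expected of coarse bead models.
    ``bead_form_factor=r_b`` multiplies by the squared form factor of a
    sphere of radius ``r_b`` (angstrom), smoothing lattice artifacts of
    volume-filling bead models.
    """
    qa = np.asarray(q, float) * _UNIT_SCALE[q_unit]  # 1/A
    coords = structure.coords
    b = structure.weights
    n = len(coords)
    i_self = float(np.sum(b**2))
    if n <= 1200:
        d = np.sqrt(np.sum((coords[:, None] - coords[None, :]) ** 2, axis=-1))
        iu = np.triu_indices(n, k=1)
        dist = d[iu]
        wpair = 2.0 * b[iu[0]] * b[iu[1]]
        qr = np.outer(qa, dist)
        with np.errstate(invalid="ignore"):
            sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
        intensity = i_self + sinc @ wpair
    else:
        # histogram of pair distances, chunked
        dmax = 0.0
        hist = np.zeros(n_hist_bins)
        lo, hi = 0.0, float(np.ptp(coords, axis=0).max() * np.sqrt(3) + 1.0)
        edges = np.linspace(lo, hi, n_hist_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        from scipy.spatial.distance import cdist

        uniform_b = np.allclose(b, b[0])
        inv_bw = n_hist_bins / (hi - lo)
        chunk = 2048
        for s in range(0, n, chunk):
            blk = coords[s : s + chunk]
            d = cdist(blk, coords)
            idx = (d.ravel() * inv_bw).astype(np.intp)
            np.clip(idx, 0, n_hist_bins - 1, out=idx)
            if uniform_b:
                hist += b[0] ** 2 * np.bincount(idx, minlength=n_hist_bins)
            else:
                w = np.outer(b[s : s + chunk], b)
                hist += np.bincount(idx, weights=w.ravel(), minlength=n_hist_bins)
        hist[0] -= i_self  # remove self terms collected in the first bin
        qr = np.outer(qa, centers)
        with np.errstate(invalid="ignore"):
            sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
        intensity = i_self + sinc @ hist
    if bead_form_factor is not None:
        x = qa * bead_form_factor
        with np.errstate(invalid="ignore"):
            f = np.where(x > 1e-6, 3.0 * (np.sin(x) - x * np.cos(x)) / np.where(x > 0, x, 1.0) ** 3, 1.0)
        intensity = intensity * f**2
    return SaxsCurve(q=np.asarray(q, float), i=intensity, q_unit=q_unit)


def guinier_kratky(curve: SaxsCurve, qrg_max: float = 0.85) -> dict:
    """Guinier fit (R_g, I0) plus the Kratky transform q^2 I(q).

    The Guinier window ``q R_g < qrg_max`` is found iteratively from an
    initial fit over the lowest-q fifth of the data.  The default window sits
    in the low-bias part of the Guinier regime (q R_g < 1.3): for globular
    shapes the systematic R_g bias at 1.3 reaches ~2%, at 0.85 it stays
    below 1%.
    """
    c = curve.in_unit("1/A")
    q, i = c.q, c.i
    pos = i > 0
    q, i = q[pos], i[pos]
    sel = slice(0, max(len(q) // 5, 4))
    window = np.zeros(len(q), bool)
    window[sel] = True
    rg = None
    for _ in range(10):
        coef = np.polyfit(q[window] ** 2, np.log(i[window]), 1)
        rg_new = float(np.sqrt(max(-3.0 * coef[0], 0.0)))
        if rg_new == 0:
            break
        window_new = q * rg_new < qrg_max
        if window_new.sum() < 4:
            raise ValueError("insufficient points in the Guinier window")
        if rg is not None and abs(rg_new - rg) < 1e-6:
            window = window_new
            rg = rg_new
            break
        window, rg = window_new, rg_new
    i0 = float(np.exp(coef[1]))
    return {
        "Rg": rg,
        "I0": i0,
        "window": window,
        "kratky_q": curve.q,
        "kratky": curve.q**2 * curve.i,
    }


def extrapolate_form_factor(series: list[SaxsCurve]) -> SaxsCurve:
    """Infinite-dilution form factor from a concentration series.

    ``I(q, c)/c`` is extrapolated linearly in c to c = 0 on the common q
    range; following the usual merging rule the extrapolated values are used
    at low q and the highest-concentration data (scaled by 1/c) at high q,
    with the crossover at the midpoint of the common range.
    """
    if len(series) < 2:
        raise ValueError("need at least two concentrations")
    if any(c.concentration is None for c in series):
        raise ValueError("every curve needs a concentration")
    unit = series[0].q_unit
    curves = [c.in_unit(unit) for c in series]
    qlo = max(c.q.min() for c in curves)
    qhi = min(c.q.max() for c in curves)
    if qlo >= qhi:
        raise ValueError("q ranges do not overlap")
    qc = np.linspace(qlo, qhi, 400)
    conc = np.array([c.concentration for c in curves])
    per_c = np.array([np.interp(qc, c.q, c.i) / c.concentration for c in curves])
    # per-q linear fit of I/c vs c, intercept at c = 0
    A = np.column_stack([np.ones_like(conc), conc])
    coef, *_ = np.linalg.lstsq(A, per_c, rcond=None)
    extrapolated = coef[0]
    top = curves[int(np.argmax(conc))]
    merged = np.where(
        qc <= 0.5 * (qlo + qhi),
        extrapolated,
        np.interp(qc, top.q, top.i) / top.concentration,
    )
    return SaxsCurve(q=qc, i=merged, q_unit=unit, concentration=0.0)


def py_structure_factor(
    q: np.ndarray,
    r_hs: float,
    phi: float,
    beta: np.ndarray | None = None,
    q_unit: str = "1/nm",
) -> np.ndarray:
    """Percus-Yevick hard-sphere structure factor S(q).

    ``r_hs`` is the effective hard-sphere radius in the same length unit
    implied by ``q_unit``; ``phi`` the volume fraction (< 0.74).  With the
    decoupling correction ``beta(q)`` for asymmetric particles the returned
    factor is ``1 + beta (S - 1)``.  ``S(0) = (1-phi)^4 / (1+2phi)^2``.
    """
    if not 0.0 <= phi < 0.74:
        raise ValueError("volume fraction must lie in [0, 0.74)")
    if r_hs <= 0:
        raise ValueError("hard-sphere radius must be positive")
    q = np.asarray(q, float)
    if phi == 0.0:
        s = np.ones_like(q)
    else:
        a = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
        bcoef = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
        g = phi * a / 2
        A = 2.0 * q * r_hs
        s = np.empty_like(A)
        small = A < 0.05
        As = A[~small]
        sinA, cosA = np.sin(As), np.cos(As)
        G = (
            a * (sinA - As * cosA) / As**2
            + bcoef * (2 * As * sinA + (2 - As**2) * cosA - 2) / As**3
            + g
            * (-(As**4) * cosA + 4 * ((3 * As**2 - 6) * cosA + (As**3 - 6 * As) * sinA + 6))
            / As**5
        )
        s[~small] = 1.0 / (1.0 + 24 * phi * G / As)
        # small-A limit: G/A -> a/3 + b/4 + g/6
        lim = a / 3 + bcoef / 4 + g / 6
        s[small] = 1.0 / (1.0 + 24 * phi * lim)
    if beta is not None:
        s = 1.0 + np.asarray(beta, float) * (s - 1.0)
    return s


def shannon_channels(q_min: float, q_max: float, d_max: float) -> float:
    """Number of Shannon channels N_s = (q_max - q_min) D_max / pi."""
    return (q_max - q_min) * d_max / np.pi


def chi2_saxs(
    model: SaxsCurve,
    data: SaxsCurve,
    d_max: float | None = None,
) -> dict:
    """Reduced chi-square of a model curve against data, scale/offset fitted.

    The scale s and constant offset b minimizing
    ``sum ((s I_model + b - I_data)/sigma)^2`` are solved analytically; the
    divisor is N - 2 or, when ``d_max`` is supplied, the Shannon-channel
    count ``(q_max - q_min) d_max / pi`` minus 2.
    """
    if data.sigma is None or np.any(data.sigma <= 0):
        raise ValueError("data uncertainties are required and must be positive")
    m = model.in_unit(data.q_unit)
    im = np.interp(data.q, m.q, m.i)
    w = 1.0 / data.sigma**2
    A = np.column_stack([im, np.ones_like(im)])
    Aw = A * w[:, None]
    coef = np.linalg.solve(A.T @ Aw, Aw.T @ data.i)
    scale, offset = coef
    resid = (scale * im + offset - data.i) / data.sigma
    chi2 = float(resid @ resid)
    if d_max is not None:
        n_eff = shannon_channels(data.q.min(), data.q.max(), d_max)
        dof = max(n_eff - 2.0, 1.0)
    else:
        dof = max(len(data.q) - 2.0, 1.0)
    return {
        "chi2": chi2,
        "chi2_reduced": chi2 / dof,
        "scale": float(scale),
        "offset": float(offset),
        "dof": float(dof),
        "residuals": resid,
    }


@dataclass
class EnsembleFit:
    """Two-state ensemble fit result."""

    fraction: float
    chi2_reduced: float
    scale: float
    offset: float
    fractions_grid: np.ndarray
    chi2_profile: np.ndarray
    interval_68: tuple
    boundary: bool
    shannon: float = None


def two_state_fit(
    curve_m1: SaxsCurve,
    curve_m2: SaxsCurve,
    data: SaxsCurve,
    d_max: float | None = None,
    n_grid: int = 201,
) -> EnsembleFit:
    """Population fraction of conformer M1 from a two-state SAXS mixture.

    chi^2(x) of ``x I_M1 + (1-x) I_M2`` (scale and offset refitted at each x)
    is profiled on a grid over [0, 1]; the reported interval contains all x
    within the 68% confidence threshold ``chi2_min + 1``.  A fraction at the
    boundary (pure state) is flagged.
    """
    xs = np.linspace(0.0, 1.0, n_grid)
    m1 = curve_m1.in_unit(data.q_unit)
    m2 = curve_m2.in_unit(data.q_unit)
    i1 = np.interp(data.q, m1.q, m1.i)
    i2 = np.interp(data.q, m2.q, m2.i)
    if np.allclose(i1, i2, rtol=1e-12):
        import warnings

        warnings.warn("identical component curves: fraction is undetermined", RuntimeWarning)
    chi2 = np.empty(n_grid)
    fits = []
    for j, x in enumerate(xs):
        mix = SaxsCurve(q=data.q, i=x * i1 + (1 - x) * i2, q_unit=data.q_unit)
        out = chi2_saxs(mix, data, d_max=d_max)
        chi2[j] = out["chi2"]
        fits.append(out)
    jbest = int(np.argmin(chi2))
    best = fits[jbest]
    within = chi2 <= chi2[jbest] + 1.0
    interval = (float(xs[within].min()), float(xs[within].max()))
    return EnsembleFit(
        fraction=float(xs[jbest]),
        chi2_reduced=best["chi2_reduced"],
        scale=best["scale"],
        offset=best["offset"],
        fractions_grid=xs,
        chi2_profile=chi2,
        interval_68=interval,
        boundary=jbest in (0, n_grid - 1),
        shannon=best["dof"] + 2 if d_max is not None else None,
    )
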