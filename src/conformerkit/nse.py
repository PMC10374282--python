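"""Neutron spin-echo modeling of rigid-body protein diffusion.

For a rigid bead model with scattering weights ``b_i`` and a 6x6 diffusion
tensor ``D`` (translational block nm^2/ns, rotational block 1/ns), the
orientationally averaged effective diffusion coefficient at scattering vector
``q`` is

    D0(q) = < sum_jk b_j b_k e^{i q.(r_k - r_j)} (q, q x r_j) . D . (q, q x r_k) >
            / (q^2 F(q)),     F(q) = < |sum_j b_j e^{i q.r_j}|^2 >,

which tends to the translational trace ``D_t`` as q -> 0 and picks up
rotational contributions at finite q.  The full intermediate scattering
function combines internal dynamics, corrected translational diffusion and a
rotational expansion in spherical harmonics:

    I(q,t)/I(q,0) = [(1-A(q)) + A(q) e^{-Gamma t}]
                    * exp(-q^2 Dt Ht t / S(q))
                    * sum_l S_l(q) e^{-l(l+1) Dr Hr t} / sum_l S_l(q),
    S_l(q) = sum_m | sum_i b_i j_l(q r_i) Y_lm(Omega_i) |^2 .

Hydrodynamic corrections follow ``H_t = 1 - c [eta]`` and the spherical-
particle approximation ``1 - H_r = (1 - H_t)/3``; the sensitivity of NSE to
internal motions is bounded by the Debye-Waller estimate
``u = sqrt(-3 ln(1 - err)) / q``.

Units: lengths nm, times ns, q in 1/nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants, special

from .structure import CoarseStructure

__all__ = [
    "NseCurve",
    "DiffusionTensorSpec",
    "HydroParams",
    "rigid_body_Deff",
    "isf_model",
    "cumulant_fit",
    "hydro_translational",
    "ht_to_hr",
    "msd_bound",
    "kirkwood_tensor",
    "sphere_tensor",
]


@dataclass
class NseCurve:
    """Normalized intermediate scattering function I(q,t)/I(q,0) at one q."""

    q: float
    t: np.ndarray
    i_norm: np.ndarray
    sd: np.ndarray = None

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("q must be positive")
        self.t = np.asarray(self.t, float)
        self.i_norm = np.asarray(self.i_norm, float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)

    def save_csv(self, path):
        sd = self.sd if self.sd is not None else np.zeros_like(self.t)
        np.savetxt(
            path,
            np.column_stack([np.full_like(self.t, self.q), self.t, self.i_norm, sd]),
            delimiter=",",
            header="q_per_nm,t_ns,I_norm,SD",
            comments="",
        )

    @classmethod
    def load_csv(cls, path):
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        sd = data[:, 3] if data.shape[1] > 3 and np.any(data[:, 3] > 0) else None
        return cls(q=float(data[0, 0]), t=data[:, 1], i_norm=data[:, 2], sd=sd)


@dataclass
class DiffusionTensorSpec:
    """6x6 rigid-body diffusion tensor at the center of diffusion.

    Block layout [[D_tt, D_tr], [D_rt, D_rr]]: translational block in
    nm^2/ns, rotational block in 1/ns, coupling blocks in nm/ns.
    """

    tensor: np.ndarray
    center: np.ndarray = None

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, float)
        if self.tensor.shape != (6, 6):
            raise ValueError("diffusion tensor must be 6x6")
        if not np.allclose(self.tensor, self.tensor.T, atol=1e-10):
            raise ValueError("diffusion tensor must be symmetric")
        ev = np.linalg.eigvalsh(self.tensor)
        if ev.min() < -1e-10 * max(abs(ev).max(), 1.0):
            raise ValueError("diffusion tensor must be positive semidefinite")
        if self.center is None:
            self.center = np.zeros(3)
        self.center = np.asarray(self.center, float)

    @property
    def d_t(self) -> float:
        """Scalar translational diffusion coefficient (trace / 3)."""
        return float(np.trace(self.tensor[:3, :3]) / 3.0)

    @property
    def d_r(self) -> float:
        """Scalar rotational diffusion coefficient (trace / 3)."""
        return float(np.trace(self.tensor[3:, 3:]) / 3.0)

    @classmethod
    def load(cls, path):
        """Read a whitespace 6x6 matrix file."""
        return cls(tensor=np.loadtxt(path))

    def save(self, path):
        np.savetxt(path, self.tensor)


@dataclass
class HydroParams:
    """Hydrodynamic and internal-dynamics parameters of the NSE model."""

    h_t: float = 1.0
    h_r: float = 1.0
    s_q: float = 1.0  # structure factor at the evaluated q
    amplitude: float = 0.0  # internal-dynamics amplitude A(q)
    rate: float = 0.0  # internal-dynamics rate Gamma (1/ns)

    def __post_init__(self):
        if not (0.0 < self.h_t <= 1.0 and 0.0 < self.h_r <= 1.0):
            raise ValueError("H_t and H_r must lie in (0, 1]")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("A(q) must lie in [0, 1]")


# ---------------------------------------------------------------------------
# orientational quadrature
# ---------------------------------------------------------------------------

def _sphere_quadrature(n_theta: int = 24, n_phi: int = 48):
    """Gauss-Legendre (cos theta) x uniform (phi) product grid on the sphere."""
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    ct = x
    st = np.sqrt(1.0 - ct**2)
    dirs = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for i in range(n_theta):
        for j in range(n_phi):
            dirs[k] = (st[i] * np.cos(phi[j]), st[i] * np.sin(phi[j]), ct[i])
            w[k] = wx[i] / (2.0 * n_phi)
            k += 1
    return dirs, w


def _mc_directions(n: int, seed: int):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v, np.full(n, 1.0 / n)


def rigid_body_Deff(
    structure: CoarseStructure,
    tensor: DiffusionTensorSpec,
    q: float,
    n_theta: int = 24,
    n_phi: int = 48,
    monte_carlo: int | None = None,
    seed: int = 0,
    coords_nm: np.ndarray | None = None,
) -> float:
    """Orientationally averaged rigid-body D0(q) in nm^2/ns.

    Coordinates are taken from ``structure`` (angstrom, converted to nm)
    relative to the tensor's center of diffusion unless ``coords_nm`` is
    given directly.  ``monte_carlo=N`` replaces the product quadrature by a
    seeded N-direction Monte-Carlo average (the oracle path).
    """
    if q <= 0:
        raise ValueError("q must be positive")
    if coords_nm is None:
        coords_nm = structure.coords * 0.1
    r = np.asarray(coords_nm, float) - tensor.center
    b = structure.weights if structure is not None else np.ones(len(r))
    if monte_carlo:
        dirs, w = _mc_directions(monte_carlo, seed)
    else:
        if n_theta * n_phi < 590:
            raise ValueError("orientational grid must have at least 590 points")
        dirs, w = _sphere_quadrature(n_theta, n_phi)
    D = tensor.tensor
    qvec = q * dirs  # (n_dir, 3)
    phase = np.exp(1j * (qvec @ r.T))  # (n_dir, n_beads)
    amp = phase * b[None, :]
    # 6-vectors v_j = (q_vec, q_vec x r_j) summed with amplitudes
    cross = np.cross(qvec[:, None, :], r[None, :, :])  # (n_dir, n_beads, 3)
    u_t = amp.sum(axis=1)[:, None] * qvec  # sum_j a_j q_vec
    u_r = np.einsum("dj,djk->dk", amp, cross)
    u = np.concatenate([u_t, u_r], axis=1)  # (n_dir, 6) complex
    num = np.real(np.einsum("di,ij,dj->d", np.conj(u), D, u))
    form = np.abs(amp.sum(axis=1)) ** 2
    numerator = float(np.sum(w * num))
    denominator = float(np.sum(w * form)) * q**2
    if denominator <= 0:
        raise ValueError(f"form factor vanishes at q={q}")
    return numerator / denominator


# ---------------------------------------------------------------------------
# full intermediate scattering function
# ---------------------------------------------------------------------------

def _sl_spectrum(coords_nm: np.ndarray, b: np.ndarray, q: float, l_max: int):
    """Rotational amplitudes S_l(q) from spherical Bessel x real harmonics."""
    r = np.linalg.norm(coords_nm, axis=1)
    r_safe = np.where(r > 0, r, 1.0)
    theta = np.arccos(np.clip(coords_nm[:, 2] / r_safe, -1.0, 1.0))
    phi = np.arctan2(coords_nm[:, 1], coords_nm[:, 0])
    sl = np.zeros(l_max + 1)
    for l in range(l_max + 1):
        jl = special.spherical_jn(l, q * r)
        for m in range(-l, l + 1):
            ylm = special.sph_harm_y(l, abs(m), theta, phi)
            if m < 0:
                y = np.sqrt(2.0) * (-1.0) ** m * np.imag(ylm)
            elif m == 0:
                y = np.real(ylm)
            else:
                y = np.sqrt(2.0) * (-1.0) ** m * np.real(ylm)
            sl[l] += float(np.sum(b * jl * y)) ** 2
    return sl


def isf_model(
    structure: CoarseStructure,
    tensor: DiffusionTensorSpec,
    hydro: HydroParams,
    q: float,
    t: np.ndarray,
    l_max: int = 15,
    coords_nm: np.ndarray | None = None,
) -> NseCurve:
    """Full rigid-body + internal-dynamics model of I(q,t)/I(q,0).

    The translational factor uses ``Dt_eff = Dt * Ht / S(q)``; the rotational
    part is the l-expansion truncated at ``l_max``; the internal term is
    ``(1 - A) + A exp(-Gamma t)``.  The value at t = 0 is exactly 1.
    """
    t = np.asarray(t, float)
    if coords_nm is None:
        coords_nm = structure.coords * 0.1
    coords_nm = coords_nm - tensor.center
    b = structure.weights
    sl = _sl_spectrum(coords_nm, b, q, l_max)
    ll = np.arange(l_max + 1)
    rot = (sl[None, :] * np.exp(-np.outer(t, ll * (ll + 1)) * tensor.d_r * hydro.h_r)).sum(
        axis=1
    ) / sl.sum()
    trans = np.exp(-(q**2) * tensor.d_t * hydro.h_t / hydro.s_q * t)
    internal = (1.0 - hydro.amplitude) + hydro.amplitude * np.exp(-hydro.rate * t)
    return NseCurve(q=q, t=t, i_norm=internal * trans * rot)


def cumulant_fit(curve: NseCurve, t_max_fit: float) -> dict:
    """Initial-slope cumulant analysis: ln(I/I0) = K1 t + K2 t^2 / 2.

    Returns K1 (1/ns), K2, the effective diffusion coefficient
    ``D_eff = -K1/q^2`` (nm^2/ns) and its SD propagated from the fit.
    """
    win = curve.t <= t_max_fit
    if win.sum() < 4:
        raise ValueError("cumulant window must contain at least 4 points")
    t = curve.t[win]
    y = np.log(np.clip(curve.i_norm[win], 1e-300, None))
    if curve.sd is not None:
        w = curve.i_norm[win] / curve.sd[win]  # d ln I = dI / I
    else:
        w = np.ones_like(t)
    X = np.column_stack([t, 0.5 * t**2])
    Xw = X * w[:, None]
    yw = y * w
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    k1, k2 = coef
    cov = np.linalg.inv(Xw.T @ Xw)
    k1_sd = float(np.sqrt(cov[0, 0]))
    if k1 > 0:
        import warnings

        warnings.warn("positive K1: intensity grows with Fourier time", RuntimeWarning)
    return {
        "K1": float(k1),
        "K2": float(k2),
        "D_eff": float(-k1 / curve.q**2),
        "D_eff_sd": k1_sd / curve.q**2,
    }


# ---------------------------------------------------------------------------
# hydrodynamic corrections and bounds
# ---------------------------------------------------------------------------

def hydro_translational(c_mg_ml: float, intrinsic_viscosity_ml_mg: float) -> float:
    """Concentration correction H_t = 1 - c [eta]."""
    x = c_mg_ml * intrinsic_viscosity_ml_mg
    if x >= 1.0:
        raise ValueError("c * [eta] must be below 1")
    return 1.0 - x


def ht_to_hr(h_t: float) -> float:
    """Spherical-particle approximation 1 - H_r = (1 - H_t)/3."""
    return 1.0 - (1.0 - h_t) / 3.0


def msd_bound(err: float, q: float) -> float:
    """Debye-Waller bound on the internal-motion MSD amplitude.

    Solves ``-u^2 q^2 / 3 = ln(1 - err)`` for the displacement u (nm) that
    would change I(q,t) by the fractional deviation ``err`` at scattering
    vector ``q`` (1/nm).
    """
    if not 0.0 < err < 1.0:
        raise ValueError("err must lie in (0, 1)")
    if q <= 0:
        raise ValueError("q must be positive")
    return float(np.sqrt(-3.0 * np.log(1.0 - err)) / q)


# ---------------------------------------------------------------------------
# synthetic-tensor helpers (tests and toy systems only)
# ---------------------------------------------------------------------------

def sphere_tensor(
    radius_nm: float, temperature: float = 293.15, viscosity_pa_s: float = 1e-3
) -> DiffusionTensorSpec:
    """Isotropic Stokes-Einstein tensor of a sphere (exact reference)."""
    kt = constants.k * temperature
    d_t = kt / (6 * np.pi * viscosity_pa_s * radius_nm * 1e-9)  # m^2/s
    d_r = kt / (8 * np.pi * viscosity_pa_s * (radius_nm * 1e-9) ** 3)  # 1/s
    D = np.zeros((6, 6))
    D[:3, :3] = np.eye(3) * d_t * 1e18 / 1e9  # m^2/s -> nm^2/ns
    D[3:, 3:] = np.eye(3) * d_r / 1e9  # 1/s -> 1/ns
    return DiffusionTensorSpec(tensor=D)


def kirkwood_tensor(
    coords_nm: np.ndarray,
    bead_radius_nm: float,
    temperature: float = 293.15,
    viscosity_pa_s: float = 1e-3,
) -> DiffusionTensorSpec:
    """Kirkwood-type bead approximation of an isotropic diffusion tensor.

    A deliberately crude synthetic-tensor generator for toy systems: the
    translational coefficient is the Kirkwood double sum and the rotational
    coefficient treats the assembly as an effective sphere enclosing all
    beads.  A single bead reproduces the exact sphere results.
    """
    r = np.atleast_2d(np.asarray(coords_nm, float))
    n = len(r)
    kt = constants.k * temperature
    inv = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                inv += 1.0 / bead_radius_nm
            else:
                inv += 1.0 / np.linalg.norm(r[i] - r[j])
    d_t = kt / (6 * np.pi * viscosity_pa_s * 1e-9) * inv / n**2  # m^2/s x (1/nm)
    center = r.mean(axis=0)
    reff = np.linalg.norm(r - center, axis=1).max() + bead_radius_nm
    d_r = kt / (8 * np.pi * viscosity_pa_s * (reff * 1e-9) ** 3)
    D = np.zeros((6, 6))
    D[:3, :3] = np.eye(3) * d_t * 1e18 / 1e9
    D[3:, 3:] = np.eye(3) * d_r / 1e9
    return DiffusionTensorSpec(tensor=D, center=center)
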