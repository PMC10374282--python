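"""Filtered fluorescence correlation spectroscopy (fFCS).

Species-selective correlation analysis of two-state (high/low FRET) photon
streams.  Detector x TAC-channel decay patterns of the two species define a
set of minimal-variance unbiased unmixing filters ``w_j^(n)``; applying the
filters to the binned signal gives species-weighted intensities whose auto-
and cross-correlations isolate exchange kinetics from diffusion:

    G^(n,m)(tc) = <F^(n)(t) F^(m)(t+tc)> / (<F^(n)> <F^(m)>)

The correlation curves are described by a product of a single diffusion term
(3D Gaussian focus) and species-pair-specific kinetic terms: up to three
exponential relaxation components whose amplitudes sum to one, an
anti-correlation amplitude for the cross-correlations, and an acceptor
bleaching term for curves involving the high-FRET species.  Relaxation times
are typically shared (global) across label-pair variants, amplitudes are
local.

Lag times in seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "FilterSet",
    "CorrCurve",
    "KineticModel",
    "compute_filters",
    "species_correlate",
    "multi_tau_lags",
    "fcs_model",
    "global_fit_ffcs",
    "mean_relaxation_time",
    "relaxation_spectrum",
]

CURVE_KINDS = ("sACF_HH", "sACF_LL", "sCCF_HL", "sCCF_LH")


@dataclass
class FilterSet:
    """Per-species unmixing filters over detector x TAC channels."""

    weights: np.ndarray  # (n_species, n_channels)
    patterns: np.ndarray  # (n_channels, n_species), column-normalized
    mean_signal: np.ndarray  # (n_channels,)
    species: tuple = ("H", "L")

    def unbiasedness(self) -> np.ndarray:
        """Matrix w @ patterns; identity for an exact filter set."""
        return self.weights @ self.patterns

    def save_json(self, path):
        import json

        payload = {
            "species": list(self.species),
            "weights": self.weights.tolist(),
            "patterns": self.patterns.tolist(),
            "mean_signal": self.mean_signal.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load_json(cls, path):
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.array(payload["weights"]),
            patterns=np.array(payload["patterns"]),
            mean_signal=np.array(payload["mean_signal"]),
            species=tuple(payload["species"]),
        )


def compute_filters(patterns: np.ndarray, mean_signal: np.ndarray, species=("H", "L")) -> FilterSet:
    """Minimal-variance unbiased species filters from decay patterns.

    ``patterns`` has one column per species (normalized to unit sum);
    ``mean_signal`` is the mean counts per channel of the measured stream.
    The filters are the weighted least-squares unmixing matrix

        W = (M^T diag(1/s) M)^-1 M^T diag(1/s)

    and satisfy ``W M = I`` (unbiasedness) exactly.
    """
    M = np.asarray(patterns, float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need at least two species patterns")
    s = np.asarray(mean_signal, float)
    if np.any(s <= 0):
        raise ValueError("mean signal must be positive in every channel")
    M = M / M.sum(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        raise np.linalg.LinAlgError(
            f"species patterns are collinear (rank {rank} < {M.shape[1]})"
        )
    Winv = M.T * (1.0 / s)[None, :]
    W = np.linalg.solve(Winv @ M, Winv)
    return FilterSet(weights=W, patterns=M, mean_signal=s, species=tuple(species))


def multi_tau_lags(bin_time: float, n_bins: int, points_per_cascade: int = 16):
    """Quasi-logarithmic multi-tau lag ladder (factor-2 cascade coarsening).

    Returns a list of (lag_in_bins, coarsening_level) pairs whose lag times
    stay below half the record length.
    """
    lags = []
    level = 0
    lag = 1
    while True:
        for _ in range(points_per_cascade):
            t_lag = lag * (2**level) * bin_time
            if lag * (2**level) > n_bins // 2:
                return lags
            lags.append((lag, level))
            lag += 1
        lag = (lag + 1) // 2
        level += 1


@dataclass
class CorrCurve:
    """One species correlation curve on a quasi-log lag grid."""

    lag: np.ndarray
    g: np.ndarray
    sd: np.ndarray = None
    kind: str = "sACF_HH"
    variant: str = ""

    def __post_init__(self):
        self.lag = np.asarray(self.lag, float)
        self.g = np.asarray(self.g, float)
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag grid must be increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
            if np.any(self.sd <= 0):
                raise ValueError("per-point SDs must be positive")
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind '{self.kind}'")

    def save_csv(self, path):
        sd = self.sd if self.sd is not None else np.full_like(self.lag, np.nan)
        np.savetxt(
            path,
            np.column_stack([self.lag, self.g, sd]),
            delimiter=",",
            header=f"lag_s,G,SD,kind={self.kind},variant={self.variant}",
            comments="",
        )


def _correlate_binned(fa: np.ndarray, fb: np.ndarray, bin_time: float,
                      points_per_cascade: int = 16):
    """Multi-tau normalized correlation of two weighted signals."""
    lag_t, g = [], []
    a, b = fa.astype(float), fb.astype(float)
    dt = bin_time
    level = 0
    lag = 1
    while True:
        n = len(a)
        done = False
        for _ in range(points_per_cascade):
            if lag >= n // 2:
                done = True
                break
            num = np.mean(a[: n - lag] * b[lag:])
            den = np.mean(a[: n - lag]) * np.mean(b[lag:])
            if den > 0:
                lag_t.append(lag * dt)
                g.append(num / den)
            lag += 1
        if done or len(a) < 4 * points_per_cascade:
            break
        # factor-2 coarsening with averaging (multi-tau scheme)
        m = len(a) // 2
        a = 0.5 * (a[: 2 * m : 2] + a[1 : 2 * m : 2])
        b = 0.5 * (b[: 2 * m : 2] + b[1 : 2 * m : 2])
        dt *= 2
        lag = (lag + 1) // 2
        level += 1
    return np.array(lag_t), np.array(g)


def species_correlate(
    signals: np.ndarray,
    filters: FilterSet,
    pair: tuple[str, str],
    bin_time: float,
    points_per_cascade: int = 16,
    n_splits: int = 1,
    variant: str = "",
) -> CorrCurve:
    """Species auto/cross correlation of a binned channel-resolved signal.

    ``signals`` has shape (n_channels, n_time_bins).  ``pair`` selects the
    species, e.g. ``("H", "H")`` for an sACF or ``("L", "H")`` for an sCCF.
    With ``n_splits > 1`` the record is split and the per-point SD across
    splits is attached to the curve.
    """
    S = np.asarray(signals, float)
    if S.ndim != 2 or S.shape[1] == 0:
        raise ValueError("signals must be a non-empty (channels, time) array")
    idx = {sp: i for i, sp in enumerate(filters.species)}
    n, m = idx[pair[0]], idx[pair[1]]
    fa = filters.weights[n] @ S
    fb = filters.weights[m] @ S
    kind = (
        f"sACF_{pair[0]}{pair[1]}" if pair[0] == pair[1] else f"sCCF_{pair[0]}{pair[1]}"
    )
    if n_splits <= 1:
        lag, g = _correlate_binned(fa, fb, bin_time, points_per_cascade)
        return CorrCurve(lag=lag, g=g, kind=kind, variant=variant)
    size = len(fa) // n_splits
    gs = []
    for i in range(n_splits):
        sl = slice(i * size, (i + 1) * size)
        lag, g = _correlate_binned(fa[sl], fb[sl], bin_time, points_per_cascade)
        gs.append(g)
    gs = np.array(gs)
    sd = gs.std(axis=0, ddof=1) / np.sqrt(n_splits)
    sd = np.where(sd > 0, sd, np.nanmax(sd) if np.nanmax(sd) > 0 else 1.0)
    return CorrCurve(lag=lag, g=gs.mean(axis=0), sd=sd, kind=kind, variant=variant)


@dataclass
class KineticModel:
    """Diffusion + multi-exponential kinetics for the four fFCS curve kinds.

    Relaxation amplitudes ``a1 + a2 + a3 = 1`` (enforced by construction when
    fitted); sACF amplitudes and the anti-correlation/bleach amplitudes are
    curve-kind specific.  Times in seconds.
    """

    n_eff: dict = field(default_factory=lambda: {"HH": 1.0, "LL": 1.0, "CC": 1.0})
    t_diff: float = 1e-3
    axial_ratio: float = 5.0
    a0: dict = field(default_factory=lambda: {"LH": 0.5, "HL": 0.5})
    times: tuple = (2e-6, 23e-6, 297e-6)
    amplitudes: tuple = (1.0, 0.0, 0.0)
    acf_amplitudes: dict = field(
        default_factory=lambda: {"HH": (0.2, 0.0, 0.0), "LL": (0.2, 0.0, 0.0)}
    )
    bleach_amplitude: float = 0.0
    bleach_time: float = 5e-3

    def __post_init__(self):
        if not np.isclose(sum(self.amplitudes), 1.0):
            raise ValueError("kinetic amplitudes must sum to 1")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("kinetic amplitudes must be non-negative")
        if any(t <= 0 for t in self.times):
            raise ValueError("relaxation times must be positive")


def _g_diff(tc, t_diff, axial_ratio):
    return (1.0 + tc / t_diff) ** -1 * (1.0 + tc / (axial_ratio**2 * t_diff)) ** -0.5


def fcs_model(tc: np.ndarray, model: KineticModel, kind: str) -> np.ndarray:
    """Evaluate the diffusion x kinetics correlation model for one curve kind."""
    tc = np.asarray(tc, float)
    if kind not in CURVE_KINDS:
        raise ValueError(f"unknown curve kind '{kind}'")
    gd = _g_diff(tc, model.t_diff, model.axial_ratio)
    times = np.asarray(model.times)
    if kind in ("sCCF_HL", "sCCF_LH"):
        amps = np.asarray(model.amplitudes)
        decay = np.sum(amps[:, None] * np.exp(-tc[None, :] / times[:, None]), axis=0)
        tag = kind[-2:]
        gk = 1.0 - model.a0[tag] * decay
        if tag == "HL" and model.bleach_amplitude:
            gk = gk * (1.0 - model.bleach_amplitude * np.exp(-tc / model.bleach_time))
        n_eff = model.n_eff["CC"]
    else:
        tag = kind[-2:]
        amps = np.asarray(model.acf_amplitudes[tag])
        gk = 1.0 + np.sum(
            amps[:, None] * (np.exp(-tc[None, :] / times[:, None]) - 1.0), axis=0
        )
        if tag == "HH" and model.bleach_amplitude:
            gk = gk * (1.0 + model.bleach_amplitude * (np.exp(-tc / model.bleach_time) - 1.0))
        n_eff = model.n_eff[tag]
    return 1.0 + gd * gk / n_eff


def mean_relaxation_time(model: KineticModel) -> float:
    """Amplitude-weighted arithmetic mean of the relaxation times."""
    amps = np.asarray(model.amplitudes)
    return float(np.sum(amps * np.asarray(model.times)) / amps.sum())


def relaxation_spectrum(rate_matrix: np.ndarray) -> np.ndarray:
    """Relaxation times (ascending) of a kinetic exchange rate matrix.

    The rate matrix has off-diagonal entries ``K[i, j] = k(j -> i)`` and
    columns summing to zero; the relaxation times are ``-1/lambda`` for the
    nonzero eigenvalues.
    """
    K = np.asarray(rate_matrix, float)
    ev = np.linalg.eigvals(K)
    ev = np.real(ev)
    nz = ev[np.abs(ev) > 1e-12 * max(np.abs(ev).max(), 1.0)]
    return np.sort(-1.0 / nz)


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

def _model_from_params(p, variant, n_times):
    times = tuple(p[f"tc{k+1}"].value for k in range(n_times))
    a1 = p[f"{variant}_a1"].value
    a2 = p[f"{variant}_a2"].value if n_times > 1 else 0.0
    if n_times == 3:
        a3 = max(1.0 - a1 - a2, 0.0)
        amps = (a1, a2, a3)
    elif n_times == 2:
        amps = (a1, 1.0 - a1, 0.0)
        times = times + (1.0,)
    else:
        amps = (1.0, 0.0, 0.0)
        times = times + (1.0, 1.0)
    total = sum(amps)
    amps = tuple(a / total for a in amps)
    return KineticModel(
        n_eff={
            "HH": p[f"{variant}_neff_HH"].value,
            "LL": p[f"{variant}_neff_LL"].value,
            "CC": p[f"{variant}_neff_CC"].value,
        },
        t_diff=p[f"{variant}_tdiff"].value,
        axial_ratio=p[f"{variant}_axial"].value,
        a0={"LH": p[f"{variant}_a0_LH"].value, "HL": p[f"{variant}_a0_HL"].value},
        times=times,
        amplitudes=amps,
        acf_amplitudes={
            "HH": tuple(p[f"{variant}_aHH{k+1}"].value for k in range(3)),
            "LL": tuple(p[f"{variant}_aLL{k+1}"].value for k in range(3)),
        },
        bleach_amplitude=p[f"{variant}_ab"].value,
        bleach_time=p[f"{variant}_tb"].value,
    )


def global_fit_ffcs(
    curves: list[CorrCurve],
    n_times: int = 3,
    initial_times: tuple = (5e-6, 5e-5, 5e-4),
    fit_bleach: bool = False,
    t_diff_init: float = 1e-3,
) -> dict:
    """Global fit of many variants' fFCS curves with shared relaxation times.

    All curves are fitted simultaneously: relaxation times are global
    parameters; amplitudes, effective molecule numbers and diffusion times are
    local per variant.  The two sCCFs of a variant share one ``N_eff``.
    Per-point SDs weight the residuals when available.

    Returns a dict with the lmfit ``result``, fitted shared ``times`` and a
    per-variant :class:`KineticModel` map.
    """
    variants = sorted({c.variant for c in curves})
    by_variant = {v: [c for c in curves if c.variant == v] for v in variants}
    params = lmfit.Parameters()
    for k in range(n_times):
        params.add(f"tc{k+1}", value=initial_times[k], min=1e-8, max=1.0)
    for v in variants:
        params.add(f"{v}_neff_HH", value=1.0, min=1e-3)
        params.add(f"{v}_neff_LL", value=1.0, min=1e-3)
        params.add(f"{v}_neff_CC", value=1.0, min=1e-3)
        params.add(f"{v}_tdiff", value=t_diff_init, min=1e-6, max=1.0)
        params.add(f"{v}_axial", value=5.0, vary=False)
        params.add(f"{v}_a0_LH", value=0.5, min=0.0, max=2.0)
        params.add(f"{v}_a0_HL", value=0.5, min=0.0, max=2.0)
        params.add(f"{v}_a1", value=1.0 / n_times, min=0.0, max=1.0)
        if n_times > 1:
            params.add(f"{v}_a2", value=1.0 / n_times, min=0.0, max=1.0)
        for k in range(3):
            vary = k < n_times
            params.add(f"{v}_aHH{k+1}", value=0.1 if vary else 0.0, min=0.0, max=2.0, vary=vary)
            params.add(f"{v}_aLL{k+1}", value=0.1 if vary else 0.0, min=0.0, max=2.0, vary=vary)
        params.add(f"{v}_ab", value=0.1 if fit_bleach else 0.0, min=0.0, max=1.0, vary=fit_bleach)
        params.add(f"{v}_tb", value=5e-3, min=1e-3, max=2e-2, vary=fit_bleach)

    def residuals(p):
        res = []
        for v in variants:
            model = _model_from_params(p, v, n_times)
            for c in by_variant[v]:
                g = fcs_model(c.lag, model, c.kind)
                w = c.sd if c.sd is not None else np.full_like(c.g, 1e-3)
                res.append((g - c.g) / w)
        return np.concatenate(res)

    result = lmfit.minimize(residuals, params, method="leastsq")
    times = np.sort([result.params[f"tc{k+1}"].value for k in range(n_times)])
    models = {v: _model_from_params(result.params, v, n_times) for v in variants}
    return {"result": result, "times": times, "models": models}
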