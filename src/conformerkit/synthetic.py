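"""Synthetic two-conformer systems and statistically faithful test data.

Builds toy multi-domain bead proteins in two conformations (M1, M2) related
by a hinge rotation, plus forward-simulated data for every modality the
package analyzes: TCSPC donor decays, DEER dipolar traces, filtered-FCS
correlation curves, NSE intermediate scattering functions, SAXS mixture
curves and a restraint table with ground truth.  All generators are
deterministic for a fixed seed and carry their parameters in the returned
bundle, so round-trip tests can compare recovered against true parameters.

Default statistical conditions mirror a two-state system with population
fractions 0.61/0.39, Gaussian distance components of ~12 A width over the
30-70 A range, microsecond exchange (relaxation times within 2-300 us),
multi-exponential donor references and photon budgets of order 1e7 counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import deer as deer_mod
from . import ffcs as ffcs_mod
from . import nse as nse_mod
from . import saxs as saxs_mod
from . import tcspc as tcspc_mod
from .discriminate import RestraintTable, predict_distances
from .labels import DistanceDistribution
from .structure import CoarseStructure, rmsd

__all__ = [
    "ToySystem",
    "NoiseSpec",
    "make_toy_system",
    "simulate_modalities",
    "candidate_ensemble",
    "simulate_telegraph",
    "two_state_rate_matrix",
    "chain_rate_matrix",
]


@dataclass
class NoiseSpec:
    """Noise law for one modality."""

    modality: str
    law: str = "gaussian"  # "poisson" | "gaussian"
    magnitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.magnitude < 0:
            raise ValueError("noise magnitude must be non-negative")
        if self.law not in ("poisson", "gaussian"):
            raise ValueError("noise law must be 'poisson' or 'gaussian'")


@dataclass
class ToySystem:
    """Two-conformer toy protein with label sites and exchange kinetics."""

    m1: CoarseStructure
    m2: CoarseStructure
    fret_pairs: list
    spin_pairs: list
    x_m1: float
    rate_matrix: np.ndarray
    hinge_angle_deg: float
    seed: int

    @property
    def relaxation_times_s(self) -> np.ndarray:
        return ffcs_mod.relaxation_spectrum(self.rate_matrix) * 1e-6  # matrix in 1/us


def two_state_rate_matrix(relaxation_time_us: float, equilibrium_x1: float = 0.61):
    """Column rate matrix (1/us) of a two-state exchange with a given
    relaxation time ``1/(k12 + k21)`` and equilibrium fraction of state 1."""
    ksum = 1.0 / relaxation_time_us
    k12 = ksum * (1.0 - equilibrium_x1)  # 1 -> 2
    k21 = ksum * equilibrium_x1
    return np.array([[-k12, k21], [k12, -k21]])


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def _helix_rod(n_res: int, start: np.ndarray, direction: np.ndarray, rng) -> np.ndarray:
    """Coarse helical rod: ~1.5 A rise per residue around the body axis."""
    direction = direction / np.linalg.norm(direction)
    # orthonormal frame
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    t = np.arange(n_res)
    radius = 5.0
    pitch_angle = 100.0 * np.pi / 180.0  # per residue
    pts = (
        start[None, :]
        + np.outer(t * 1.5, direction)
        + radius * np.outer(np.cos(t * pitch_angle), u)
        + radius * np.outer(np.sin(t * pitch_angle), v)
    )
    return pts


def make_toy_system(
    n_bodies: int = 4,
    hinge_angle_deg: float = 40.0,
    n_fret_pairs: int = 12,
    n_spin_pairs: int = 8,
    seed: int = 0,
    x_m1: float = 0.61,
    relaxation_times_us: tuple = (2.0, 23.0, 297.0),
    residues_per_body: int = 40,
) -> ToySystem:
    """Deterministic two-conformer toy protein.

    M1 is a chain of ``n_bodies`` helical rigid bodies; M2 is M1 with every
    body beyond the first hinge rotated by ``hinge_angle_deg`` about an axis
    through the hinge point, so inter-label distances across the hinge change
    by several to tens of angstrom.  Label pairs are drawn (seeded) to span
    the hinge.  The exchange kinetics is a 3-state chain whose rate matrix is
    built to have relaxation times ``relaxation_times_us`` when 3 or more
    states are requested (two states give the first time only).
    """
    if n_bodies < 2:
        raise ValueError("need at least two rigid bodies")
    rng = np.random.default_rng(seed)
    coords = []
    body_tags = []
    start = np.zeros(3)
    direction = np.array([1.0, 0.0, 0.0])
    for ib in range(n_bodies):
        rod = _helix_rod(residues_per_body, start, direction, rng)
        coords.append(rod)
        body_tags.extend([ib] * residues_per_body)
        # fold back into a compact bundle: large in-plane turn plus a lift
        direction = _rotation_matrix(np.array([0.0, 0.0, 1.0]), (-1) ** ib * 2.45) @ direction
        start = rod[-1] + direction * 6.0 + np.array([0.0, 0.0, 12.0])
    coords = np.vstack(coords)
    n_res = len(coords)
    body_tags = np.array(body_tags)
    m1 = CoarseStructure(
        coords=coords,
        radii=3.0,
        weights=1.0,
        residue_ids=np.arange(1, n_res + 1),
        rigid_body=body_tags,
        label="M1",
    )

    # hinge: the distal half of the bodies rotates about the connector bead
    first_moving = max(n_bodies // 2, 1)
    moving = body_tags >= first_moving
    pivot = coords[first_moving * residues_per_body - 1]
    R = _rotation_matrix(np.array([0.0, 0.0, 1.0]), np.deg2rad(hinge_angle_deg))
    coords2 = coords.copy()
    coords2[moving] = (coords2[moving] - pivot) @ R.T + pivot
    m2 = CoarseStructure(
        coords=coords2,
        radii=3.0,
        weights=1.0,
        residue_ids=np.arange(1, n_res + 1),
        rigid_body=body_tags,
        label="M2",
    )

    # label sites near the quarter points of each body; keep pairs whose M1
    # distance falls in the FRET/DEER-informative window, informative
    # (hinge-sensitive) pairs first
    site_pool = []
    for ib in range(n_bodies):
        base = ib * residues_per_body
        site_pool.extend(
            [base + residues_per_body // 4, base + 3 * residues_per_body // 4]
        )
    site_pool = [s + 1 for s in site_pool]  # residue ids are 1-based

    candidates = []
    for idx_a in range(len(site_pool)):
        for idx_b in range(idx_a + 1, len(site_pool)):
            a, b = site_pool[idx_a], site_pool[idx_b]
            d1 = float(np.linalg.norm(coords[a - 1] - coords[b - 1]))
            d2 = float(np.linalg.norm(coords2[a - 1] - coords2[b - 1]))
            if 25.0 <= d1 <= 75.0:
                candidates.append((abs(d1 - d2), max(d1, d2), a, b))
    candidates.sort(key=lambda c: -c[0])

    def draw_pairs(n_pairs, max_distance=np.inf, offset=0):
        picked = []
        for delta, dmax, a, b in candidates[offset:]:
            if dmax > max_distance:
                continue
            picked.append((a, b))
            if len(picked) == n_pairs:
                break
        return picked

    # FRET spans the 30-80 A window; spin pairs stay short (DEER-friendly,
    # well inside a few-microsecond dipolar evolution window)
    fret_pairs = draw_pairs(n_fret_pairs)
    spin_pairs = draw_pairs(n_spin_pairs, max_distance=58.0, offset=1)

    if len(relaxation_times_us) >= 2:
        rate = chain_rate_matrix(relaxation_times_us)
    else:
        rate = two_state_rate_matrix(relaxation_times_us[0], x_m1)
    return ToySystem(
        m1=m1,
        m2=m2,
        fret_pairs=fret_pairs,
        spin_pairs=spin_pairs,
        x_m1=x_m1,
        rate_matrix=rate,
        hinge_angle_deg=hinge_angle_deg,
        seed=seed,
    )


def chain_rate_matrix(times_us) -> np.ndarray:
    """Symmetric nearest-neighbour exchange chain with prescribed relaxation
    times.

    An (n+1)-state chain with symmetric rates r_1..r_n (1/us) has n nonzero
    eigenvalues; the rates are solved numerically so the relaxation times
    ``-1/lambda`` match ``times_us`` exactly.
    """
    from scipy.optimize import least_squares

    times = np.sort(np.asarray(times_us, float))[::-1]  # slow .. fast
    n = len(times)
    target = np.sort(-1.0 / times)  # ascending (most negative = fastest)

    def build(rates):
        K = np.zeros((n + 1, n + 1))
        for i, r in enumerate(rates):
            K[i, i] -= r
            K[i + 1, i + 1] -= r
            K[i, i + 1] += r
            K[i + 1, i] += r
        return K

    def resid(log_rates):
        K = build(np.exp(log_rates))
        ev = np.sort(np.linalg.eigvalsh(K))[:n]
        return ev - target

    x0 = np.log(1.0 / times)
    sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not np.allclose(resid(sol.x), 0.0, atol=1e-8 * np.abs(target).max()):
        raise RuntimeError("could not match the requested relaxation spectrum")
    return build(np.exp(sol.x))


# ---------------------------------------------------------------------------
# modality simulation
# ---------------------------------------------------------------------------

def simulate_modalities(
    system: ToySystem,
    seed: int = 0,
    tcspc_counts: float = 2e7,
    deer_noise_sd: float = 0.005,
    ffcs_noise_sd: float = 0.003,
    nse_noise_sd: float = 0.005,
    saxs_noise_frac: float = 0.005,
    width_da: float = 12.0,
    grid_spacing: float = 2.0,
    restraint_sigma: float = 3.0,
    restraint_noise_factor: float = 0.5,
    saxs_sigma_inflation: float = 3.0,
    n_variants_ffcs: int | None = None,
    include: tuple = ("tcspc", "deer", "ffcs", "nse", "saxs"),
) -> dict:
    """Forward-simulate every modality for a toy system.

    Every dataset is generated by the corresponding forward model of the
    analysis modules with seeded noise; the returned bundle carries the
    ground truth (model distances, fractions, relaxation times, tensors)
    alongside the data.

    Reported uncertainties are conservative relative to the injected noise:
    restraint values are drawn with SD ``restraint_noise_factor * sigma`` and
    SAXS errors are quoted ``saxs_sigma_inflation`` times the actual noise
    SD, emulating experimental uncertainty budgets that include systematic
    contributions on top of counting statistics.
    """
    # independent per-modality streams so subsets are reproducible
    rngs = {k: np.random.default_rng([seed, i]) for i, k in enumerate(
        ("restraints", "tcspc", "deer", "ffcs", "nse", "saxs"))}
    rng = rngs["restraints"]
    cache: dict = {}

    # --- ground-truth label distances on both conformers -------------------
    rows = []
    for i, (a, b) in enumerate(system.fret_pairs):
        rows.append(("F%02d" % i, "FRET", a, b))
    for i, (a, b) in enumerate(system.spin_pairs):
        rows.append(("S%02d" % i, "DEER", a, b))
    proto = pd.DataFrame(
        {
            "pair_id": [r[0] for r in rows],
            "technique": [r[1] for r in rows],
            "state": "M1",
            "residue_1": [r[2] for r in rows],
            "residue_2": [r[3] for r in rows],
            "distance_A": 0.0,
            "sigma_minus": restraint_sigma,
            "sigma_plus": restraint_sigma,
        }
    )
    base = RestraintTable(table=proto)
    pred_m1 = predict_distances(system.m1, base, grid_spacing=grid_spacing, _cache=cache)
    pred_m2 = predict_distances(system.m2, base, grid_spacing=grid_spacing, _cache=cache)

    # restraint table: one row per pair and state, experimental value =
    # truth + noise within sigma
    tables = []
    for state, pred in (("M1", pred_m1), ("M2", pred_m2)):
        t = proto.copy()
        t["state"] = state
        t["distance_A"] = pred + rng.normal(
            0, restraint_noise_factor * restraint_sigma, size=len(pred)
        )
        tables.append(t)
    restraints = RestraintTable(table=pd.concat(tables, ignore_index=True))

    bundle = {
        "restraints": restraints,
        "pred_m1": pred_m1,
        "pred_m2": pred_m2,
        "seed": seed,
    }

    # --- TCSPC --------------------------------------------------------------
    if "tcspc" in include:
        rng = rngs["tcspc"]
        donor_ref = tcspc_mod.FluorophoreReference([0.8, 0.2], [4.0, 2.0])
        t_ns = np.arange(0.0, 32.0, 0.016)
        irf = np.exp(-0.5 * ((t_ns - 1.0) / 0.108) ** 2)  # FWHM ~254 ps
        decays = []
        truth_tcspc = []
        nf = len(system.fret_pairs)
        for i in range(nf):
            model = tcspc_mod.GaussianMixtureDistance(
                r1=pred_m1[i], r2=pred_m2[i], w=width_da, x1=system.x_m1, x_donly=0.0
            )
            decays.append(
                tcspc_mod.simulate_decay(
                    model, donor_ref, t_ns, irf, total_counts=tcspc_counts,
                    seed=int(rng.integers(2**31)),
                )
            )
            truth_tcspc.append(model)
        bundle["tcspc"] = {"decays": decays, "donor_ref": donor_ref, "truth": truth_tcspc}

    # --- DEER ---------------------------------------------------------------
    if "deer" in include:
        rng = rngs["deer"]
        r_nm = np.arange(1.5, 8.0001, 0.05)
        kernel = deer_mod.build_kernel(np.linspace(0.0, 4.0, 256), r_nm)
        deer_traces = []
        truth_deer = []
        offset = nf
        for i in range(len(system.spin_pairs)):
            mu1, mu2 = pred_m1[offset + i] / 10.0, pred_m2[offset + i] / 10.0  # A -> nm
            p = DistanceDistribution.gaussian_mixture(
                [mu1, mu2], 0.6, [system.x_m1, 1 - system.x_m1], r_nm, kind="spin"
            )
            trace = deer_mod.simulate_deer(
                p, kernel, modulation_depth=0.4, background_rate=0.08,
                noise_sd=deer_noise_sd, seed=int(rng.integers(2**31)),
            )
            deer_traces.append(trace)
            truth_deer.append(p)
        bundle["deer"] = {"traces": deer_traces, "kernel": kernel, "truth": truth_deer}

    # --- fFCS ---------------------------------------------------------------
    if "ffcs" in include:
        rng = rngs["ffcs"]
        times_s = system.relaxation_times_s
        n_times = len(times_s)
        lag = np.unique(np.geomspace(2e-7, 0.05, 80))
        curves = []
        truth_ffcs = {"times_s": times_s}
        nv = n_variants_ffcs if n_variants_ffcs is not None else nf
        for i in range(nv):
            amps = rng.dirichlet(np.ones(n_times) * 2.0)
            amps3 = tuple(amps) + (0.0,) * (3 - n_times)
            times3 = tuple(times_s) + (1.0,) * (3 - n_times)
            model = ffcs_mod.KineticModel(
                n_eff={
                    "HH": rng.uniform(0.5, 2.0),
                    "LL": rng.uniform(0.5, 2.0),
                    "CC": rng.uniform(0.5, 2.0),
                },
                t_diff=rng.uniform(5e-4, 2e-3),
                a0={"LH": rng.uniform(0.3, 0.8), "HL": rng.uniform(0.3, 0.8)},
                times=times3,
                amplitudes=amps3,
                acf_amplitudes={
                    "HH": tuple(rng.uniform(0.05, 0.3, 3)),
                    "LL": tuple(rng.uniform(0.05, 0.3, 3)),
                },
            )
            for kind in ffcs_mod.CURVE_KINDS:
                g = ffcs_mod.fcs_model(lag, model, kind)
                sd = np.full_like(g, ffcs_noise_sd)
                curves.append(
                    ffcs_mod.CorrCurve(
                        lag=lag,
                        g=g + rng.normal(0, ffcs_noise_sd, size=g.shape),
                        sd=sd,
                        kind=kind,
                        variant=f"v{i:02d}",
                    )
                )
            truth_ffcs[f"v{i:02d}"] = model
        bundle["ffcs"] = {"curves": curves, "truth": truth_ffcs}

    # --- NSE ----------------------------------------------------------------
    if "nse" in include:
        rng = rngs["nse"]
        tensor1 = nse_mod.kirkwood_tensor(system.m1.coords * 0.1, 0.3)
        tensor2 = nse_mod.kirkwood_tensor(system.m2.coords * 0.1, 0.3)
        hydro = nse_mod.HydroParams(h_t=0.61, h_r=nse_mod.ht_to_hr(0.61))
        t_nse = np.linspace(0.0, 150.0, 40)
        nse_curves = []
        for q in (0.3, 0.6, 0.9, 1.2):
            c1 = nse_mod.isf_model(system.m1, tensor1, hydro, q, t_nse)
            c2 = nse_mod.isf_model(system.m2, tensor2, hydro, q, t_nse)
            i_mix = system.x_m1 * c1.i_norm + (1 - system.x_m1) * c2.i_norm
            noise = rng.normal(0, nse_noise_sd, size=i_mix.shape)
            noise[0] = 0.0  # t = 0 normalization point
            nse_curves.append(
                nse_mod.NseCurve(q=q, t=t_nse, i_norm=i_mix + noise,
                                 sd=np.full_like(i_mix, max(nse_noise_sd, 1e-6)))
            )
        bundle["nse"] = {"curves": nse_curves,
                         "truth": {"tensor_m1": tensor1, "tensor_m2": tensor2,
                                   "hydro": hydro}}

    # --- SAXS ---------------------------------------------------------------
    if "saxs" in include:
        rng = rngs["saxs"]
        q_saxs = np.linspace(0.008, 0.35, 120)
        s1 = saxs_mod.debye_scatter(system.m1, q_saxs)
        s2 = saxs_mod.debye_scatter(system.m2, q_saxs)
        i_mix = system.x_m1 * s1.i + (1 - system.x_m1) * s2.i
        noise_sd = saxs_noise_frac * i_mix + 1e-12
        saxs_data = saxs_mod.SaxsCurve(
            q=q_saxs,
            i=i_mix + rng.normal(0, noise_sd),
            sigma=saxs_sigma_inflation * noise_sd,
        )

        bundle["saxs"] = {"data": saxs_data, "m1": s1, "m2": s2, "x_m1": system.x_m1}
    return bundle


def candidate_ensemble(
    system: ToySystem,
    n_decoys: int = 8,
    perturbation_scale: float = 1.0,
    seed: int = 0,
) -> list[dict]:
    """Truth structures plus hinge/rigid-body decoys of graded RMSD.

    Each entry is ``{"structure", "kind", "rmsd_m1", "rmsd_m2"}`` where the
    RMSDs are Kabsch-aligned against the two truth conformers.  Decoys are
    generated by extra hinge rotations and rigid-body displacements scaled by
    ``perturbation_scale`` (0 gives copies of the truth).
    """
    if n_decoys < 1:
        raise ValueError("need at least one decoy")
    rng = np.random.default_rng(seed)
    out = [
        {"structure": system.m1, "kind": "truth_m1"},
        {"structure": system.m2, "kind": "truth_m2"},
    ]
    body_tags = system.m1.rigid_body
    n_bodies = int(body_tags.max()) + 1
    for i in range(n_decoys):
        base = system.m1 if i % 2 == 0 else system.m2
        coords = base.coords.copy()
        # one or two distal-block rotations so global alignment cannot
        # absorb the perturbation; graded angles give graded RMSDs
        n_moves = 1 + int(rng.random() < 0.5)
        for _ in range(n_moves):
            first_moving = int(rng.integers(1, n_bodies))
            moving = body_tags >= first_moving
            pivot = coords[np.flatnonzero(~moving)[-1]]
            angle = perturbation_scale * rng.uniform(5.0, 160.0) * np.deg2rad(1.0)
            axis = rng.normal(size=3)
            R = _rotation_matrix(axis, angle)
            shift = perturbation_scale * rng.normal(0, 4.0, size=3)
            coords[moving] = (coords[moving] - pivot) @ R.T + pivot + shift
        decoy = CoarseStructure(
            coords=coords,
            radii=base.radii,
            weights=base.weights,
            residue_ids=base.residue_ids,
            rigid_body=base.rigid_body,
            label=f"decoy{i:02d}",
        )
        out.append({"structure": decoy, "kind": f"decoy{i:02d}"})
    for entry in out:
        entry["rmsd_m1"] = rmsd(entry["structure"].coords, system.m1.coords)
        entry["rmsd_m2"] = rmsd(entry["structure"].coords, system.m2.coords)
    return out


def simulate_telegraph(
    rate_matrix_per_us: np.ndarray,
    n_bins: int,
    bin_time_us: float,
    seed: int = 0,
) -> np.ndarray:
    """Discrete-time state trajectory of a Markov exchange process.

    The transition matrix over one bin is ``expm(K dt)``; used as a slow
    photon-level oracle for the analytic fFCS constructions.
    """
    from scipy.linalg import expm

    K = np.asarray(rate_matrix_per_us, float)
    n_states = K.shape[0]
    P = expm(K * bin_time_us)  # columns: from-state
    P = np.clip(P, 0, None)
    P /= P.sum(axis=0, keepdims=True)
    rng = np.random.default_rng(seed)
    # start from equilibrium (null vector of K)
    w, v = np.linalg.eig(K)
    pi = np.real(v[:, np.argmin(np.abs(w))])
    pi = np.abs(pi) / np.abs(pi).sum()
    states = np.empty(n_bins, dtype=np.intp)
    states[0] = rng.choice(n_states, p=pi)
    cum = np.cumsum(P, axis=0)
    u = rng.random(n_bins)
    for i in range(1, n_bins):
        states[i] = np.searchsorted(cum[:, states[i - 1]], u[i])
    return states
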