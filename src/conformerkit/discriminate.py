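"""Fisher-method discrimination of candidate conformer pairs.

A conformationally heterogeneous ensemble approximated by two states (M1,
M2) is modeled by *pairs* of candidate structures.  Every pair is scored
against the label-based distance restraints (FRET and DEER) by an
uncertainty-weighted chi-square and against SAXS by a two-state mixture fit;
the two probabilities are fused by Fisher's method,

    X^2 = -2 ln(p_label * p_SAXS) ~ chi^2(2k),

and pairs with a combined p-value below the confidence threshold are
rejected.  Because redundant restraints inflate the nominal degrees of
freedom, an effective dof is estimated by greedy backward elimination:
restraints whose removal leaves the pair ranking unchanged are uninformative.

Ensemble precision is reported as the SD of all pairwise C-alpha distances
over the accepted ensemble, normalized by the same quantity for reference
ensembles regenerated from restraints resampled within their experimental
uncertainties, plus per-residue RMSF after iterative global superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .labels import LabelSite, MTSSL_SITE_DEFAULTS, compute_av, apply_acv, \
    distance_distribution, fret_observables, subsample_cloud, InaccessibleSiteError
from .structure import CoarseStructure, superpose

__all__ = [
    "RestraintTable",
    "ScoredPair",
    "EnsembleMetrics",
    "predict_distances",
    "chi2_labels",
    "estimate_effective_dof",
    "chi2_to_pvalue",
    "fisher_combine",
    "score_pairs",
    "select_pairs",
    "ensemble_precision",
]


@dataclass
class RestraintTable:
    """Experimental distance restraints with state assignments.

    Columns: pair_id, technique (FRET | DEER), state (M1 | M2 | shared),
    residue_1, residue_2, distance_A, sigma_minus, sigma_plus.
    """

    table: pd.DataFrame

    REQUIRED = (
        "pair_id",
        "technique",
        "state",
        "residue_1",
        "residue_2",
        "distance_A",
        "sigma_minus",
        "sigma_plus",
    )

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"restraint table lacks columns: {sorted(missing)}")
        if (self.table[["sigma_minus", "sigma_plus"]] <= 0).any().any():
            raise ValueError("uncertainties must be positive")
        bad = ~self.table["state"].isin(["M1", "M2", "shared"])
        if bad.any():
            raise ValueError("state must be one of M1, M2, shared")

    def __len__(self):
        return len(self.table)

    @classmethod
    def load_csv(cls, path):
        return cls(table=pd.read_csv(path))

    def save_csv(self, path):
        self.table.to_csv(path, index=False)

    def subset(self, keep_index) -> "RestraintTable":
        return RestraintTable(table=self.table.loc[keep_index].reset_index(drop=True))

    def with_distances(self, new_distances) -> "RestraintTable":
        t = self.table.copy()
        t["distance_A"] = np.asarray(new_distances, float)
        return RestraintTable(table=t)

    def swapped_states(self) -> "RestraintTable":
        t = self.table.copy()
        t["state"] = t["state"].map({"M1": "M2", "M2": "M1", "shared": "shared"})
        return RestraintTable(table=t)


def predict_distances(
    structure: CoarseStructure,
    restraints: RestraintTable,
    fret_site_params: dict | None = None,
    spin_site_params: dict | None = None,
    grid_spacing: float = 2.0,
    R0: float = 52.0,
    max_cloud_points: int = 1200,
    _cache: dict | None = None,
) -> np.ndarray:
    """AV/ACV model distances for every restraint row on one structure.

    FRET rows report the FRET-averaged distance (R0-weighted); DEER rows the
    mean inter-cloud distance.  Clouds larger than ``max_cloud_points`` are
    subsampled (weight-proportionally, seeded) before the pairwise average.
    ``_cache`` avoids recomputing clouds and per-pair observables across rows
    and candidates.
    """
    fret_site_params = fret_site_params or {}
    spin_site_params = dict(MTSSL_SITE_DEFAULTS, **(spin_site_params or {}))

    def cloud(resid, technique):
        key = (id(structure), resid, technique)
        if _cache is not None and key in _cache:
            return _cache[key]
        params = fret_site_params if technique == "FRET" else spin_site_params
        site = LabelSite(residue_id=int(resid), **params)
        cl = compute_av(structure, site, grid_spacing=grid_spacing)
        if site.contact_fraction > 0:
            cl = apply_acv(cl, site, structure)
        cl = subsample_cloud(cl, max_cloud_points, seed=int(resid))
        if _cache is not None:
            _cache[key] = cl
        return cl

    out = np.empty(len(restraints))
    for i, row in restraints.table.iterrows():
        okey = (id(structure), int(row.residue_1), int(row.residue_2), row.technique)
        if _cache is not None and okey in _cache:
            out[i] = _cache[okey]
            continue
        c1 = cloud(row.residue_1, row.technique)
        c2 = cloud(row.residue_2, row.technique)
        if row.technique == "FRET":
            val = fret_observables(c1, c2, R0=R0)["fret_averaged_distance"]
        else:
            val = distance_distribution(c1, c2, nbins=64).mean()
        if _cache is not None:
            _cache[okey] = val
        out[i] = val
    return out


def chi2_labels(
    pred_m1: np.ndarray,
    pred_m2: np.ndarray,
    restraints: RestraintTable,
) -> tuple[float, bool]:
    """Uncertainty-weighted label chi-square of an (M1, M2) candidate pair.

    ``pred_m1``/``pred_m2`` are per-row model distances on the two candidate
    structures.  State-specific rows are evaluated on the assigned member,
    shared rows on both; the assignment swap (M1 <-> M2) is also evaluated
    and the minimum taken.

    Returns (chi2, swapped).
    """

    def one_assignment(p1, p2):
        total = 0.0
        for i, row in restraints.table.iterrows():
            preds = {
                "M1": (p1[i],),
                "M2": (p2[i],),
                "shared": (p1[i], p2[i]),
            }[row.state]
            for pred in preds:
                dev = pred - row.distance_A
                sigma = row.sigma_plus if dev > 0 else row.sigma_minus
                total += (dev / sigma) ** 2
        return total

    direct = one_assignment(pred_m1, pred_m2)
    swapped = one_assignment(pred_m2, pred_m1)
    if swapped < direct:
        return float(swapped), True
    return float(direct), False


def chi2_to_pvalue(chi2: float, k: float) -> float:
    """Upper-tail chi-square probability (survival function)."""
    if k < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.chi2.sf(chi2, k))


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: X^2 = -2 sum ln p, combined p from chi^2(2k)."""
    p = np.asarray(p_values, float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("zero p-value clipped to float tiny", RuntimeWarning)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x2 = float(-2.0 * np.sum(np.log(p)))
    return x2, float(stats.chi2.sf(x2, 2 * len(p)))


def estimate_effective_dof(
    chi2_per_restraint: np.ndarray,
    correlation_threshold: float = 0.9,
) -> int:
    """Effective number of informative restraints by backward elimination.

    ``chi2_per_restraint`` is the (n_restraints, n_candidate_pairs) matrix of
    per-restraint chi-square contributions.  Restraints are removed greedily,
    each time dropping the one whose removal best preserves the Spearman
    correlation between the reduced and the full candidate ranking; removal
    stops when the correlation would fall below ``correlation_threshold``.
    The retained count is the effective dof (at least 1).
    """
    contrib = np.atleast_2d(np.asarray(chi2_per_restraint, float))
    n = contrib.shape[0]
    if n == 1:
        return 1
    full = contrib.sum(axis=0)
    active = list(range(n))
    while len(active) > 1:
        best_rho, best_j = -np.inf, None
        for j in active:
            reduced = contrib[[i for i in active if i != j]].sum(axis=0)
            rho = stats.spearmanr(full, reduced).statistic
            if rho > best_rho:
                best_rho, best_j = rho, j
        if best_rho < correlation_threshold:
            break
        active.remove(best_j)
    return max(len(active), 1)


@dataclass
class ScoredPair:
    """Scores of one (M1, M2) candidate pair."""

    m1_id: str
    m2_id: str
    chi2_labels: float
    chi2_saxs: float
    dof_labels: float
    dof_saxs: float
    p_labels: float
    p_saxs: float
    fisher_x2: float
    p_combined: float
    saxs_fraction_m1: float = np.nan
    swapped: bool = False
    valid: bool = True


def score_pairs(
    label_chi2: dict,
    saxs_chi2: dict,
    dof_labels: float,
    dof_saxs: float,
    saxs_fractions: dict | None = None,
    swapped_flags: dict | None = None,
) -> list[ScoredPair]:
    """Assemble ScoredPair records from per-pair chi-square maps.

    ``label_chi2`` and ``saxs_chi2`` map (m1_id, m2_id) -> chi2.
    """
    out = []
    for key, c_lab in label_chi2.items():
        c_sax = saxs_chi2[key]
        p_lab = chi2_to_pvalue(c_lab, dof_labels)
        p_sax = chi2_to_pvalue(c_sax, dof_saxs)
        x2, p_comb = fisher_combine([p_lab, p_sax])
        out.append(
            ScoredPair(
                m1_id=key[0],
                m2_id=key[1],
                chi2_labels=c_lab,
                chi2_saxs=c_sax,
                dof_labels=dof_labels,
                dof_saxs=dof_saxs,
                p_labels=p_lab,
                p_saxs=p_sax,
                fisher_x2=x2,
                p_combined=p_comb,
                saxs_fraction_m1=(saxs_fractions or {}).get(key, np.nan),
                swapped=(swapped_flags or {}).get(key, False),
            )
        )
    return out


def select_pairs(scored: list[ScoredPair], confidence: float = 0.68):
    """Keep pairs whose combined p-value meets the confidence threshold.

    Returns (accepted list, rejection fraction).
    """
    if not scored:
        raise ValueError("no scored pairs supplied")
    accepted = [s for s in scored if s.valid and s.p_combined >= confidence]
    frac_rejected = 1.0 - len(accepted) / len(scored)
    return accepted, frac_rejected


def evaluate_candidates(
    structures: dict,
    restraints: RestraintTable,
    saxs_data=None,
    saxs_curves: dict | None = None,
    grid_spacing: float = 2.0,
    confidence: float = 0.68,
    dof_mode: str = "raw",
    d_max: float | None = None,
) -> dict:
    """Full discrimination pipeline over a candidate structure pool.

    ``structures`` maps id -> CoarseStructure; every ordered (M1, M2) pair of
    distinct candidates is scored against the label restraints (AV-predicted
    distances) and, when ``saxs_data`` and per-candidate ``saxs_curves`` are
    given, against SAXS via the two-state mixture fit.  Label dof defaults to
    the raw restraint count; ``dof_mode='effective'`` switches to greedy
    backward elimination, which is informative for large diverse candidate
    pools but degenerates (k_eff -> 1) when every decoy violates every
    restraint, so it is exposed for stability analysis rather than as the
    default.  SAXS dof is the Shannon-channel count when ``d_max`` is given,
    else the point count minus the three fitted scalars.

    Returns scored pairs, the accepted subset at ``confidence`` and the
    per-structure prediction table.
    """
    from . import saxs as saxs_mod

    cache: dict = {}
    preds = {}
    for name, st in structures.items():
        try:
            preds[name] = predict_distances(
                st, restraints, grid_spacing=grid_spacing, _cache=cache
            )
        except InaccessibleSiteError:
            preds[name] = None  # buried label site: candidate invalid
    names = list(structures)
    all_keys = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    invalid_keys = [k for k in all_keys if preds[k[0]] is None or preds[k[1]] is None]
    pair_keys = [k for k in all_keys if k not in invalid_keys]

    label_chi2, swapped_flags = {}, {}
    contrib = np.zeros((len(restraints), len(pair_keys)))
    for j, (a, b) in enumerate(pair_keys):
        chi2, swapped = chi2_labels(preds[a], preds[b], restraints)
        label_chi2[(a, b)] = chi2
        swapped_flags[(a, b)] = swapped
        pa, pb = (preds[b], preds[a]) if swapped else (preds[a], preds[b])
        for i, row in restraints.table.iterrows():
            targets = {"M1": (pa[i],), "M2": (pb[i],), "shared": (pa[i], pb[i])}[row.state]
            for pred in targets:
                dev = pred - row.distance_A
                sigma = row.sigma_plus if dev > 0 else row.sigma_minus
                contrib[i, j] += (dev / sigma) ** 2

    if dof_mode == "effective" and len(restraints) > 1:
        dof_labels = estimate_effective_dof(contrib)
    else:
        dof_labels = len(restraints)

    saxs_chi2, saxs_fracs = {}, {}
    if saxs_data is not None and saxs_curves:
        # information content: Shannon channels when D_max is known,
        # otherwise point count minus the three fitted scalars
        if d_max is not None:
            dof_saxs = max(
                saxs_mod.shannon_channels(saxs_data.q.min(), saxs_data.q.max(), d_max),
                1.0,
            )
        else:
            dof_saxs = max(len(saxs_data.q) - 3.0, 1.0)
        for key in pair_keys:
            fit = saxs_mod.two_state_fit(saxs_curves[key[0]], saxs_curves[key[1]], saxs_data)
            saxs_chi2[key] = fit.chi2_reduced * dof_saxs
            saxs_fracs[key] = fit.fraction
    else:
        dof_saxs = 1.0
        saxs_chi2 = {key: 0.0 for key in pair_keys}

    scored = score_pairs(label_chi2, saxs_chi2, dof_labels, dof_saxs,
                         saxs_fractions=saxs_fracs, swapped_flags=swapped_flags)
    for a, b in invalid_keys:
        scored.append(
            ScoredPair(
                m1_id=a, m2_id=b, chi2_labels=np.nan, chi2_saxs=np.nan,
                dof_labels=dof_labels, dof_saxs=dof_saxs, p_labels=np.nan,
                p_saxs=np.nan, fisher_x2=np.nan, p_combined=0.0, valid=False,
            )
        )
    accepted, frac_rejected = select_pairs(scored, confidence=confidence)
    return {
        "scored": scored,
        "accepted": accepted,
        "rejection_fraction": frac_rejected,
        "predictions": preds,
        "dof_labels": dof_labels,
        "dof_saxs": dof_saxs,
    }


@dataclass
class EnsembleMetrics:
    """Precision metrics of an accepted structural ensemble."""

    sd_matrix: np.ndarray
    sd_ref_matrix: np.ndarray
    normalized: np.ndarray
    rmsf: np.ndarray


def _pairwise_sd(ensembles: list[np.ndarray]) -> np.ndarray:
    stack = np.array(
        [np.sqrt(np.sum((c[:, None] - c[None, :]) ** 2, axis=-1)) for c in ensembles]
    )
    return stack.std(axis=0)


def ensemble_rmsf(coords_list: list[np.ndarray], n_iter: int = 3) -> np.ndarray:
    """Per-residue RMSF after iterative superposition to the ensemble mean."""
    aligned = [c.copy() for c in coords_list]
    mean = aligned[0]
    for _ in range(n_iter):
        aligned = [superpose(c, mean) for c in aligned]
        mean = np.mean(aligned, axis=0)
    diffs = np.array(aligned) - mean
    return np.sqrt(np.mean(np.sum(diffs**2, axis=-1), axis=0))


def ensemble_precision(
    accepted_coords: list[np.ndarray],
    reference_ensembles: list[list[np.ndarray]],
) -> EnsembleMetrics:
    """Pairwise-distance SD of the accepted ensemble, normalized by reference.

    ``reference_ensembles`` are accepted ensembles regenerated under
    restraints resampled within their uncertainties with the best model as
    ground truth (one list per resampling seed); their mean pairwise SD is
    the reference precision.
    """
    shapes = {c.shape for c in accepted_coords}
    if len(shapes) != 1:
        raise ValueError("ensemble members must share residue indexing")
    sd = _pairwise_sd(accepted_coords)
    refs = [_pairwise_sd(e) for e in reference_ensembles if len(e) > 1]
    if not refs:
        raise ValueError("reference ensembles need at least two members")
    sd_ref = np.mean(refs, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(sd_ref > 0, sd / np.where(sd_ref > 0, sd_ref, 1.0), np.nan)
    return EnsembleMetrics(
        sd_matrix=sd,
        sd_ref_matrix=sd_ref,
        normalized=normalized,
        rmsf=ensemble_rmsf(accepted_coords),
    )
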