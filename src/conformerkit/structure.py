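"""Coarse bead-model structures and rigid-body geometry utilities.

A :class:`CoarseStructure` is the common in-memory representation used by the
label-simulation, SAXS and NSE forward models: a set of beads with coordinates
(angstrom), radii, scattering weights and residue/chain bookkeeping, optionally
tagged with rigid-body membership.  Bead models are typically one bead per
residue (C-alpha like) so standard PDB records can carry them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover - gemmi is a hard dependency
    gemmi = None

__all__ = [
    "CoarseStructure",
    "kabsch_rotation",
    "superpose",
    "rmsd",
    "pairwise_distances",
]


@dataclass
class CoarseStructure:
    """Bead model of a (multi-domain) protein.

    Parameters
    ----------
    coords : (N, 3) float array
        Bead coordinates in angstrom.
    radii : (N,) float array
        Per-bead hard-sphere radii in angstrom (> 0).
    weights : (N,) float array
        Per-bead scattering weights ``b_i`` (arbitrary units).
    residue_ids : (N,) int array
        Residue numbering used to address label sites.
    chain_ids : sequence of str
        Per-bead chain identifier.
    rigid_body : (N,) int array, optional
        Rigid-body membership tag per bead.
    """

    coords: np.ndarray
    radii: np.ndarray
    weights: np.ndarray
    residue_ids: np.ndarray = None
    chain_ids: np.ndarray = None
    rigid_body: np.ndarray = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.coords)
        if n == 0:
            raise ValueError("structure must contain at least one bead")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("bead coordinates must be finite")
        self.radii = np.broadcast_to(
            np.asarray(self.radii, dtype=float), (n,)
        ).copy()
        if np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        self.weights = np.broadcast_to(
            np.asarray(self.weights, dtype=float), (n,)
        ).copy()
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, n + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.chain_ids is None:
            self.chain_ids = np.array(["A"] * n)
        else:
            self.chain_ids = np.asarray(self.chain_ids)
        if self.rigid_body is not None:
            self.rigid_body = np.asarray(self.rigid_body, dtype=int)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_pdb(cls, path, bead_radius: float = 1.9, atom_name: str = "CA"):
        """Read a bead model from PDB/mmCIF, one bead per ``atom_name`` atom.

        The default radius (1.9 angstrom) is a C-alpha-like excluded-volume
        radius; scattering weights default to 1 per bead.
        """
        if gemmi is None:
            raise ImportError("gemmi is required for structure I/O")
        st = gemmi.read_structure(str(path))
        coords, resids, chains = [], [], []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom_name is None or atom.name == atom_name:
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        resids.append(res.seqid.num)
                        chains.append(chain.name)
        if not coords:
            raise ValueError(f"no '{atom_name}' atoms found in {path}")
        return cls(
            coords=np.array(coords),
            radii=bead_radius,
            weights=1.0,
            residue_ids=np.array(resids),
            chain_ids=np.array(chains),
            label=str(path),
        )

    def to_pdb(self, path):
        """Write the bead model as a PDB file (one CA atom per bead)."""
        if gemmi is None:
            raise ImportError("gemmi is required for structure I/O")
        st = gemmi.Structure()
        st.name = self.label or "bead model"
        model = gemmi.Model("1")
        for cname in np.unique(self.chain_ids):
            chain = gemmi.Chain(str(cname))
            sel = np.flatnonzero(self.chain_ids == cname)
            for i in sel:
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(int(self.residue_ids[i]), " ")
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.pos = gemmi.Position(*self.coords[i])
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))

    # -- queries -------------------------------------------------------------

    def __len__(self):
        return len(self.coords)

    def site_coord(self, residue_id: int, chain_id: str | None = None) -> np.ndarray:
        """Coordinate of the bead addressed by residue (and optional chain) id."""
        mask = self.residue_ids == residue_id
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"residue {residue_id} not found in structure")
        return self.coords[idx[0]].copy()

    def centered(self) -> "CoarseStructure":
        """Copy translated so the weight-averaged center sits at the origin."""
        w = self.weights / self.weights.sum()
        center = w @ self.coords
        return self.transformed(np.eye(3), -center)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = CoarseStructure(
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            radii=self.radii,
            weights=self.weights,
            residue_ids=self.residue_ids,
            chain_ids=self.chain_ids,
            rigid_body=self.rigid_body,
            label=self.label,
        )
        return out

    def radius_of_gyration(self) -> float:
        w = self.weights / self.weights.sum()
        center = w @ self.coords
        return float(np.sqrt(np.sum(w * np.sum((self.coords - center) ** 2, axis=1))))


def pairwise_distances(coords_a: np.ndarray, coords_b: np.ndarray | None = None):
    """Dense Euclidean distance matrix between two coordinate sets."""
    a = np.asarray(coords_a, dtype=float)
    b = a if coords_b is None else np.asarray(coords_b, dtype=float)
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return np.sqrt(d2)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray, weights=None):
    """Optimal rotation superposing centered ``mobile`` onto centered ``target``."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, float)
    w = w / w.sum()
    mc = w @ mobile
    tc = w @ target
    H = (mobile - mc).T @ ((target - tc) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mc, tc


def superpose(mobile: np.ndarray, target: np.ndarray, weights=None) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``target`` (Kabsch)."""
    R, mc, tc = kabsch_rotation(mobile, target, weights)
    return (np.asarray(mobile, float) - mc) @ R.T + tc


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, align: bool = True) -> float:
    """RMSD between two conformations of the same bead topology."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have identical shape")
    if align:
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
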