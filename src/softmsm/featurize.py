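"""Trajectory featurization: inter-residue distances, dihedrals, contacts.

The flagship feature set is the flattened matrix of nearest-neighbour
heavy-atom distances between residue pairs separated by at least
``min_seq_sep`` positions in sequence — for a 42-residue chain with the
default separation of 3 this yields 780 input dimensions. Distance
computations go through mdtraj and apply the minimum-image convention
whenever box vectors are present.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import ContactSeries, DistanceSeries, FeatureSeries, TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "residue_pairs",
    "nn_distance_features",
    "backbone_dihedrals",
    "chi1_dihedrals",
    "ligand_min_distances",
    "detect_pi_stacks",
    "circular_embed",
]

#: Aromatic side-chain ring atom names, used to build default ring definitions.
AROMATIC_RING_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HSD": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HSE": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def _wrap(theta: np.ndarray) -> np.ndarray:
    return np.mod(theta + np.pi, 2 * np.pi) - np.pi


def _peptide_residues(topology, ligand_resname: str | None):
    return [r for r in topology.residues
            if ligand_resname is None or r.name != ligand_resname]


def residue_pairs(n_residues: int, min_seq_sep: int = 3) -> list[tuple[int, int]]:
    """Ordered (i, j) residue index pairs with j - i >= min_seq_sep.

    Row-major: for each i ascending, all j > i. The count for n residues
    and separation s is (n - s)(n - s + 1)/2.
    """
    if min_seq_sep < 1:
        raise ValueError("min_seq_sep must be >= 1")
    return [(i, j) for i in range(n_residues)
            for j in range(i + min_seq_sep, n_residues)]


def nn_distance_features(
    ensemble: TrajectoryEnsemble, min_seq_sep: int = 3
) -> FeatureSeries:
    """Nearest-neighbour heavy-atom distances per eligible residue pair.

    Each feature is the minimum over all heavy-atom pairs of the
    Euclidean (minimum-image, if a box is present) distance between two
    residues at sequence separation >= min_seq_sep.
    """
    import mdtraj as md

    top = ensemble.topology
    residues = _peptide_residues(top, ensemble.ligand_resname)
    for r in residues:
        if not any(a.element.symbol != "H" for a in r.atoms):
            raise ValueError(f"residue {r} has no heavy atoms")
    pairs = residue_pairs(len(residues), min_seq_sep)
    if not pairs:
        warnings.warn(
            f"no residue pair at separation >= {min_seq_sep} for "
            f"{len(residues)} residues; feature set is empty"
        )
        return FeatureSeries(
            [np.zeros((t.n_frames, 0)) for t in ensemble.trajectories],
            [], ensemble.frame_interval_ps, "nm")
    index_pairs = [(residues[i].index, residues[j].index) for i, j in pairs]
    arrays = []
    for t in ensemble.trajectories:
        d, _ = md.compute_contacts(t, contacts=index_pairs, scheme="closest-heavy",
                                   periodic=True)
        arrays.append(np.asarray(d, dtype=float))
    labels = [(residues[i].resSeq, residues[j].resSeq) for i, j in pairs]
    return FeatureSeries(arrays, labels, ensemble.frame_interval_ps, "nm")


def backbone_dihedrals(ensemble: TrajectoryEnsemble) -> FeatureSeries:
    """phi and psi per residue; undefined terminal angles are NaN."""
    import mdtraj as md

    top = ensemble.topology
    residues = _peptide_residues(top, ensemble.ligand_resname)
    n = len(residues)
    res_pos = {r.index: i for i, r in enumerate(residues)}
    arrays = []
    for t in ensemble.trajectories:
        out = np.full((t.n_frames, 2 * n), np.nan)
        phi_idx, phi = md.compute_phi(t)
        psi_idx, psi = md.compute_psi(t)
        for col, quad in enumerate(phi_idx):
            r = top.atom(int(quad[1])).residue.index  # N atom of the residue
            if r in res_pos:
                out[:, res_pos[r]] = phi[:, col]
        for col, quad in enumerate(psi_idx):
            r = top.atom(int(quad[0])).residue.index
            if r in res_pos:
                out[:, n + res_pos[r]] = psi[:, col]
        arrays.append(_wrap(out))
    labels = [(r.resSeq, "phi") for r in residues] + [(r.resSeq, "psi") for r in residues]
    missing = np.isnan(arrays[0][0])
    n_missing = int(missing.sum())
    if n_missing > 2:  # more than the two undefined terminal angles
        logger.warning("%d backbone dihedrals undefined (missing atoms?)", n_missing)
    return FeatureSeries(arrays, labels, ensemble.frame_interval_ps, "rad")


def chi1_dihedrals(ensemble: TrajectoryEnsemble) -> FeatureSeries:
    """chi1 angle series for every residue that defines one."""
    import mdtraj as md

    top = ensemble.topology
    arrays_per_traj = []
    labels = None
    for t in ensemble.trajectories:
        idx, chi = md.compute_chi1(t)
        cols = []
        labs = []
        for col, quad in enumerate(idx):
            r = top.atom(int(quad[0])).residue
            if ensemble.ligand_resname is not None and r.name == ensemble.ligand_resname:
                continue
            cols.append(_wrap(chi[:, col]))
            labs.append((r.resSeq, "chi1"))
        if labels is None:
            labels = labs
        arrays_per_traj.append(
            np.stack(cols, axis=1) if cols else np.zeros((t.n_frames, 0)))
    if not labels:
        warnings.warn("no residue with a defined chi1 angle (Gly/Ala-only chain?)")
        labels = []
    return FeatureSeries(arrays_per_traj, labels, ensemble.frame_interval_ps, "rad")


def _heavy_atom_indices(residue) -> list[int]:
    return [a.index for a in residue.atoms if a.element.symbol != "H"]


def ligand_min_distances(
    ensemble: TrajectoryEnsemble, level: str = "residue"
) -> DistanceSeries:
    """Minimum heavy-atom distances between the ligand and the peptide.

    level="residue": one column per peptide residue, the minimum distance
    from any ligand heavy atom to any heavy atom of that residue.
    level="atom": one column per ligand heavy atom, the minimum distance
    to any peptide heavy atom.
    """
    import mdtraj as md

    if ensemble.ligand_resname is None:
        raise ValueError("ensemble has no ligand selection")
    top = ensemble.topology
    lig_res = [r for r in top.residues if r.name == ensemble.ligand_resname]
    if not lig_res:
        raise ValueError(f"no residue named {ensemble.ligand_resname!r} in topology")
    lig_atoms = [i for r in lig_res for i in _heavy_atom_indices(r)]
    pep_res = _peptide_residues(top, ensemble.ligand_resname)
    if level == "residue":
        groups = [(_heavy_atom_indices(r), f"res{r.resSeq}") for r in pep_res]
    elif level == "atom":
        pep_atoms = [i for r in pep_res for i in _heavy_atom_indices(r)]
        groups = [([a], top.atom(a).name) for a in lig_atoms]
    else:
        raise ValueError("level must be 'residue' or 'atom'")

    arrays = []
    for t in ensemble.trajectories:
        cols = []
        for atoms, _ in groups:
            other = pep_atoms if level == "atom" else lig_atoms
            pairs = np.array([(a, b) for a in atoms for b in other])
            d = md.compute_distances(t, pairs, periodic=True)
            cols.append(d.min(axis=1))
        arrays.append(np.stack(cols, axis=1))
    return DistanceSeries(arrays, [g[1] for g in groups],
                          ensemble.frame_interval_ps, "nm")


def ring_centroids(traj, atom_indices: list[int]) -> np.ndarray:
    """Unweighted centroid of a ring's atoms, per frame."""
    if len(atom_indices) < 5:
        raise ValueError(f"a ring needs at least 5 atoms, got {len(atom_indices)}")
    return traj.xyz[:, atom_indices, :].mean(axis=1)


def _ring_normal(traj, atom_indices: list[int]) -> np.ndarray:
    xyz = traj.xyz[:, atom_indices, :]
    c = xyz.mean(axis=1, keepdims=True)
    x = xyz - c
    # smallest principal axis of the ring atoms = plane normal
    u, s, vt = np.linalg.svd(x)
    return vt[:, -1, :]


def default_ring_definitions(topology, ligand_resname: str,
                             ligand_rings: list[list[str]]) -> dict:
    """Ring name -> atom index list for ligand rings and aromatic residues."""
    rings = {}
    for r in topology.residues:
        if r.name == ligand_resname:
            atoms = {a.name: a.index for a in r.atoms}
            for i, names in enumerate(ligand_rings):
                rings[f"lig_ring{i + 1}"] = [atoms[n] for n in names]
        elif r.name in AROMATIC_RING_ATOMS:
            atoms = {a.name: a.index for a in r.atoms}
            names = AROMATIC_RING_ATOMS[r.name]
            if all(n in atoms for n in names):
                rings[f"{r.name}{r.resSeq}"] = [atoms[n] for n in names]
    return rings


def detect_pi_stacks(
    ensemble: TrajectoryEnsemble,
    ligand_rings: dict,
    residue_rings: dict,
    centroid_cutoff: float = 0.55,
    max_plane_angle: float | None = None,
) -> ContactSeries:
    """Per-frame ring-stacking indicator per (ligand ring, residue ring).

    The default criterion is purely geometric: ring-centroid distance at
    or below ``centroid_cutoff`` (nm). Passing ``max_plane_angle`` (in
    degrees) additionally requires the two ring planes to be within that
    angle of parallel.
    """
    arrays = []
    labels = [f"{ln}|{rn}" for ln in ligand_rings for rn in residue_rings]
    for t in ensemble.trajectories:
        cols = []
        for ln, l_atoms in ligand_rings.items():
            lc = ring_centroids(t, l_atoms)
            for rn, r_atoms in residue_rings.items():
                rc = ring_centroids(t, r_atoms)
                diff = lc - rc
                if t.unitcell_lengths is not None:
                    box = t.unitcell_lengths[:, None, :] if diff.ndim == 3 \
                        else t.unitcell_lengths
                    diff = diff - box * np.round(diff / box)
                on = np.linalg.norm(diff, axis=-1) <= centroid_cutoff
                if max_plane_angle is not None:
                    nl = _ring_normal(t, l_atoms)
                    nr = _ring_normal(t, r_atoms)
                    cosang = np.abs(np.sum(nl * nr, axis=-1))
                    on &= cosang >= np.cos(np.radians(max_plane_angle))
                cols.append(on)
        arrays.append(np.stack(cols, axis=1))
    return ContactSeries(arrays, labels, ensemble.frame_interval_ps,
                         cutoff_nm=centroid_cutoff)


def circular_embed(series: FeatureSeries, drop_nan: bool = True) -> FeatureSeries:
    """Embed angle features as (cos, sin) pairs for model input.

    Columns that are NaN in any frame (undefined terminal dihedrals) are
    dropped when drop_nan is set, keeping the model input finite.
    """
    if series.units != "rad":
        raise ValueError("circular_embed expects angle features in radians")
    keep = np.arange(series.n_features)
    if drop_nan:
        finite = np.ones(series.n_features, dtype=bool)
        for a in series.arrays:
            finite &= np.isfinite(a).all(axis=0)
        keep = np.where(finite)[0]
    arrays = []
    for a in series.arrays:
        sub = a[:, keep]
        arrays.append(np.concatenate([np.cos(sub), np.sin(sub)], axis=1))
    labels = [(series.labels[i], "cos") for i in keep] + \
             [(series.labels[i], "sin") for i in keep]
    return FeatureSeries(arrays, labels, series.frame_interval_ps, "dimensionless")
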