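"""Trajectory post-processing for the NBD1–ICL4 interface.

Metrics on coordinate trajectories of the CFTR domain interface between ICL4
(residues 1050–1080, human numbering) and the NBD1 loop around the F508del
site (residues 495–512): backbone-superposed RMSD, greedy RMSD-neighbor
(Daura) conformational clustering at a 0.1 nm cutoff, χ1 (N-Cα-Cβ-Cγ)
rotamer densities for interface side chains, and hydrogen-bond occupancy
under the 0.35 nm donor–acceptor / 30° hydrogen–donor–acceptor criterion.

Coordinates are handled in nm throughout. Multi-model PDB files (frames as
MODEL records) are read and written through biotite; residue numbering maps
(e.g. zebrafish→human offsets) are plain dicts applied to selections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "InterfaceSelection",
    "ClusterResult",
    "HBondSeries",
    "rmsd_fit",
    "superpose",
    "daura_cluster",
    "chi1_angle",
    "chi1_density",
    "hbond_series",
    "dihedral",
    "place_amide_hydrogen",
    "validate_unwrapped",
    "ca_superpose_rmsd",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "GAMMA_ATOMS",
]

#: γ atom by residue type for the χ1 dihedral (N-Cα-Cβ-γ).
GAMMA_ATOMS = {
    "SER": "OG", "THR": "OG1", "CYS": "SG", "ILE": "CG1", "VAL": "CG1",
}
# every other χ1-bearing residue uses CG


def _gamma_atom(res_name: str) -> str:
    return GAMMA_ATOMS.get(res_name.upper(), "CG")


@dataclass
class Trajectory:
    """Frames × atoms coordinate set (nm) with atom labels.

    ``atoms`` is a DataFrame with columns ``res_id``, ``res_name``,
    ``atom_name``, ``chain``; its row order matches the atom axis of
    ``coords`` (n_frames, n_atoms, 3).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_spacing: float = 500.0  # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table length must match coordinate atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, res_ids=None, atom_names=None, chain=None) -> np.ndarray:
        sel = np.ones(len(self.atoms), dtype=bool)
        if res_ids is not None:
            sel &= self.atoms["res_id"].isin(list(res_ids)).to_numpy()
        if atom_names is not None:
            sel &= self.atoms["atom_name"].isin(list(atom_names)).to_numpy()
        if chain is not None:
            sel &= (self.atoms["chain"] == chain).to_numpy()
        return np.flatnonzero(sel)


@dataclass(frozen=True)
class InterfaceSelection:
    """Residue ranges of the ICL4 / NBD1-loop interface and the backbone
    atoms used for superposition. Ranges are inclusive and in the numbering
    of the trajectory after ``numbering_map`` is applied (identity for human
    numbering; e.g. map zebrafish 1078 → human 1070 via an explicit dict)."""

    icl4_range: tuple[int, int] = (1050, 1080)
    nbd1_range: tuple[int, int] = (495, 512)
    backbone_atoms: tuple[str, ...] = ("N", "CA", "C")
    numbering_map: dict[int, int] = field(default_factory=dict)

    def residues(self) -> list[int]:
        res = list(range(self.icl4_range[0], self.icl4_range[1] + 1))
        res += list(range(self.nbd1_range[0], self.nbd1_range[1] + 1))
        if self.numbering_map:
            inv = {v: k for k, v in self.numbering_map.items()}
            res = [inv.get(r, r) for r in res]
        return res

    def backbone_indices(self, traj: Trajectory) -> np.ndarray:
        idx = traj.atom_indices(res_ids=self.residues(),
                                atom_names=self.backbone_atoms)
        if idx.size == 0:
            raise ValueError("selection matches no atoms in the trajectory")
        sub = traj.atoms.iloc[idx]
        for res_id, grp in sub.groupby("res_id"):
            missing = set(self.backbone_atoms) - set(grp["atom_name"])
            if missing:
                raise ValueError(f"residue {res_id} lacks backbone atoms {missing}")
        return idx


@dataclass(frozen=True)
class ClusterResult:
    assignments: np.ndarray   # frame -> cluster id (0-based, by rank)
    populations: np.ndarray   # fraction per cluster, non-increasing
    centers: np.ndarray       # representative frame per cluster
    cutoff: float


@dataclass(frozen=True)
class HBondSeries:
    """Per-bond boolean occupancy over frames, keyed by
    (donor atom index, hydrogen atom index, acceptor atom index)."""

    occupancy: dict[tuple[int, int, int], np.ndarray]
    d_cut: float
    a_cut: float
    n_frames: int
    hydrogens_reconstructed: bool = False

    def fraction(self, key) -> float:
        return float(np.mean(self.occupancy[key]))

    def counts_per_frame(self) -> np.ndarray:
        if not self.occupancy:
            return np.zeros(self.n_frames, dtype=int)
        return np.sum(list(self.occupancy.values()), axis=0)


# ---------------------------------------------------------------------------
# superposition / RMSD


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal rigid-body superposition (Kabsch) of ``mobile`` onto
    ``reference``; returns the transformed coordinates and the RMSD."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must share shape (n_atoms, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for a rigid superposition")
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    m_c = mobile - mu_m
    r_c = reference - mu_r
    if np.linalg.matrix_rank(m_c, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) atom configuration")
    rot, rssd = Rotation.align_vectors(r_c, m_c)
    moved = rot.apply(m_c) + mu_r
    return moved, float(rssd / math.sqrt(n))


def rmsd_fit(frame_a: np.ndarray, frame_b: np.ndarray,
             fit_atoms: np.ndarray | None = None) -> float:
    """RMSD (nm) between two frames after least-squares superposition on
    ``fit_atoms`` (all atoms when omitted); the RMSD is computed over the
    same atoms used for the fit."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if fit_atoms is not None:
        a = a[fit_atoms]
        b = b[fit_atoms]
    _, rmsd = superpose(b, a)
    return rmsd


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rmsd_fit(coords[i], coords[j])
    return d


def daura_cluster(
    traj: Trajectory,
    selection: InterfaceSelection | None = None,
    cutoff: float = 0.1,
) -> ClusterResult:
    """Greedy RMSD-neighbor (Daura) clustering of trajectory frames.

    Pairwise backbone-superposed RMSDs over the interface selection define a
    neighbor graph at ``cutoff`` (nm, boundary inclusive). Iteratively, the
    frame with the most unassigned neighbors becomes a cluster center (ties
    broken by lowest frame index); it and its neighbors form a cluster and
    leave the pool. Clusters are ranked by population (descending), ties in
    population by center frame index.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory must contain at least one frame")
    if selection is not None:
        idx = selection.backbone_indices(traj)
        coords = traj.coords[:, idx]
    else:
        coords = traj.coords
    d = _pairwise_rmsd(coords)
    adj = d <= cutoff  # includes self

    n = traj.n_frames
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    raw_clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[center] & remaining)
        raw_clusters.append((center, members))
        remaining[members] = False

    order = sorted(
        range(len(raw_clusters)),
        key=lambda k: (-raw_clusters[k][1].size, raw_clusters[k][0]),
    )
    centers = np.array([raw_clusters[k][0] for k in order])
    pops = np.array([raw_clusters[k][1].size / n for k in order])
    for rank, k in enumerate(order):
        assignments[raw_clusters[k][1]] = rank
    return ClusterResult(assignments=assignments, populations=pops,
                         centers=centers, cutoff=cutoff)


# ---------------------------------------------------------------------------
# dihedrals


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle (degrees, in [0, 360)) defined by four points, using
    the standard IUPAC sign convention about the p1–p2 axis."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(-y, x))
    return ang % 360.0


def chi1_angle(traj: Trajectory, frame: int, res_id: int, chain=None) -> float:
    """χ1 side-chain dihedral (N-Cα-Cβ-γ) of one residue in one frame.

    The γ atom is CG, or the residue-specific variant (OG/OG1/SG/CG1).
    Residues without a γ atom (Gly, Ala) raise a ValueError.
    """
    sub_idx = traj.atom_indices(res_ids=[res_id], chain=chain)
    if sub_idx.size == 0:
        raise ValueError(f"residue {res_id} not found")
    sub = traj.atoms.iloc[sub_idx]
    res_name = str(sub["res_name"].iloc[0])
    gamma = _gamma_atom(res_name)
    pos = {}
    for name in ("N", "CA", "CB", gamma):
        match = sub_idx[(sub["atom_name"] == name).to_numpy()]
        if match.size == 0:
            raise ValueError(f"residue {res_id} ({res_name}) lacks atom {name}: no chi1")
        pos[name] = traj.coords[frame, match[0]]
    return dihedral(pos["N"], pos["CA"], pos["CB"], pos[gamma])


def chi1_series(traj: Trajectory, res_id: int, chain=None) -> np.ndarray:
    return np.array([chi1_angle(traj, f, res_id, chain) for f in range(traj.n_frames)])


def chi1_density(angles, bin_width: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of χ1 over [0°, 360°) with periodic binning.

    Returns (bin_centers, density); the density integrates to exactly 1 over
    the circle. ``bin_width`` must divide 360.
    """
    angles = np.asarray(angles, dtype=float) % 360.0
    if angles.size == 0:
        raise ValueError("need at least one angle")
    n_bins = int(round(360.0 / bin_width))
    if abs(n_bins * bin_width - 360.0) > 1e-9:
        raise ValueError("bin width must divide 360 degrees")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    density = counts / (angles.size * bin_width)
    centers = edges[:-1] + bin_width / 2.0
    return centers, density


# ---------------------------------------------------------------------------
# hydrogen bonds


def place_amide_hydrogen(n_pos, ca_pos, c_prev_pos, bond_length: float = 0.101):
    """Idealized backbone amide hydrogen: placed on the bisector of the
    N→Cα and N→C(previous residue) directions, pointing away from both, at
    the standard 0.101 nm N–H bond length."""
    n_pos, ca_pos, c_prev_pos = (np.asarray(p, float) for p in (n_pos, ca_pos, c_prev_pos))
    u = ca_pos - n_pos
    v = c_prev_pos - n_pos
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = -(u + v)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("collinear N/CA/C geometry: cannot place hydrogen")
    return n_pos + bond_length * d / norm


def hbond_series(
    traj: Trajectory,
    pairs,
    d_cut: float = 0.35,
    a_cut: float = 30.0,
) -> HBondSeries:
    """Hydrogen-bond occupancy per frame for explicit donor/acceptor pairs.

    ``pairs`` is an iterable of (donor_idx, hydrogen_idx, acceptor_idx) atom
    index triples; pass ``hydrogen_idx=None`` to have an idealized amide
    hydrogen placed from the donor's N/CA and the preceding residue's C
    (flagged in the result). A bond is present in a frame iff the
    donor–acceptor distance is ≤ ``d_cut`` (nm) AND the hydrogen–donor–
    acceptor angle is ≤ ``a_cut`` (degrees); both boundaries inclusive.
    An empty pair list yields an empty series.
    """
    occupancy: dict[tuple[int, int, int], np.ndarray] = {}
    reconstructed = False
    for pair in pairs:
        d_idx, h_idx, a_idx = pair
        dpos = traj.coords[:, d_idx]
        apos = traj.coords[:, a_idx]
        if h_idx is None:
            reconstructed = True
            hpos = np.empty_like(dpos)
            row = traj.atoms.iloc[d_idx]
            res_id = int(row["res_id"])
            ca = traj.atom_indices(res_ids=[res_id], atom_names=["CA"])
            c_prev = traj.atom_indices(res_ids=[res_id - 1], atom_names=["C"])
            if ca.size == 0 or c_prev.size == 0:
                raise ValueError(
                    f"cannot reconstruct amide H for residue {res_id}: need CA and previous C"
                )
            for f in range(traj.n_frames):
                hpos[f] = place_amide_hydrogen(
                    dpos[f], traj.coords[f, ca[0]], traj.coords[f, c_prev[0]]
                )
            h_key = -(d_idx + 1)  # synthetic hydrogen marker in the key
        else:
            hpos = traj.coords[:, h_idx]
            h_key = h_idx
        da = np.linalg.norm(apos - dpos, axis=1)
        u = hpos - dpos
        v = apos - dpos
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        occupancy[(d_idx, h_key, a_idx)] = (da <= d_cut) & (ang <= a_cut)
    return HBondSeries(occupancy=occupancy, d_cut=d_cut, a_cut=a_cut,
                       n_frames=traj.n_frames, hydrogens_reconstructed=reconstructed)


def validate_unwrapped(traj: Trajectory, max_bond: float = 0.25) -> None:
    """Reject trajectories with broken (likely PBC-wrapped) backbone bonds.

    Checks N–CA and CA–C distances within every residue in every frame
    against ``max_bond`` nm.
    """
    for res_id, grp in traj.atoms.groupby("res_id"):
        names = dict(zip(grp["atom_name"], grp.index))
        for a, b in (("N", "CA"), ("CA", "C")):
            if a in names and b in names:
                d = np.linalg.norm(
                    traj.coords[:, names[a]] - traj.coords[:, names[b]], axis=1
                )
                if np.any(d > max_bond):
                    raise ValueError(
                        f"residue {res_id}: {a}-{b} bond exceeds {max_bond} nm; "
                        "trajectory looks wrapped across periodic boundaries"
                    )


# ---------------------------------------------------------------------------
# structure comparison and PDB I/O (biotite-backed)


def ca_superpose_rmsd(pdb_path_mobile: str, pdb_path_ref: str,
                      res_range: tuple[int, int] | None = None,
                      exclude_res: tuple[int, ...] = ()) -> float:
    """Cα superposition RMSD (Å) between two structure files.

    Residues are matched by residue id over the intersection of the two
    structures (optionally restricted to ``res_range`` and excluding
    ``exclude_res``, e.g. position 508 when one partner carries F508del).
    """
    import biotite.structure as struc
    import biotite.structure.io as strucio

    def load_ca(path):
        arr = strucio.load_structure(path)
        if isinstance(arr, struc.AtomArrayStack):
            arr = arr[0]
        ca = arr[(arr.atom_name == "CA") & struc.filter_amino_acids(arr)]
        return {int(r): c for r, c in zip(ca.res_id, ca.coord)}

    mob = load_ca(pdb_path_mobile)
    ref = load_ca(pdb_path_ref)
    common = sorted(set(mob) & set(ref))
    if res_range is not None:
        common = [r for r in common if res_range[0] <= r <= res_range[1]]
    common = [r for r in common if r not in exclude_res]
    if len(common) < 3:
        raise ValueError("fewer than 3 matched Calpha atoms")
    a = np.array([mob[r] for r in common])
    b = np.array([ref[r] for r in common])
    _, rmsd = superpose(a, b)
    return rmsd  # input files are in Angstrom, so this RMSD is too


def read_multimodel_pdb(path: str, frame_spacing: float = 500.0) -> Trajectory:
    """Read a multi-model PDB (frames as MODEL records) into a Trajectory,
    converting Å to nm."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure()  # AtomArrayStack, coords in Angstrom
    atoms = pd.DataFrame({
        "res_id": stack.res_id.astype(int),
        "res_name": stack.res_name.astype(str),
        "atom_name": stack.atom_name.astype(str),
        "chain": stack.chain_id.astype(str),
    })
    return Trajectory(coords=stack.coord / 10.0, atoms=atoms,
                      frame_spacing=frame_spacing)


def write_multimodel_pdb(traj: Trajectory, path: str) -> None:
    """Write a Trajectory as a multi-model PDB (nm → Å)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_at = traj.n_atoms
    template = struc.AtomArray(n_at)
    template.res_id = traj.atoms["res_id"].to_numpy(dtype=int)
    template.res_name = np.array(traj.atoms["res_name"], dtype="U5")
    template.atom_name = np.array(traj.atoms["atom_name"], dtype="U6")
    template.chain_id = np.array(traj.atoms["chain"], dtype="U4")
    template.element = np.array(
        [n[:1] for n in traj.atoms["atom_name"]], dtype="U2"
    )
    stack = struc.stack([template] * traj.n_frames)
    stack.coord = traj.coords * 10.0
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)
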