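"""Active-site hydration analytics on role-tagged trajectories.

The analyses mirror what is routinely computed from classical MD of a
flavoprotein active site: the solvent-accessible pocket volume around a seed
point (grid flood fill), the number of resident water molecules, water
radial distribution functions, inter-group distances (e.g. flavin ring to an
arginine guanidinium group), the isoalloxazine "butterfly" dihedral, and
time-averaged water density maps.

Atoms carry a *role* rather than a full topology:

=====  =============================================================
role   meaning
=====  =============================================================
REF    reference group (e.g. the isoalloxazine ring atoms)
PRB    probe group (e.g. the R451 guanidinium group)
HOH    water oxygens (hydrogens are ignored throughout)
OCC    other occluding atoms (protein wall / cage)
=====  =============================================================

Geometry conventions: coordinates in Angstrom; pocket occlusion uses
van-der-Waals radii plus a solvent probe radius; flood fill is 6-connected
over cell centers.  Periodic imaging is applied only in the RDF and only
when a box is present (the active site is assumed far from box edges).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "Frame",
    "Trajectory",
    "GridSpec",
    "PocketResult",
    "RDFResult",
    "DensityMap",
    "VDW_RADII",
    "pocket_region",
    "count_pocket_waters",
    "rdf",
    "distance_series",
    "dihedral",
    "density_map",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_density_map",
    "read_density_map",
]

ROLES = ("REF", "PRB", "HOH", "OCC")

#: default van der Waals radii in Angstrom (overridable per GridSpec)
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
GENERIC_VDW = 1.7


@dataclass
class Frame:
    """One trajectory frame: parallel arrays of atom ids, roles, elements and
    coordinates (n x 3, Angstrom)."""

    ids: np.ndarray
    roles: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.roles = np.asarray(self.roles)
        self.elements = np.asarray(self.elements)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.ids.size
        if not (self.roles.size == n and self.elements.size == n and self.coords.shape == (n, 3)):
            raise ValueError("inconsistent atom arrays in Frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def select(self, role: str) -> np.ndarray:
        """Coordinates of all atoms with the given role."""
        return self.coords[self.roles == role]

    def ids_of(self, role: str) -> np.ndarray:
        return self.ids[self.roles == role]

    def occluders(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates and elements of all non-water (occluding) atoms."""
        mask = self.roles != "HOH"
        return self.coords[mask], self.elements[mask]


@dataclass
class Trajectory:
    """A list of frames with an identical atom roster, optional orthorhombic
    box lengths (Angstrom) and free-form metadata."""

    frames: list[Frame]
    box: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if (
                f.ids.size != ref.ids.size
                or not np.array_equal(f.ids, ref.ids)
                or not np.array_equal(f.roles, ref.roles)
            ):
                raise ValueError("all frames must share the same atom roster")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive lengths")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class GridSpec:
    """Grid parameters for pocket detection.

    spacing: cell edge (A); search_radius: extent of the region explored
    around the seed point (A); probe_radius: solvent probe added to the
    per-element van der Waals radii.
    """

    spacing: float = 0.4
    search_radius: float = 8.0
    probe_radius: float = 1.4
    occlusion_radii: dict = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.search_radius <= self.spacing:
            raise ValueError("search_radius must exceed spacing")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")

    def radius_of(self, element: str) -> float:
        return self.occlusion_radii.get(element, GENERIC_VDW)


@dataclass
class PocketResult:
    """Flood-filled pocket: boolean cell mask on a cubic grid plus derived
    volume (A^3) and resident water ids."""

    origin: np.ndarray          # coordinate of cell (0,0,0) center
    spacing: float
    mask: np.ndarray            # boolean (n,n,n); True = cell in region
    volume: float
    water_ids: np.ndarray

    @property
    def cells(self) -> set[tuple[int, int, int]]:
        return set(zip(*(idx.tolist() for idx in np.nonzero(self.mask))))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of cartesian points in region cells."""
        points = np.atleast_2d(points)
        idx = np.rint((points - self.origin) / self.spacing).astype(int)
        n = self.mask.shape[0]
        ok = np.all((idx >= 0) & (idx < n), axis=1)
        out = np.zeros(len(points), dtype=bool)
        out[ok] = self.mask[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        return out


@dataclass
class RDFResult:
    """Radial distribution function g(r) with its bin centers and the bulk
    reference density used for normalization."""

    r_centers: np.ndarray
    g: np.ndarray
    reference_density: float


@dataclass
class DensityMap:
    """Per-cell mean occupancy (fraction of frames with >= 1 target atom in
    the cell) on a regular grid."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (nx, ny, nz)


def _occupancy_mask(points: np.ndarray, elements: np.ndarray, grid_pts: np.ndarray,
                    grid: GridSpec) -> np.ndarray:
    """True for grid points lying within vdW+probe of any occluding atom."""
    occluded = np.zeros(len(grid_pts), dtype=bool)
    if len(points) == 0:
        return occluded
    radii = np.array([grid.radius_of(e) for e in elements])
    tree = cKDTree(points)
    # nearest occluder per grid point is not enough with mixed radii; query
    # within the largest radius and refine per atom group
    for r in np.unique(radii):
        sub = points[radii == r]
        d, _ = cKDTree(sub).query(grid_pts, k=1)
        occluded |= d <= (r + grid.probe_radius)
    del tree
    return occluded


def pocket_region(frame: Frame, seed_point, grid: GridSpec) -> PocketResult:
    """Solvent-accessible pocket connected to a seed point.

    A cubic grid of the given spacing is centered on the seed; a cell is
    *free* when its center lies farther than (vdW + probe) from every
    occluding atom (roles OCC, PRB, REF) and within ``search_radius`` of the
    seed.  The pocket is the 6-connected flood fill from the seed cell over
    free cells; its volume is the cell count times spacing^3.  Water oxygens
    whose position falls inside a region cell are reported by id.
    """
    seed = np.asarray(seed_point, dtype=float)
    occ_pts, occ_el = frame.occluders()
    if len(occ_pts):
        radii = np.array([grid.radius_of(e) for e in occ_el])
        d = np.linalg.norm(occ_pts - seed, axis=1)
        if np.any(d <= radii + grid.probe_radius):
            raise ValueError("seed point lies inside an occluding atom")

    half = int(np.ceil(grid.search_radius / grid.spacing))
    n = 2 * half + 1
    ax = (np.arange(n) - half) * grid.spacing
    origin = seed + np.array([ax[0], ax[0], ax[0]])
    X, Y, Z = np.meshgrid(ax + seed[0], ax + seed[1], ax + seed[2], indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    within = np.linalg.norm(pts - seed, axis=1) <= grid.search_radius
    free = within & ~_occupancy_mask(occ_pts, occ_el, pts, grid)
    free = free.reshape(n, n, n)

    seed_idx = (half, half, half)
    if not free[seed_idx]:
        raise ValueError("seed cell is occluded")
    labels, _ = ndimage.label(free, structure=ndimage.generate_binary_structure(3, 1))
    mask = labels == labels[seed_idx]

    volume = float(mask.sum()) * grid.spacing**3
    result = PocketResult(origin, grid.spacing, mask, volume, np.array([], dtype=int))
    waters = frame.select("HOH")
    if len(waters):
        inside = result.contains(waters)
        result.water_ids = frame.ids_of("HOH")[inside]
    return result


def count_pocket_waters(frame: Frame, region: PocketResult) -> int:
    """Number of distinct water oxygens of ``frame`` inside the region."""
    waters = frame.select("HOH")
    if len(waters) == 0:
        return 0
    return int(np.count_nonzero(region.contains(waters)))


def rdf(traj: Trajectory, ref_role: str, target_role: str, dr: float = 0.2,
        r_max: float = 10.0, bulk_density: float | None = None) -> RDFResult:
    """Radial distribution function of target atoms around reference atoms.

    g(r_k) = <n_k> / (4 pi r_k^2 dr rho), averaged over frames and reference
    atoms, with rho the bulk target density.  When the trajectory has a box,
    rho defaults to N_target / V_box and distances use the minimum-image
    convention; otherwise ``bulk_density`` (A^-3) must be supplied.
    """
    if dr <= 0 or r_max <= dr:
        raise ValueError("need dr > 0 and r_max > dr")
    f0 = traj.frames[0]
    n_ref = int(np.count_nonzero(f0.roles == ref_role))
    n_tgt = int(np.count_nonzero(f0.roles == target_role))
    if n_ref == 0:
        raise ValueError(f"no atoms with reference role {ref_role!r}")
    if traj.box is None:
        if bulk_density is None:
            raise ValueError("no box in trajectory: supply bulk_density (A^-3)")
        rho = bulk_density
    else:
        rho = n_tgt / float(np.prod(traj.box))

    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        refs = frame.select(ref_role)
        tgts = frame.select(target_role)
        if len(tgts) == 0:
            continue
        diff = tgts[None, :, :] - refs[:, None, :]
        if traj.box is not None:
            diff -= traj.box * np.rint(diff / traj.box)
        d = np.linalg.norm(diff, axis=2).ravel()
        counts += np.histogram(d, bins=edges)[0]

    r_centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_centers**2 * dr
    norm = len(traj.frames) * n_ref * shell * rho
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    return RDFResult(r_centers, g, rho)


def distance_series(traj: Trajectory, role_a: str, role_b: str,
                    metric: str = "centroid") -> np.ndarray:
    """Per-frame distance between two atom groups.

    ``metric='centroid'`` (default): centroid-to-centroid distance.
    ``metric='min_heavy'``: minimum pairwise heavy-atom distance (all atoms
    in these trajectories are heavy atoms).
    """
    if metric not in ("centroid", "min_heavy"):
        raise ValueError(f"unknown metric {metric!r}")
    out = np.empty(len(traj.frames))
    for i, frame in enumerate(traj.frames):
        a = frame.select(role_a)
        b = frame.select(role_b)
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"missing role {role_a!r} or {role_b!r} in frame {i}")
        if metric == "centroid":
            out[i] = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        else:
            out[i] = np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2))
    return out


def dihedral(frame: Frame, a1: int, a2: int, a3: int, a4: int) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) over four atom ids.

    Uses the atan2 of the cross-product construction; e.g. the flavin
    butterfly bending angle is the C4-N5-N10-C9 dihedral.
    """
    ids = [a1, a2, a3, a4]
    if len(set(ids)) != 4:
        raise ValueError("four distinct atom ids required")
    lookup = {int(i): k for k, i in enumerate(frame.ids)}
    try:
        p = np.array([frame.coords[lookup[int(i)]] for i in ids])
    except KeyError as err:
        raise ValueError(f"atom id {err} not in frame") from err
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
        raise ValueError("collinear triple: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def density_map(traj: Trajectory, target_role: str = "HOH", spacing: float = 0.4,
                padding: float = 1.0) -> DensityMap:
    """Mean per-cell occupancy of target atoms over all frames.

    A cell counts as occupied in a frame when at least one target atom falls
    in it; the map value is the fraction of frames occupied.  The grid spans
    the bounding box of all target positions plus ``padding``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    all_pts = [f.select(target_role) for f in traj.frames]
    stacked = np.concatenate([p for p in all_pts if len(p)], axis=0) if any(
        len(p) for p in all_pts
    ) else None
    if stacked is None:
        raise ValueError(f"no atoms with role {target_role!r} in trajectory")
    lo = stacked.min(axis=0) - padding
    hi = stacked.max(axis=0) + padding
    dims = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0  # center of cell (0,0,0)
    counts = np.zeros(tuple(dims))
    for pts in all_pts:
        if len(pts) == 0:
            continue
        idx = np.floor((pts - lo) / spacing).astype(int)
        idx = np.clip(idx, 0, dims - 1)
        occupied = np.zeros(tuple(dims), dtype=bool)
        occupied[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        counts += occupied
    return DensityMap(origin, spacing, counts / len(traj.frames))


# ---------------------------------------------------------------------------
# I/O: multi-model PDB (roles in residue names), XYZ + role sidecar, and a
# plain-text volumetric grid format.
# ---------------------------------------------------------------------------

def write_pdb_trajectory(traj: Trajectory, path) -> None:
    """Write frames as a multi-model PDB; roles are stored as residue names."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    f0 = traj.frames[0]
    n = f0.ids.size
    arr = struc.AtomArrayStack(len(traj.frames), n)
    arr.coord = np.stack([f.coords for f in traj.frames]).astype(np.float32)
    arr.res_name = f0.roles.astype("U4")
    arr.element = f0.elements.astype("U2")
    names = []
    res_ids = np.empty(n, dtype=int)
    counter: dict[str, int] = {}
    for i, (role, el) in enumerate(zip(f0.roles, f0.elements)):
        counter[role] = counter.get(role, 0) + 1
        names.append(f"{el}{counter[role] % 100}")
        res_ids[i] = counter[role] if role == "HOH" else 1
    arr.atom_name = np.array(names, dtype="U4")
    arr.res_id = res_ids
    arr.chain_id = np.full(n, "A", dtype="U2")
    arr.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb_trajectory(path, box=None, meta=None) -> Trajectory:
    """Read a multi-model PDB written by :func:`write_pdb_trajectory` (or any
    PDB whose residue names encode the roles REF/PRB/HOH/OCC)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=None)
    roles = np.array([r if r in ROLES else "OCC" for r in arr.res_name])
    elements = np.asarray(arr.element, dtype="U2")
    ids = np.arange(arr.array_length())
    frames = [
        Frame(ids, roles, elements, np.asarray(arr.coord[m], dtype=float))
        for m in range(arr.stack_depth())
    ]
    return Trajectory(frames, box=box, meta=meta or {})


def write_xyz_trajectory(traj: Trajectory, xyz_path, roles_path) -> None:
    """XYZ frames plus a sidecar table mapping atom index -> role."""
    f0 = traj.frames[0]
    with open(xyz_path, "w", encoding="utf-8", newline="\n") as fh:
        for k, frame in enumerate(traj.frames):
            fh.write(f"{f0.ids.size}\nframe {k}\n")
            for el, (x, y, z) in zip(frame.elements, frame.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")
    with open(roles_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("index,role\n")
        for i, role in enumerate(f0.roles):
            fh.write(f"{i},{role}\n")


def read_xyz_trajectory(xyz_path, roles_path, box=None) -> Trajectory:
    roles_map = {}
    with open(roles_path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            i, role = line.strip().split(",")
            roles_map[int(i)] = role
    frames = []
    with open(xyz_path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].strip())
        block = lines[pos + 2 : pos + 2 + n]
        elements, coords = [], []
        for row in block:
            parts = row.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        ids = np.arange(n)
        roles = np.array([roles_map[i] for i in range(n)])
        frames.append(Frame(ids, roles, np.array(elements), np.array(coords)))
        pos += 2 + n
    return Trajectory(frames, box=box)


def write_density_map(dmap: DensityMap, path) -> None:
    """Plain-text grid: header (origin, spacing, dims) then one value per
    line in C order."""
    v = dmap.values
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# photokin density map\n")
        fh.write(f"origin {dmap.origin[0]:.6f} {dmap.origin[1]:.6f} {dmap.origin[2]:.6f}\n")
        fh.write(f"spacing {dmap.spacing:.6f}\n")
        fh.write(f"dims {v.shape[0]} {v.shape[1]} {v.shape[2]}\n")
        np.savetxt(fh, v.ravel()[:, None], fmt="%.8g")


def read_density_map(path) -> DensityMap:
    with open(path, encoding="utf-8") as fh:
        lines = [l for l in fh.read().splitlines() if l.strip() and not l.startswith("#")]
    origin = np.array([float(x) for x in lines[0].split()[1:4]])
    spacing = float(lines[1].split()[1])
    dims = tuple(int(x) for x in lines[2].split()[1:4])
    values = np.array([float(l) for l in lines[3:]]).reshape(dims)
    return DensityMap(origin, spacing, values)
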