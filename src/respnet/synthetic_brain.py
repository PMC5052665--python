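"""Synthetic structural substrate: spherical hemispheres, parcellation, both connectivities.

The substrate mirrors the geometry the network model assumes: each hemisphere is a
closed 2-sphere triangulated quasi-uniformly, cortical areas are contiguous patches
on the mesh, subcortical areas are single points between the hemispheres.  Short-range
connectivity is a translation-invariant Gaussian kernel on each sphere with no
interhemispheric links; long-range connectivity is a sparse directed area-level graph
with distance-derived transmission delays.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import ConvexHull

from .exceptions import FormatError, InvalidArgumentError

__all__ = [
    "BrainGeometry",
    "Parcellation",
    "HomogeneousSC",
    "HeterogeneousSC",
    "generate_sphere_mesh",
    "generate_parcellation",
    "build_homogeneous_sc",
    "generate_heterogeneous_sc",
    "normalize_heterogeneous",
    "read_connectome",
    "write_connectome",
    "read_mesh",
    "write_mesh",
    "read_off",
]

LEFT, RIGHT = 0, 1


# --------------------------------------------------------------------------- types


@dataclass
class BrainGeometry:
    """Meshed cortical hemispheres plus point-like subcortical areas.

    Node order convention used throughout the package: left-hemisphere cortical
    vertices, then right-hemisphere vertices, then one node per subcortical area.
    """

    cortical_vertices: np.ndarray  # (n_cortical, 3) mm
    triangles: np.ndarray  # (n_tri, 3) vertex indices
    hemisphere_label: np.ndarray  # (n_cortical,) 0=left, 1=right
    subcortical_positions: np.ndarray  # (n_sub, 3) mm
    sphere_centers: np.ndarray | None = None  # (2, 3); set for generated meshes
    sphere_radius: float | None = None

    @property
    def n_cortical(self) -> int:
        return self.cortical_vertices.shape[0]

    @property
    def n_subcortical(self) -> int:
        return self.subcortical_positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.n_cortical + self.n_subcortical

    @property
    def node_positions(self) -> np.ndarray:
        """All node coordinates in the global node order."""
        return np.vstack([self.cortical_vertices, self.subcortical_positions])

    def validate(self) -> None:
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= self.n_cortical
        ):
            raise InvalidArgumentError("triangle references an invalid vertex")
        if not np.isin(self.hemisphere_label, (LEFT, RIGHT)).all():
            raise InvalidArgumentError("hemisphere labels must be 0 (left) or 1 (right)")
        for tri in self.triangles:
            if len(set(self.hemisphere_label[tri])) != 1:
                raise InvalidArgumentError("triangle spans both hemispheres")

    def mesh_adjacency(self) -> sp.csr_matrix:
        """Undirected vertex adjacency of the triangulation (cortical nodes only)."""
        t = self.triangles
        rows = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
        cols = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
        n = self.n_cortical
        a = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    def great_circle_distances(self, hemisphere: int) -> np.ndarray:
        """Pairwise great-circle distances between vertices of one hemisphere (mm)."""
        if self.sphere_centers is None or self.sphere_radius is None:
            raise InvalidArgumentError(
                "great-circle distances require a generated spherical mesh"
            )
        idx = np.where(self.hemisphere_label == hemisphere)[0]
        u = self.cortical_vertices[idx] - self.sphere_centers[hemisphere]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cosang = np.clip(u @ u.T, -1.0, 1.0)
        return self.sphere_radius * np.arccos(cosang)


@dataclass
class Parcellation:
    """Assignment of nodes to areas, plus the area table.

    Area id convention: ids ``0..m-1`` are left cortical, ``m..2m-1`` right
    cortical, ``2m..2m+n-1`` subcortical.  ``node_area`` covers every node in
    the global node order (subcortical node ``s`` belongs to area ``2m+s``).
    """

    node_area: np.ndarray  # (n_nodes,) area id per node
    areas: pd.DataFrame  # columns: id, name, kind, hemisphere, is_callosal
    area_centroids: np.ndarray  # (n_areas, 3) mm

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def m(self) -> int:
        """Cortical areas per hemisphere (callosal patch included)."""
        return int((self.areas["kind"] == "cortical").sum() // 2)

    @property
    def n_subcortical(self) -> int:
        return int((self.areas["kind"] == "subcortical").sum())

    def members(self, area_id: int) -> np.ndarray:
        return np.where(self.node_area == area_id)[0]

    @property
    def membership(self) -> list[np.ndarray]:
        return [self.members(a) for a in range(self.n_areas)]

    def is_callosal_node(self) -> np.ndarray:
        callosal_ids = set(self.areas.loc[self.areas["is_callosal"], "id"])
        return np.isin(self.node_area, list(callosal_ids))

    def cortical_area_ids(self, include_callosal: bool = False) -> np.ndarray:
        df = self.areas[self.areas["kind"] == "cortical"]
        if not include_callosal:
            df = df[~df["is_callosal"]]
        return df["id"].to_numpy()

    def subcortical_area_ids(self) -> np.ndarray:
        return self.areas.loc[self.areas["kind"] == "subcortical", "id"].to_numpy()

    def validate(self) -> None:
        if self.n_areas != 2 * self.m + self.n_subcortical:
            raise InvalidArgumentError("area count must equal 2m + n")
        for aid in self.areas["id"]:
            row = self.areas.loc[self.areas["id"] == aid].iloc[0]
            size = self.members(aid).size
            if row["kind"] == "subcortical" and size != 1:
                raise InvalidArgumentError("subcortical areas must be singletons")
            if row["kind"] == "cortical" and not row["is_callosal"] and size < 1:
                raise InvalidArgumentError("empty functional cortical area")


@dataclass
class HomogeneousSC:
    """Short-range node-to-node connectivity (target rows, incoming sums = 1)."""

    weights: sp.csr_matrix  # (n_nodes, n_nodes); W[i, j] = weight of j -> i
    sigma: float  # mm

    def validate(self, geometry: BrainGeometry, parcellation: Parcellation) -> None:
        w = self.weights.tocoo()
        if (w.data < 0).any():
            raise InvalidArgumentError("negative homogeneous weight")
        hemi = np.full(geometry.n_nodes, -1)
        hemi[: geometry.n_cortical] = geometry.hemisphere_label
        if (hemi[w.row] != hemi[w.col]).any():
            raise InvalidArgumentError("homogeneous weight crosses hemispheres")
        callosal = parcellation.is_callosal_node()
        if callosal[w.row].any() or callosal[w.col].any():
            raise InvalidArgumentError("callosal-patch node is not isolated")
        sums = np.asarray(self.weights.sum(axis=1)).ravel()
        active = (~callosal) & (hemi >= 0)
        if not np.allclose(sums[active], 1.0, atol=1e-12):
            raise InvalidArgumentError("incoming homogeneous weights must sum to 1")


@dataclass
class HeterogeneousSC:
    """Long-range area-to-area connectivity with finite-speed delays.

    ``weights[i, j]`` is the strength of the directed connection from source
    area ``j`` to target area ``i`` (target-row convention).
    """

    weights: np.ndarray  # (n_areas, n_areas) dimensionless
    tract_lengths: np.ndarray  # (n_areas, n_areas) mm
    speed: float = 6.0  # m/s; equivalently mm/ms
    labels: list[str] | None = None
    centres: np.ndarray | None = None  # (n_areas, 3) mm

    @property
    def n_areas(self) -> int:
        return self.weights.shape[0]

    @property
    def delays(self) -> np.ndarray:
        """Transmission delays in seconds: length / speed, zero off-support."""
        tau = np.zeros_like(self.tract_lengths)
        nz = self.weights > 0
        # lengths are mm, speed m/s = 1e3 mm/s
        tau[nz] = self.tract_lengths[nz] / (self.speed * 1e3)
        return tau

    def validate(self, require_normalized: bool = True) -> None:
        if self.weights.shape[0] != self.weights.shape[1]:
            raise InvalidArgumentError("weight matrix must be square")
        if (self.weights < 0).any():
            raise InvalidArgumentError("negative heterogeneous weight")
        if require_normalized and self.weights.any():
            max_in = self.weights.sum(axis=1).max()
            if abs(max_in - 1.0) > 1e-12:
                raise InvalidArgumentError(
                    f"maximum incoming weight sum is {max_in}, expected 1"
                )
        if (self.delays < 0).any():
            raise InvalidArgumentError("negative delay")


# ---------------------------------------------------------------- mesh generation


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere via the Fibonacci lattice."""
    i = np.arange(n)
    phi = (1 + np.sqrt(5.0)) / 2
    theta = 2 * np.pi * i / phi
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return radius * pts


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_sphere_mesh(
    nodes_per_hemisphere: int,
    radius: float,
    seed: int,
    n_subcortical: int = 0,
    gap_fraction: float = 0.25,
) -> BrainGeometry:
    """Generate two disjoint triangulated spheres plus subcortical points.

    Each hemisphere is a Fibonacci lattice on a sphere (randomly rotated per
    seed) triangulated by its convex hull, which is a valid closed surface
    triangulation for points on a sphere.  Subcortical points are scattered
    in the gap between the hemispheres.

    Parameters
    ----------
    nodes_per_hemisphere
        Vertices per hemisphere; at least 4 (tetrahedron).
    radius
        Sphere radius in mm.
    seed
        Seed for the random rotation and subcortical placement.
    n_subcortical
        Number of point-like subcortical areas to place between the spheres.
    """
    if nodes_per_hemisphere < 4:
        raise InvalidArgumentError("nodes_per_hemisphere must be >= 4")
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    rng = np.random.default_rng(seed)
    gap = gap_fraction * radius
    centers = np.array(
        [[-(radius + gap / 2), 0.0, 0.0], [radius + gap / 2, 0.0, 0.0]]
    )
    verts, tris, hemi = [], [], []
    offset = 0
    for h in (LEFT, RIGHT):
        pts = _fibonacci_sphere(nodes_per_hemisphere, radius) @ _random_rotation(rng).T
        hull = ConvexHull(pts)
        verts.append(pts + centers[h])
        tris.append(hull.simplices + offset)
        hemi.append(np.full(nodes_per_hemisphere, h))
        offset += nodes_per_hemisphere
    # subcortical blob in the interhemispheric gap, clear of both spheres
    sub = rng.uniform(-1, 1, size=(n_subcortical, 3))
    sub *= np.array([gap / 2 * 0.8, radius * 0.5, radius * 0.5])
    geom = BrainGeometry(
        cortical_vertices=np.vstack(verts),
        triangles=np.vstack(tris),
        hemisphere_label=np.concatenate(hemi),
        subcortical_positions=sub.reshape(n_subcortical, 3),
        sphere_centers=centers,
        sphere_radius=float(radius),
    )
    geom.validate()
    return geom


# ----------------------------------------------------------------- parcellation


def _grow_patches(
    adj: sp.csr_matrix, node_idx: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """Multi-source BFS over the mesh adjacency; returns patch label per node.

    Growing patches breadth-first from seed nodes guarantees each patch is a
    connected subgraph of the adjacency.
    """
    local = {g: i for i, g in enumerate(node_idx)}
    labels = np.full(node_idx.size, -1)
    frontier: list[list[int]] = [[local[s]] for s in seeds]
    for p, s in enumerate(seeds):
        labels[local[s]] = p
    indptr, indices = adj.indptr, adj.indices
    remaining = node_idx.size - len(seeds)
    while remaining > 0:
        progressed = False
        for p in range(len(seeds)):
            nxt = []
            for ln in frontier[p]:
                g = node_idx[ln]
                for nb in indices[indptr[g] : indptr[g + 1]]:
                    lnb = local.get(nb)
                    if lnb is not None and labels[lnb] == -1:
                        labels[lnb] = p
                        nxt.append(lnb)
                        remaining -= 1
            frontier[p] = nxt
            progressed = progressed or bool(nxt)
        if not progressed:
            break
    if (labels == -1).any():
        # disconnected leftovers: attach to the nearest labelled node
        unl = np.where(labels == -1)[0]
        lab = np.where(labels != -1)[0]
        for ln in unl:
            labels[ln] = labels[lab[0]]
    return labels


def generate_parcellation(
    geometry: BrainGeometry,
    areas_per_hemisphere: int,
    n_subcortical: int,
    seed: int,
) -> Parcellation:
    """Partition each hemisphere into contiguous patches plus a medial callosal patch.

    One patch per hemisphere is flagged callosal and seeded at the vertex on the
    medial face (closest to the midline); its nodes are later isolated in the
    short-range connectivity.  Every subcortical point becomes a singleton area.
    """
    m = areas_per_hemisphere
    if m < 2:
        raise InvalidArgumentError("areas_per_hemisphere must be >= 2")
    if n_subcortical != geometry.n_subcortical:
        raise InvalidArgumentError(
            f"geometry carries {geometry.n_subcortical} subcortical points, "
            f"requested {n_subcortical}"
        )
    rng = np.random.default_rng(seed)
    adj = geometry.mesh_adjacency()
    node_area = np.full(geometry.n_nodes, -1)
    rows = []
    centroids = []
    for h in (LEFT, RIGHT):
        idx = np.where(geometry.hemisphere_label == h)[0]
        if m > idx.size:
            raise InvalidArgumentError("more areas than nodes in hemisphere")
        # medial face: largest x for the left (negative-x) sphere, smallest for right
        x = geometry.cortical_vertices[idx, 0]
        callosal_seed = idx[np.argmax(x) if h == LEFT else np.argmin(x)]
        others = idx[idx != callosal_seed]
        func_seeds = rng.choice(others, size=m - 1, replace=False)
        seeds = np.concatenate([func_seeds, [callosal_seed]])
        labels = _grow_patches(adj, idx, seeds)
        base = h * m
        node_area[idx] = base + labels
        hemi_name = "left" if h == LEFT else "right"
        for p in range(m):
            is_cal = p == m - 1
            aid = base + p
            rows.append(
                dict(
                    id=aid,
                    name=(f"{hemi_name[0].upper()}{'CAL' if is_cal else f'A{p}'}"),
                    kind="cortical",
                    hemisphere=hemi_name,
                    is_callosal=is_cal,
                )
            )
            mem = idx[labels == p]
            centroids.append(geometry.cortical_vertices[mem].mean(axis=0))
    for s in range(geometry.n_subcortical):
        aid = 2 * m + s
        node_area[geometry.n_cortical + s] = aid
        rows.append(
            dict(id=aid, name=f"SUB{s}", kind="subcortical", hemisphere="none",
                 is_callosal=False)
        )
        centroids.append(geometry.subcortical_positions[s])
    parc = Parcellation(
        node_area=node_area,
        areas=pd.DataFrame(rows),
        area_centroids=np.asarray(centroids),
    )
    parc.validate()
    return parc


# ------------------------------------------------------------- homogeneous SC


def build_homogeneous_sc(
    geometry: BrainGeometry,
    parcellation: Parcellation,
    sigma: float,
    cutoff: float = 4.0,
) -> HomogeneousSC:
    """Gaussian short-range connectivity on each hemisphere.

    Weight of ``j -> i`` is proportional to ``exp(-d(i,j)^2 / (2 sigma^2))`` for
    same-hemisphere pairs within ``cutoff * sigma`` (great-circle distance on the
    generating sphere), zero otherwise.  Self-weight is included.  Callosal-patch
    nodes are fully isolated.  Incoming weights of every connected node are
    renormalized to sum to one.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be positive")
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    callosal = parcellation.is_callosal_node()
    n = geometry.n_nodes
    blocks = []
    for h in (LEFT, RIGHT):
        idx = np.where(geometry.hemisphere_label == h)[0]
        d = geometry.great_circle_distances(h)
        w = np.exp(-(d**2) / (2 * sigma**2))
        w[d > cutoff * sigma] = 0.0
        iso = callosal[idx]
        w[iso, :] = 0.0
        w[:, iso] = 0.0
        sums = w.sum(axis=1)
        ok = sums > 0
        w[ok] /= sums[ok, None]
        blocks.append((idx, w))
    full = sp.lil_matrix((n, n))
    for idx, w in blocks:
        full[np.ix_(idx, idx)] = w
    hom = HomogeneousSC(weights=full.tocsr(), sigma=float(sigma))
    hom.validate(geometry, parcellation)
    return hom


# ----------------------------------------------------------- heterogeneous SC


def normalize_heterogeneous(weights: np.ndarray) -> np.ndarray:
    """Scale so the maximum over target areas of the incoming weight sum is 1."""
    w = np.asarray(weights, dtype=float)
    mx = w.sum(axis=1).max()
    if mx > 0:
        w = w / mx
    return w


def generate_heterogeneous_sc(
    parcellation: Parcellation,
    connection_density: float,
    speed: float,
    seed: int,
    length_jitter: float = 0.0,
) -> HeterogeneousSC:
    """Random directed area-level connectivity with distance-derived delays.

    Stand-in for a tractography- or database-derived connectome: each ordered
    area pair carries a connection with probability ``connection_density``;
    weights are uniform on (0, 1] before normalization; tract lengths are the
    Euclidean centroid distances with optional multiplicative jitter.
    """
    if not 0 < connection_density <= 1:
        raise InvalidArgumentError("connection_density must be in (0, 1]")
    if speed <= 0:
        raise InvalidArgumentError("speed must be positive")
    rng = np.random.default_rng(seed)
    n = parcellation.n_areas
    mask = rng.random((n, n)) < connection_density
    np.fill_diagonal(mask, False)
    w = np.where(mask, rng.uniform(0.0, 1.0, size=(n, n)), 0.0)
    # uniform(0,1) can be exactly 0; nudge to keep mask and support identical
    w[mask] = np.maximum(w[mask], 1e-12)
    c = parcellation.area_centroids
    lengths = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
    if length_jitter > 0:
        lengths = lengths * (1 + length_jitter * rng.uniform(-1, 1, size=lengths.shape))
    lengths[~mask] = 0.0
    het = HeterogeneousSC(
        weights=normalize_heterogeneous(w),
        tract_lengths=lengths,
        speed=float(speed),
        labels=list(parcellation.areas["name"]),
        centres=c.copy(),
    )
    het.validate()
    return het


# --------------------------------------------------------------------------- IO


def _load_square(text: str, what: str) -> np.ndarray:
    try:
        m = np.loadtxt(io.StringIO(text), ndmin=2)
    except ValueError as e:
        raise FormatError(f"cannot parse {what}: {e}") from e
    if m.shape[0] != m.shape[1]:
        raise FormatError(f"{what} is not square: shape {m.shape}")
    return m


def _read_text(root: Path, name: str) -> str:
    if root.is_dir():
        p = root / name
        if not p.exists():
            raise FormatError(f"missing {name} in {root}")
        return p.read_text()
    if zipfile.is_zipfile(root):
        with zipfile.ZipFile(root) as zf:
            for entry in zf.namelist():
                if Path(entry).name == name:
                    return zf.read(entry).decode()
        raise FormatError(f"missing {name} in {root}")
    raise FormatError(f"{root} is neither a directory nor a zip archive")


def read_connectome(
    weights_path,
    lengths_path=None,
    centres_path=None,
    speed: float = 6.0,
    normalize: bool = True,
) -> HeterogeneousSC:
    """Read a connectome in the standard zip/directory dialect.

    Accepts either a single zip/directory containing ``weights.txt``,
    ``tract_lengths.txt`` and ``centres.txt``, or the three file paths
    explicitly.  Weight rows are targets (weight of ``j -> i`` at ``[i, j]``).
    """
    weights_path = Path(weights_path)
    if lengths_path is None:
        w_txt = _read_text(weights_path, "weights.txt")
        l_txt = _read_text(weights_path, "tract_lengths.txt")
        c_txt = _read_text(weights_path, "centres.txt")
    else:
        w_txt = Path(weights_path).read_text()
        l_txt = Path(lengths_path).read_text()
        c_txt = Path(centres_path).read_text() if centres_path else ""
    w = _load_square(w_txt, "weights")
    lengths = _load_square(l_txt, "tract lengths")
    if w.shape != lengths.shape:
        raise FormatError(
            f"weights {w.shape} and tract lengths {lengths.shape} dimension mismatch"
        )
    if (w < 0).any():
        raise FormatError("negative weights in connectome file")
    labels, centres = None, None
    if c_txt.strip():
        rows = [ln.split() for ln in c_txt.strip().splitlines()]
        if any(len(r) != 4 for r in rows):
            raise FormatError("centres rows must be: label x y z")
        if len(rows) != w.shape[0]:
            raise FormatError(
                f"centres row count {len(rows)} does not match matrix dimension "
                f"{w.shape[0]}"
            )
        labels = [r[0] for r in rows]
        centres = np.array([[float(v) for v in r[1:]] for r in rows])
    het = HeterogeneousSC(
        weights=normalize_heterogeneous(w) if normalize else w,
        tract_lengths=lengths,
        speed=float(speed),
        labels=labels,
        centres=centres,
    )
    het.validate(require_normalized=normalize)
    return het


def write_connectome(het: HeterogeneousSC, out_dir, raw_weights: np.ndarray | None = None):
    """Write a connectome directory (weights.txt, tract_lengths.txt, centres.txt)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "weights.txt", raw_weights if raw_weights is not None else het.weights)
    np.savetxt(out / "tract_lengths.txt", het.tract_lengths)
    if het.centres is not None:
        labels = het.labels or [f"area{i}" for i in range(het.n_areas)]
        with open(out / "centres.txt", "w") as f:
            for lab, (x, y, z) in zip(labels, het.centres):
                f.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")
    return out


def write_mesh(geometry: BrainGeometry, vertices_path, triangles_path) -> None:
    """Write the cortical mesh as TSV vertex and triangle tables."""
    vdf = pd.DataFrame(geometry.cortical_vertices, columns=["x", "y", "z"])
    vdf["hemisphere"] = np.where(geometry.hemisphere_label == LEFT, "left", "right")
    vdf.to_csv(vertices_path, sep="\t", index=False)
    pd.DataFrame(geometry.triangles, columns=["v0", "v1", "v2"]).to_csv(
        triangles_path, sep="\t", index=False
    )


def read_mesh(vertices_path, triangles_path) -> BrainGeometry:
    """Read a cortical mesh from TSV vertex and triangle tables."""
    vdf = pd.read_csv(vertices_path, sep="\t")
    tdf = pd.read_csv(triangles_path, sep="\t")
    for col in ("x", "y", "z", "hemisphere"):
        if col not in vdf.columns:
            raise FormatError(f"vertex table missing column {col!r}")
    geom = BrainGeometry(
        cortical_vertices=vdf[["x", "y", "z"]].to_numpy(float),
        triangles=tdf.to_numpy(int),
        hemisphere_label=np.where(vdf["hemisphere"] == "left", LEFT, RIGHT),
        subcortical_positions=np.empty((0, 3)),
    )
    geom.validate()
    return geom


def read_off(path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal OFF surface reader; returns (vertices, triangles)."""
    lines = [
        ln.strip() for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines or lines[0] != "OFF":
        raise FormatError("not an OFF file")
    nv, nf, _ = (int(v) for v in lines[1].split())
    verts = np.array([[float(v) for v in ln.split()] for ln in lines[2 : 2 + nv]])
    faces = []
    for ln in lines[2 + nv : 2 + nv + nf]:
        parts = [int(v) for v in ln.split()]
        if parts[0] != 3:
            raise FormatError("only triangular OFF faces are supported")
        faces.append(parts[1:4])
    return verts, np.array(faces, dtype=int)
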