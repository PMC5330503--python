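"""Structural descriptors of conformers and ensembles.

Backbone-dependent descriptors: secondary structure (C-alpha geometry,
P-SEA-style), hinge counting by rigid-segment decomposition, per-residue
contact networks.  Backbone-independent descriptors: grid-estimated protein
volume and normalized radius of gyration, two-probe grid pockets, grid
clearance-field tunnels, Shrake-Rupley solvent accessibility and ligand
inventories.

Pocket and tunnel detection are deliberately simple, fully specified
geometric methods (not reimplementations of Fpocket or MOLE); the printed
parameters of the reference analyses are honoured where they exist
(3 A probe/origin radius and 1.25 A interior threshold for tunnels,
0.5 A probe and 1.5 A grid for protein volume).  Both run on a grid
anchored to the structure's bounding box, so results are invariant under
rigid motion of the structure up to grid discretization.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gemmi
import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from confdiv.io import ConformerStructure, EnsembleRecord
from confdiv.superpose import MaxPair, kabsch_rmsd

__all__ = [
    "DescriptorSet",
    "Pocket",
    "Tunnel",
    "assign_secondary_structure",
    "protein_volume",
    "radius_of_gyration_normalized",
    "residue_network_degree",
    "detect_pockets",
    "pocket_variation_with_idrs",
    "detect_tunnels",
    "tunnel_variation",
    "count_hinges",
    "sasa",
    "ligand_stats",
    "compute_descriptors",
]


def _vdw_radius(element: str) -> float:
    r = gemmi.Element(element).vdw_r
    return float(r) if r and r > 0 else 1.7


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------


def assign_secondary_structure(conf: ConformerStructure) -> dict[int, str]:
    """C-alpha-geometry secondary structure: H (helix), E (strand), C (coil).

    Uses the P-SEA distance/angle signatures over sliding windows of the
    C-alpha trace (as implemented in biotite).  Unassignable or unobserved
    positions are coil; fewer than 5 observed residues yields all-coil.
    """
    import biotite.structure as bst

    observed = [r for r in conf.residues if r.observed]
    if len(observed) < 5:
        return {r.seq_pos: "C" for r in observed}
    arr = bst.AtomArray(len(observed))
    arr.coord = np.array([r.ca_xyz for r in observed], dtype=np.float32)
    arr.chain_id = np.array(["A"] * len(observed))
    arr.res_id = np.array([r.seq_pos for r in observed], dtype=int)
    arr.res_name = np.array([(r.name3 or "ALA") for r in observed])
    arr.atom_name = np.array(["CA"] * len(observed))
    arr.element = np.array(["C"] * len(observed))
    arr.hetero = np.zeros(len(observed), dtype=bool)
    sse = bst.annotate_sse(arr)
    mapping = {"a": "H", "b": "E", "c": "C"}
    out: dict[int, str] = {}
    for r, code in zip(observed, sse):
        out[r.seq_pos] = mapping.get(str(code), "C")
    return out


def ss_fractions(ss: dict[int, str]) -> tuple[float, float, float]:
    n = len(ss)
    if n == 0:
        return (0.0, 0.0, 1.0)
    vals = list(ss.values())
    return (vals.count("H") / n, vals.count("E") / n, vals.count("C") / n)


# ---------------------------------------------------------------------------
# volume and radius of gyration
# ---------------------------------------------------------------------------


def _rasterize(
    coords: np.ndarray, radii: np.ndarray, origin: np.ndarray, shape: tuple[int, int, int],
    spacing: float,
) -> np.ndarray:
    """Boolean grid marking voxel centers within radius of any atom."""
    mask = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        lo = np.maximum(np.floor((c - r - origin) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - origin) / spacing).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ix = np.arange(lo[0], hi[0])
        iy = np.arange(lo[1], hi[1])
        iz = np.arange(lo[2], hi[2])
        dx = origin[0] + ix * spacing - c[0]
        dy = origin[1] + iy * spacing - c[1]
        dz = origin[2] + iz * spacing - c[2]
        d2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return mask


def protein_volume(
    conf: ConformerStructure, probe: float = 0.5, grid: float = 1.5
) -> float:
    """Grid-estimated protein volume in A^3 (voxels within vdw+probe of an atom)."""
    coords, _, elements = conf.heavy_atoms()
    if coords.shape[0] == 0:
        raise ValueError("no observed atoms")
    radii = np.array([_vdw_radius(e) + probe for e in elements])
    pad = radii.max() + grid
    origin = coords.min(axis=0) - pad
    extent = coords.max(axis=0) + pad - origin
    shape = tuple(np.ceil(extent / grid).astype(int) + 1)
    mask = _rasterize(coords, radii, origin, shape, grid)
    return float(mask.sum()) * grid**3


def radius_of_gyration_normalized(
    conf: ConformerStructure, probe: float = 0.5, grid: float = 1.5
) -> float:
    """Rg over heavy atoms (uniform mass) divided by the Rg of the uniform
    sphere with the same (grid-estimated) volume: sqrt(3/5)*(3V/4pi)^(1/3)."""
    coords, _, _ = conf.heavy_atoms()
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 observed atoms")
    center = coords.mean(axis=0)
    rg = float(np.sqrt(((coords - center) ** 2).sum(axis=1).mean()))
    vol = protein_volume(conf, probe=probe, grid=grid)
    if vol <= 0:
        raise ValueError("grid volume is zero")
    r_sphere = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    return rg / (np.sqrt(3.0 / 5.0) * r_sphere)


# ---------------------------------------------------------------------------
# residue interaction network
# ---------------------------------------------------------------------------


def residue_network_degree(
    conf: ConformerStructure, cutoff: float = 5.0, min_seq_sep: int = 2
) -> tuple[nx.Graph, float]:
    """Residue contact network: nodes are observed residues, an edge joins two
    residues with any heavy-atom pair within ``cutoff`` and sequence
    separation >= ``min_seq_sep``.  Returns the graph and 2E/N."""
    coords, respos, _ = conf.heavy_atoms()
    if conf.n_observed < 2:
        raise ValueError("need at least 2 observed residues")
    g = nx.Graph()
    g.add_nodes_from(sorted(set(respos.tolist())))
    if coords.shape[0]:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(cutoff):
            pi, pj = int(respos[i]), int(respos[j])
            if abs(pi - pj) >= min_seq_sep:
                g.add_edge(pi, pj)
    avg_degree = 2.0 * g.number_of_edges() / g.number_of_nodes()
    return g, avg_degree


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pocket:
    volume: float  # A^3
    mouth_exposure: float  # fraction of pocket voxels adjacent to bulk solvent
    lining_positions: frozenset[int]


def _ball_structure(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return d2 <= radius_vox**2


def _bulk_mask(blocked_large: np.ndarray, dilate_vox: float) -> np.ndarray:
    """Bulk solvent: large-probe-feasible region connected to the box
    boundary, swept by the large probe (dilation by its radius)."""
    solvent = ~blocked_large
    lab, n = ndimage.label(solvent, structure=np.ones((3, 3, 3), dtype=bool))
    border = np.zeros_like(solvent)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    border_labels = np.unique(lab[border & solvent])
    seed = np.isin(lab, border_labels[border_labels > 0])
    return ndimage.binary_dilation(seed, structure=_ball_structure(dilate_vox))


def detect_pockets(
    conf: ConformerStructure,
    grid: float = 1.0,
    small_probe: float = 1.4,
    large_probe: float = 4.0,
    min_voxels: int = 3,
    exclude_positions: Iterable[int] = (),
) -> list[Pocket]:
    """Two-probe grid pocket detection.

    Pocket voxels are accessible to the small (water-sized) probe but not
    swept by the large probe rolling in from bulk solvent; 6-connected
    clusters are reported sorted by volume (voxel count x grid^3)
    descending.  Fully enclosed cavities count as pockets.
    """
    coords, respos, elements = conf.heavy_atoms(exclude_positions=exclude_positions)
    if coords.shape[0] == 0:
        return []
    vdw = np.array([_vdw_radius(e) for e in elements])
    pad = vdw.max() + large_probe + 2.0 * grid
    origin = coords.min(axis=0) - pad
    extent = coords.max(axis=0) + pad - origin
    shape = tuple(np.ceil(extent / grid).astype(int) + 1)
    blocked_small = _rasterize(coords, vdw + small_probe, origin, shape, grid)
    blocked_large = _rasterize(coords, vdw + large_probe, origin, shape, grid)
    bulk = _bulk_mask(blocked_large, large_probe / grid)
    pocket_space = (~blocked_small) & (~bulk)
    lab, n = ndimage.label(pocket_space, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return []
    tree = cKDTree(coords)
    max_reach = vdw.max() + small_probe + grid
    bulk_neighbors = ndimage.binary_dilation(bulk, ndimage.generate_binary_structure(3, 1))
    pockets: list[Pocket] = []
    for label_id in range(1, n + 1):
        vox = np.argwhere(lab == label_id)
        if vox.shape[0] < min_voxels:
            continue
        centers = origin + vox * grid
        mouth = float(bulk_neighbors[tuple(vox.T)].mean())
        lining: set[int] = set()
        for c in centers:
            for ai in tree.query_ball_point(c, max_reach):
                if np.linalg.norm(coords[ai] - c) <= vdw[ai] + small_probe + grid:
                    lining.add(int(respos[ai]))
        pockets.append(Pocket(vox.shape[0] * grid**3, mouth, frozenset(lining)))
    pockets.sort(key=lambda p: -p.volume)
    return pockets


def pocket_variation_with_idrs(
    pv1: float, pv2: float, pv1_idr: float, pv2_idr: float
) -> float:
    """|max(pV1_IDR, pV2_IDR) - max(pV1, pV2)| / max of both maxima.

    ``pVi`` is the largest pocket volume of conformer i; ``pVi_IDR`` the
    same after removing IDR residues.  Symmetric in the conformer
    arguments, bounded in [0, 1].
    """
    vals = (pv1, pv2, pv1_idr, pv2_idr)
    if any(v < 0 for v in vals):
        raise ValueError("pocket volumes must be non-negative")
    m_plain = max(pv1, pv2)
    m_idr = max(pv1_idr, pv2_idr)
    denom = max(m_plain, m_idr)
    if denom == 0:
        raise ValueError("all pocket volumes are zero; variation undefined")
    return abs(m_idr - m_plain) / denom


# ---------------------------------------------------------------------------
# tunnels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Tunnel:
    path: np.ndarray  # (n, 3) polyline of voxel centers
    length: float  # arc length in A
    bottleneck_radius: float  # minimum clearance along the path
    lining_positions: frozenset[int]


_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _clearance_field(
    coords: np.ndarray, vdw: np.ndarray, origin: np.ndarray,
    shape: tuple[int, int, int], spacing: float,
) -> np.ndarray:
    """clearance(x) = min over atoms of (|x - a| - vdw) at voxel centers."""
    ax = [origin[d] + np.arange(shape[d]) * spacing for d in range(3)]
    pts = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(coords)
    k = min(24, coords.shape[0])
    dist, idx = tree.query(pts, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    clearance = (dist - vdw[idx]).min(axis=1)
    return clearance.reshape(shape)


def _widest_path(
    clearance: np.ndarray, passable: np.ndarray, start: tuple[int, int, int],
    targets: np.ndarray,
) -> Optional[list[tuple[int, int, int]]]:
    """Best-first search maximizing the minimum clearance along the path,
    from ``start`` to any voxel flagged in ``targets`` (6-connectivity)."""
    shape = clearance.shape
    best = np.full(shape, -np.inf)
    parent: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    c0 = clearance[start]
    best[start] = c0
    heap = [(-c0, start)]
    while heap:
        negb, node = heapq.heappop(heap)
        b = -negb
        if b < best[node]:
            continue
        if targets[node]:
            path = [node]
            while node in parent:
                node = parent[node]
                path.append(node)
            return path[::-1]
        for off in _NEIGHBORS6:
            nb = (node[0] + off[0], node[1] + off[1], node[2] + off[2])
            if not (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]):
                continue
            if not passable[nb]:
                continue
            nb_bottleneck = min(b, float(clearance[nb]))
            if nb_bottleneck > best[nb]:
                best[nb] = nb_bottleneck
                parent[nb] = node
                heapq.heappush(heap, (-nb_bottleneck, nb))
    return None


def detect_tunnels(
    conf: ConformerStructure,
    start: Optional[np.ndarray] = None,
    grid: float = 1.0,
    origin_radius: float = 3.0,
    interior_threshold: float = 1.25,
    min_length: float = 5.0,
    max_tunnels: int = 3,
    lining_pad: float = 3.0,
) -> list[Tunnel]:
    """Grid clearance-field tunnel search.

    The clearance field is the distance to the nearest atom surface.  Bulk
    solvent is the boundary-connected region with clearance >= the origin
    radius, swept inward by that radius.  The start point is the deepest
    buried voxel (maximal clearance capped at the origin radius; ties by
    distance from bulk) unless given.  A widest-bottleneck path is traced
    from the start to bulk solvent over voxels with clearance >= the
    interior threshold; if a second, disjoint path leaves in another
    direction the two are merged into a single through-tunnel.  Tunnels
    shorter than ``min_length`` (measured over the buried portion of the
    path) are discarded.
    """
    coords, respos, elements = conf.heavy_atoms()
    if coords.shape[0] == 0:
        return []
    vdw = np.array([_vdw_radius(e) for e in elements])
    pad = vdw.max() + origin_radius + 2.0 * grid
    origin = coords.min(axis=0) - pad
    extent = coords.max(axis=0) + pad - origin
    shape = tuple(np.ceil(extent / grid).astype(int) + 1)
    clearance = _clearance_field(coords, vdw, origin, shape, grid)

    open_space = clearance >= origin_radius
    lab, _ = ndimage.label(open_space, structure=np.ones((3, 3, 3), dtype=bool))
    border = np.zeros(shape, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    exterior_labels = np.unique(lab[border & open_space])
    exterior = np.isin(lab, exterior_labels[exterior_labels > 0])
    bulk = ndimage.binary_dilation(exterior, structure=_ball_structure(origin_radius / grid))

    passable = clearance >= interior_threshold
    buried = passable & ~bulk
    if not buried.any():
        return []
    depth = ndimage.distance_transform_edt(~bulk, sampling=grid)

    def pick_start(candidates: np.ndarray) -> Optional[tuple[int, int, int]]:
        if start is not None:
            idx = np.round((np.asarray(start, dtype=float) - origin) / grid).astype(int)
            idx = tuple(np.clip(idx, 0, np.array(shape) - 1))
            return idx if candidates[idx] else None
        if not candidates.any():
            return None
        capped = np.where(candidates, np.minimum(clearance, origin_radius), -np.inf)
        score = capped + 1e-6 * np.where(candidates, depth, 0.0)
        return tuple(int(v) for v in np.unravel_index(np.argmax(score), shape))

    tree = cKDTree(coords)
    tunnels: list[Tunnel] = []
    blocked = np.zeros(shape, dtype=bool)
    for _ in range(max_tunnels):
        candidates = buried & ~blocked
        s = pick_start(candidates)
        if s is None:
            break
        avail = passable & ~blocked
        path1 = _widest_path(clearance, avail, s, bulk)
        if path1 is None:
            if start is not None:
                break
            blocked[s] = True
            continue
        # second, disjoint exit in the opposite direction -> through-tunnel
        avail2 = avail.copy()
        for node in path1[1:]:
            avail2[node] = False
        path2 = _widest_path(clearance, avail2, s, bulk)
        full = (path2[::-1][:-1] + path1) if path2 is not None else path1
        # measure only the buried portion (trim bulk voxels at the ends)
        inside = [node for node in full if not bulk[node]]
        if inside:
            pts = origin + np.array(inside, dtype=float) * grid
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) if len(pts) > 1 else np.array([])
            # breaks from trimming should not contribute phantom length
            length = float(seg[seg <= 2.0 * grid].sum())
        else:
            pts, length = np.zeros((0, 3)), 0.0
        bottleneck = float(min(clearance[node] for node in full))
        for node in full:
            blocked[node] = True
        blocked |= ndimage.binary_dilation(blocked, _ball_structure(2.0 / grid))
        if length < min_length or bottleneck < interior_threshold:
            if start is not None:
                break
            continue
        lining: set[int] = set()
        for c in pts:
            for ai in tree.query_ball_point(c, bottleneck + lining_pad):
                lining.add(int(respos[ai]))
        tunnels.append(Tunnel(pts, length, bottleneck, frozenset(lining)))
        if start is not None:
            break
    tunnels.sort(key=lambda t: -t.length)
    return tunnels


def export_tunnel_pdb(tunnels: Sequence[Tunnel], path) -> None:
    """Write tunnel paths as PDB-format pseudo-atom traces (HETATM, element
    X as helium-sized dummies) for visual inspection alongside the protein."""
    lines = []
    serial = 1
    for t_idx, t in enumerate(tunnels):
        for p in t.path:
            lines.append(
                f"HETATM{serial:5d}  DOT TUN {chr(65 + t_idx % 26)}{serial % 10000:4d}    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{1.00:6.2f}{t.bottleneck_radius:6.2f}          He"
            )
            serial += 1
    lines.append("END")
    from pathlib import Path as _Path

    _Path(path).write_text("\n".join(lines) + "\n")


def tunnel_variation(l1: float, l2: float) -> float:
    """|L1 - L2| / max(L1, L2) for the longest-tunnel lengths of the two
    conformers of the max-RMSD pair."""
    if l1 < 0 or l2 < 0:
        raise ValueError("tunnel lengths must be non-negative")
    m = max(l1, l2)
    if m == 0:
        raise ValueError("both tunnel lengths are zero; variation undefined")
    return abs(l1 - l2) / m


# ---------------------------------------------------------------------------
# hinges
# ---------------------------------------------------------------------------


def _segment_rmsd_tables(a: np.ndarray, b: np.ndarray):
    """Prefix sums enabling O(1) covariance for any contiguous segment."""
    outer = np.einsum("ni,nj->nij", b, a)
    return (
        np.concatenate([[np.zeros(3)], np.cumsum(a, axis=0)]),
        np.concatenate([[np.zeros(3)], np.cumsum(b, axis=0)]),
        np.concatenate([[np.zeros((3, 3))], np.cumsum(outer, axis=0)]),
        np.concatenate([[0.0], np.cumsum((a * a).sum(axis=1))]),
        np.concatenate([[0.0], np.cumsum((b * b).sum(axis=1))]),
    )


def _segment_rmsd(tables, i: int, j: int) -> float:
    """Optimal-superposition RMSD of paired coordinates i..j (inclusive)."""
    sa, sb, sba, sa2, sb2 = tables
    n = j - i + 1
    va = sa[j + 1] - sa[i]
    vb = sb[j + 1] - sb[i]
    h = (sba[j + 1] - sba[i]) - np.outer(vb, va) / n
    e0 = (sa2[j + 1] - sa2[i] - (va @ va) / n) + (sb2[j + 1] - sb2[i] - (vb @ vb) / n)
    s = np.linalg.svd(h, compute_uv=False)
    d = np.sign(np.linalg.det(h))
    if d == 0:
        d = 1.0
    tr = s[0] + s[1] + d * s[2]
    return float(np.sqrt(max(e0 - 2.0 * tr, 0.0) / n))


def count_hinges(
    ens: EnsembleRecord,
    pair: MaxPair,
    rigid_rmsd_threshold: float = 1.5,
    min_segment: int = 15,
    max_breakpoints: int = 10,
) -> tuple[int, list[int], bool]:
    """Rigid-segment decomposition of the max-RMSD pair by dynamic programming.

    Finds the minimal number of breakpoints such that every contiguous
    segment (>= ``min_segment`` common positions) superposes with RMSD <=
    the threshold.  Returns ``(n_hinges, hinge seq_pos boundaries, flagged)``;
    when no decomposition with at most ``max_breakpoints`` exists the count
    saturates at ``max_breakpoints`` and ``flagged`` is True.
    """
    a_id, b_id = pair.pair
    common = ens.common_observed_positions(a_id, b_id)
    if len(common) < 20:
        raise ValueError(f"{ens.protein_id}: max pair shares only {len(common)} positions")
    xa = ens.conformer(a_id).ca_coords(common)
    xb = ens.conformer(b_id).ca_coords(common)
    tables = _segment_rmsd_tables(xa, xb)
    n = len(common)

    INF = 10**9
    # cost[j]: (segments, total squared error) covering positions [0, j);
    # the secondary objective pins breakpoints to the actual hinge sites
    cost: list[tuple[int, float]] = [(INF, np.inf)] * (n + 1)
    back = [-1] * (n + 1)
    cost[0] = (0, 0.0)
    for j in range(min_segment, n + 1):
        for i in range(0, j - min_segment + 1):
            segs, err = cost[i]
            if segs >= INF:
                continue
            r = _segment_rmsd(tables, i, j - 1)
            if r > rigid_rmsd_threshold:
                continue
            cand = (segs + 1, err + r * r * (j - i))
            if cand < cost[j]:
                cost[j] = cand
                back[j] = i
    fmin = [c[0] for c in cost]
    if fmin[n] >= INF or fmin[n] - 1 > max_breakpoints:
        return max_breakpoints, [], True
    bounds: list[int] = []
    j = n
    while back[j] > 0:
        j = back[j]
        bounds.append(common[j])  # seq_pos of the first residue after the hinge
    return fmin[n] - 1, sorted(bounds), False


# ---------------------------------------------------------------------------
# solvent accessibility
# ---------------------------------------------------------------------------


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci-spiral unit sphere points."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def sasa(
    conf: ConformerStructure, n_points: int = 960, probe: float = 1.4
) -> np.ndarray:
    """Shrake-Rupley accessible surface area per heavy atom (A^2).

    Deterministic sphere sampling (spiral points), 1.4 A probe by default.
    Returns areas in the order of :meth:`ConformerStructure.heavy_atoms`.
    """
    coords, _, elements = conf.heavy_atoms()
    if coords.shape[0] == 0:
        return np.zeros(0)
    radii = np.array([_vdw_radius(e) + probe for e in elements])
    sphere = _spiral_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(coords.shape[0])
    for i in range(coords.shape[0]):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed / n_points
    return areas


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------


def ligand_stats(ens: EnsembleRecord, min_heavy_atoms: int = 6) -> dict:
    """Cognate-ligand inventory of an ensemble.

    A ligand qualifies as cognate when it has at least ``min_heavy_atoms``
    heavy atoms (ions and buffer components fall below).  A conformer is
    holo iff it carries at least one qualifying ligand.
    """
    seen: dict[str, float] = {}
    apo, holo = [], []
    for conf in ens.conformers:
        qualifying = [l for l in conf.ligands if l.n_heavy_atoms >= min_heavy_atoms]
        (holo if qualifying else apo).append(conf.conformer_id)
        for lig in qualifying:
            seen.setdefault(lig.het_code, lig.molecular_weight)
    return {
        "n_distinct_ligands": len(seen),
        "mean_ligand_mw": float(np.mean(list(seen.values()))) if seen else 0.0,
        "apo_ids": sorted(apo),
        "holo_ids": sorted(holo),
    }


# ---------------------------------------------------------------------------
# assembled descriptor set
# ---------------------------------------------------------------------------


@dataclass
class DescriptorSet:
    protein_id: str
    rg_norm_mean: float = np.nan
    avg_degree: float = np.nan
    pocket_vol_max: float = 0.0
    pocket_variation_idr: float = np.nan
    tunnel_len_max: float = 0.0
    tunnel_variation: float = np.nan
    tunnel_len_ratio: float = 0.0
    n_hinges: int = 0
    n_distinct_ligands: int = 0
    mean_ligand_mw: float = 0.0
    ss_fractions: tuple[float, float, float] = (0.0, 0.0, 1.0)
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        h, e, c = self.ss_fractions
        return {
            "protein_id": self.protein_id,
            "rg_norm_mean": self.rg_norm_mean,
            "avg_degree": self.avg_degree,
            "pocket_vol_max": self.pocket_vol_max,
            "pocket_variation_idr": self.pocket_variation_idr,
            "tunnel_len_max": self.tunnel_len_max,
            "tunnel_variation": self.tunnel_variation,
            "tunnel_len_ratio": self.tunnel_len_ratio,
            "n_hinges": self.n_hinges,
            "n_distinct_ligands": self.n_distinct_ligands,
            "mean_ligand_mw": self.mean_ligand_mw,
            "ss_frac_helix": h,
            "ss_frac_strand": e,
            "ss_frac_coil": c,
        }


def compute_descriptors(
    ens: EnsembleRecord,
    idrs,
    max_pair: MaxPair,
    contact_cutoff: float = 5.0,
    do_pockets: bool = True,
    do_tunnels: bool = True,
    do_hinges: bool = True,
    min_heavy_atoms: int = 6,
) -> DescriptorSet:
    """Per-protein descriptor set, evaluated on the max-RMSD conformer pair
    (ligand statistics use the whole ensemble)."""
    ds = DescriptorSet(protein_id=ens.protein_id)
    pair_confs = [ens.conformer(cid) for cid in max_pair.pair]

    ds.rg_norm_mean = float(np.mean([radius_of_gyration_normalized(c) for c in pair_confs]))
    ds.avg_degree = float(
        np.mean([residue_network_degree(c, cutoff=contact_cutoff)[1] for c in pair_confs])
    )
    fr = [ss_fractions(assign_secondary_structure(c)) for c in pair_confs]
    ds.ss_fractions = tuple(float(np.mean([f[i] for f in fr])) for i in range(3))

    idr_union: set[int] = set()
    for ann in idrs:
        idr_union |= ann.positions()

    if do_pockets:
        def largest_pocket(c: ConformerStructure, excl=()) -> float:
            pockets = detect_pockets(c, exclude_positions=excl)
            return pockets[0].volume if pockets else 0.0

        pv = [largest_pocket(c) for c in pair_confs]
        ds.pocket_vol_max = float(max(pv))
        pv_idr = [largest_pocket(c, idr_union) for c in pair_confs] if idr_union else pv
        try:
            ds.pocket_variation_idr = pocket_variation_with_idrs(pv[0], pv[1], pv_idr[0], pv_idr[1])
        except ValueError:
            ds.flags.append("pocket_variation_undefined")

    if do_tunnels:
        lengths = []
        for c in pair_confs:
            tl = detect_tunnels(c)
            lengths.append(tl[0].length if tl else 0.0)
        ds.tunnel_len_max = float(max(lengths))
        try:
            ds.tunnel_variation = tunnel_variation(lengths[0], lengths[1])
        except ValueError:
            ds.flags.append("tunnel_variation_undefined")
        ds.tunnel_len_ratio = float(
            np.mean([l / max(c.n_observed, 1) for l, c in zip(lengths, pair_confs)])
        )

    if do_hinges:
        try:
            n_h, _, flagged = count_hinges(ens, max_pair)
            ds.n_hinges = n_h
            if flagged:
                ds.flags.append("hinge_decomposition_saturated")
        except ValueError as exc:
            ds.flags.append(f"hinges_failed:{exc}")

    lig = ligand_stats(ens, min_heavy_atoms=min_heavy_atoms)
    ds.n_distinct_ligands = lig["n_distinct_ligands"]
    ds.mean_ligand_mw = lig["mean_ligand_mw"]
    return ds
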