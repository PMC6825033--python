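"""Benchmark geometries: single-edge-notched plate and layered aortic tube.

Both meshes are generated programmatically.  The plate is a structured
plane-strain quadrilateral grid with the notch modelled as a geometric slit
(duplicated node line) from the mid-left edge to the center.  The tube is a
structured cylindrical grid of six concentric layers (four medial sub-layers
of 0.375 mm, two adventitial of 0.5 mm) split into tetrahedra with a Kuhn
subdivision; the initial tear is a meshed void spanning the innermost three
medial sub-layers radially, an arc of ``beta`` degrees circumferentially and
``w`` mm axially, centred at mid-height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import FiberFrame, MaterialParams
from .mesh import Mesh
from .phasefield import PhaseFieldParams

__all__ = [
    "NotchedPlateSpec",
    "TubeSpec",
    "make_notched_plate",
    "make_tube_segment",
    "assign_layers",
    "LayerAssignment",
    "aorta_layer_table",
    "healthy_from_degenerated",
    "DEGENERATED_MEDIA",
    "HEALTHY_MEDIA",
    "ADVENTITIA",
    "DEGENERATED_MEDIA_PF",
    "HEALTHY_MEDIA_PF",
    "ADVENTITIA_PF",
]


# --------------------------------------------------------------- SEN plate
@dataclass(frozen=True)
class NotchedPlateSpec:
    """Square single-edge-notched plate (plane strain).

    The canonical configuration: unit square with a slit from the middle of
    the left edge to the center; the bottom edge is held (u_y = 0) and the
    top edge is pulled vertically.
    """

    side: float = 1.0          # mm
    notch_length: float = 0.5  # mm, slit from the left edge at mid-height
    h: float = 0.02            # target element size, mm
    fiber_angle: float = 45.0  # degrees from the x-axis

    def __post_init__(self) -> None:
        if not (0 < self.notch_length < self.side):
            raise ValueError("notch length must lie inside the plate")
        if self.h <= 0 or self.h > self.side / 4:
            raise ValueError(f"element size h = {self.h} incompatible with the plate")


def make_notched_plate(spec: NotchedPlateSpec) -> Mesh:
    """Structured quad mesh of the notched square with a duplicated-node slit.

    Node sets: ``bottom``, ``top``, ``bottom_left`` (single corner node for
    rigid-mode control).  The slit faces are traction-free.
    """
    L = spec.side
    nx = max(4, int(round(L / spec.h)))
    ny = nx if nx % 2 == 0 else nx + 1  # even so the slit lies on a node line
    nx = ny
    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, L, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):  # column i, row j
        return j * (nx + 1) + i

    jm = ny // 2  # node row at mid-height
    tip_i = int(round(spec.notch_length / L * nx))
    # duplicate slit nodes (strictly left of the tip); elements below the
    # slit keep the duplicates so the two crack faces can separate
    slit_cols = np.arange(0, tip_i)
    dup_ids = {}
    extra = []
    for i in slit_cols:
        dup_ids[i] = len(nodes) + len(extra)
        extra.append(nodes[nid(i, jm)])
    if extra:
        nodes = np.vstack([nodes, np.asarray(extra)])

    elems = []
    for j in range(ny):
        for i in range(nx):
            n00, n10, n11, n01 = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            if j == jm - 1:  # row directly below the slit: remap top nodes
                if i in dup_ids:
                    n01 = dup_ids[i]
                if (i + 1) in dup_ids:
                    n11 = dup_ids[i + 1]
            elems.append([n00, n10, n11, n01])
    elems = np.asarray(elems, dtype=np.int64)

    bottom = np.array([nid(i, 0) for i in range(nx + 1)])
    top = np.array([nid(i, ny) for i in range(nx + 1)])
    mesh = Mesh(nodes=nodes, elements=elems, cell_type="quad")
    mesh.node_sets = {"bottom": bottom, "top": top, "bottom_left": np.array([nid(0, 0)])}
    return mesh


# ------------------------------------------------------------------- tube
@dataclass(frozen=True)
class TubeSpec:
    """Idealized multi-layer thoracic-aorta segment with an initial tear.

    Defaults reproduce the reference geometry: inner radius 15 mm, outer
    radius 17.5 mm, height 40 mm, four medial sub-layers of 0.375 mm and two
    adventitial layers of 0.5 mm; the tear has arc angle ``beta`` (degrees),
    axial width ``w`` and cuts through the innermost three medial sub-layers.
    """

    Ri: float = 15.0
    H: float = 40.0
    t_med: float = 0.375
    t_adv: float = 0.5
    n_med: int = 4
    n_adv: int = 2
    beta: float = 30.0        # tear arc angle, degrees
    w: float = 2.0            # tear axial width, mm
    tear_layers: int = 3      # radial extent of the tear, in medial sub-layers
    n_theta: int = 36         # circumferential element count
    n_z: int = 16             # axial element count
    n_r_per_layer: int = 1    # radial elements per sub-layer

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < 180.0):
            raise ValueError("tear angle beta must lie in (0, 180) degrees (0 = no tear)")
        if self.tear_layers > self.n_med - 1:
            raise ValueError(
                f"tear through {self.tear_layers} medial sub-layers exceeds the "
                f"admissible depth of {self.n_med - 1}"
            )

    @property
    def Ro(self) -> float:
        return self.Ri + self.n_med * self.t_med + self.n_adv * self.t_adv

    @property
    def layer_radii(self) -> np.ndarray:
        """Interface radii, inner wall to outer wall (n_layers + 1 values)."""
        t = [self.t_med] * self.n_med + [self.t_adv] * self.n_adv
        return self.Ri + np.concatenate([[0.0], np.cumsum(t)])

    @property
    def tear_arc_length(self) -> float:
        """Circumferential tear length pi * Ri * beta / 180 (mm)."""
        return np.pi * self.Ri * self.beta / 180.0


# Kuhn subdivision of the unit cube: 6 tetrahedra along the main diagonal,
# conforming across translated copies of the cell.
_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def _kuhn_tets():
    tets = []
    for perm in _KUHN_PATHS:
        corners = [np.zeros(3, dtype=int)]
        acc = np.zeros(3, dtype=int)
        for axis in perm:
            acc = acc.copy()
            acc[axis] = 1
            corners.append(acc)
        tets.append(corners)
    return tets


def make_tube_segment(spec: TubeSpec) -> Mesh:
    """Tetrahedral mesh of the layered tube with the tear cut out.

    Region tags are the layer index (0..3 media, media 3 = index 2 the
    degenerated sub-layer; 4..5 adventitia).  Facet set ``inner`` carries the
    pressurized lumen surface (tear faces remain traction-free); node sets
    ``bottom`` and ``top`` tag the end planes for axial/twist conditions.
    """
    radii = spec.layer_radii
    # radial node positions, refined per layer
    r_nodes = [radii[0]]
    for a, b in zip(radii[:-1], radii[1:]):
        r_nodes.extend(np.linspace(a, b, spec.n_r_per_layer + 1)[1:])
    r_nodes = np.asarray(r_nodes)
    nr = len(r_nodes) - 1

    if spec.beta > 0.0:
        # circumferential grid aligned with the tear edges at +/- beta/2
        hb = np.deg2rad(spec.beta) / 2.0
        n_tear_t = max(2, int(round(spec.n_theta * spec.beta / 360.0)))
        n_rest_t = max(4, spec.n_theta - n_tear_t)
        thetas = np.concatenate([
            np.linspace(-hb, hb, n_tear_t + 1),
            np.linspace(hb, 2.0 * np.pi - hb, n_rest_t + 1)[1:-1],
        ])
        # axial grid aligned with the tear band [H/2 - w/2, H/2 + w/2]
        z1, z2 = spec.H / 2.0 - spec.w / 2.0, spec.H / 2.0 + spec.w / 2.0
        n_mid_z = max(1, int(round(spec.n_z * spec.w / spec.H)))
        n_out_z = max(1, (spec.n_z - n_mid_z) // 2)
        zs = np.concatenate([
            np.linspace(0.0, z1, n_out_z + 1),
            np.linspace(z1, z2, n_mid_z + 1)[1:],
            np.linspace(z2, spec.H, n_out_z + 1)[1:],
        ])
        n_tear_iz = range(n_out_z, n_out_z + n_mid_z)
    else:  # intact tube
        n_tear_t = 0
        thetas = np.linspace(0.0, 2.0 * np.pi, spec.n_theta, endpoint=False)
        zs = np.linspace(0.0, spec.H, spec.n_z + 1)
        n_tear_iz = range(0)
    nt = len(thetas)
    nz = len(zs) - 1

    def nid(ir, itheta, iz):
        return (ir * nt + (itheta % nt)) * (nz + 1) + iz

    R, T, Z = np.meshgrid(r_nodes, thetas, zs, indexing="ij")
    nodes = np.column_stack(
        [(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(), Z.ravel()]
    )

    # hex cells in the tear void (indices): first n_tear_t theta columns,
    # middle z band, innermost tear_layers sub-layers
    tear_ir = spec.tear_layers * spec.n_r_per_layer if spec.beta > 0.0 else 0
    tear_iz = n_tear_iz

    kuhn = _kuhn_tets()
    elems, layer = [], []
    layer_of_ir = np.repeat(np.arange(len(radii) - 1), spec.n_r_per_layer)
    for ir in range(nr):
        for it in range(nt):
            for iz in range(nz):
                if ir < tear_ir and it < n_tear_t and iz in tear_iz:
                    continue  # meshed void: the initial tear
                base = np.array([ir, it, iz])
                for tet in kuhn:
                    elems.append([nid(*(base + c)) for c in tet])
                    layer.append(layer_of_ir[ir])
    elems = np.asarray(elems, dtype=np.int64)
    layer = np.asarray(layer, dtype=np.int64)

    # fix orientation: positive volume for all tets
    a = nodes[elems[:, 1]] - nodes[elems[:, 0]]
    b = nodes[elems[:, 2]] - nodes[elems[:, 0]]
    c = nodes[elems[:, 3]] - nodes[elems[:, 0]]
    vol6 = np.einsum("ei,ei->e", np.cross(a, b), c)
    neg = vol6 < 0
    elems[neg, 2], elems[neg, 3] = elems[neg, 3].copy(), elems[neg, 2].copy()

    # drop orphan nodes
    used = np.unique(elems)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = Mesh(nodes=nodes[used], elements=remap[elems], cell_type="tet", region=layer)

    r_node = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
    tol = 1e-8 * spec.Ri
    mesh.node_sets = {
        "bottom": np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-9 * spec.H),
        "top": np.flatnonzero(np.abs(mesh.nodes[:, 2] - spec.H) < 1e-9 * spec.H),
    }
    boundary = mesh.boundary_facets()
    on_inner = np.all(r_node[boundary] < spec.Ri + tol + 1e-9, axis=1)
    mesh.facet_sets = {"inner": boundary[on_inner]}
    return mesh


# ---------------------------------------------------------- layer materials
def _round_half_up(x: float, ndigits: int = 2) -> float:
    """Table-style decimal rounding (0.005 rounds up, unlike float round)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def healthy_from_degenerated(mat: MaterialParams) -> MaterialParams:
    """Healthy-media constants: degenerated values raised by 20% and rounded
    to two decimals (the precision of the published layer table; the fiber
    angle is not scaled, only rounded)."""
    return MaterialParams(
        mu=_round_half_up(mat.mu * 1.2),
        k1=_round_half_up(mat.k1 * 1.2),
        k2=_round_half_up(mat.k2 * 1.2),
        alpha=_round_half_up(mat.alpha),
        kappa=mat.kappa,
        fibers_tension_only=mat.fibers_tension_only,
    )


# Fitted constants of the degenerated media (full precision) and the
# published per-layer table values.
FITTED_MEDIA = MaterialParams(mu=83.509, k1=101.651, k2=4.173, alpha=44.705)
DEGENERATED_MEDIA = MaterialParams(mu=83.51, k1=101.65, k2=4.17, alpha=44.71)
HEALTHY_MEDIA = healthy_from_degenerated(FITTED_MEDIA)          # 100.21 / 121.98 / 5.01
ADVENTITIA = MaterialParams(mu=200.0, k1=400.0, k2=4.0, alpha=44.71)

_PF_COMMON = dict(l=0.1875, omega_M=1e3, omega_Mp=1e3)
DEGENERATED_MEDIA_PF = PhaseFieldParams(gc_iso_over_l=6.0, gc_ani_over_l=18.0, **_PF_COMMON)
HEALTHY_MEDIA_PF = PhaseFieldParams(gc_iso_over_l=100.0, gc_ani_over_l=300.0, **_PF_COMMON)
ADVENTITIA_PF = HEALTHY_MEDIA_PF


def aorta_layer_table(kappa_ratio: float = 3.0, l: float = 0.1875) -> dict:
    """Per-layer (MaterialParams, PhaseFieldParams) for the six-layer tube.

    Layer tags 0..3 are the medial sub-layers (tag 2 = *media 3*, the
    degenerated layer), tags 4..5 the adventitia.  ``kappa_ratio`` sets the
    bulk modulus as a multiple of each layer's shear modulus (the ratio used
    in the plate sensitivity study).
    """
    def with_kappa(m: MaterialParams) -> MaterialParams:
        return MaterialParams(mu=m.mu, k1=m.k1, k2=m.k2, alpha=m.alpha,
                              kappa=kappa_ratio * m.mu)

    def with_l(pf: PhaseFieldParams) -> PhaseFieldParams:
        return PhaseFieldParams(l=l, gc_iso_over_l=pf.gc_iso_over_l,
                                gc_ani_over_l=pf.gc_ani_over_l,
                                omega_M=pf.omega_M, omega_Mp=pf.omega_Mp,
                                eta=pf.eta, a_iso=pf.a_iso, a_ani=pf.a_ani)

    healthy = (with_kappa(HEALTHY_MEDIA), with_l(HEALTHY_MEDIA_PF))
    table = {
        0: healthy,
        1: healthy,
        2: (with_kappa(DEGENERATED_MEDIA), with_l(DEGENERATED_MEDIA_PF)),
        3: healthy,
        4: (with_kappa(ADVENTITIA), with_l(ADVENTITIA_PF)),
        5: (with_kappa(ADVENTITIA), with_l(ADVENTITIA_PF)),
    }
    return table


@dataclass
class LayerAssignment:
    """Per-element material lookup plus per-element fiber frames."""

    materials: dict              # tag -> (MaterialParams, PhaseFieldParams)
    frames: FiberFrame           # batched per-element M / Mp, shape (ne, 3)


def assign_layers(mesh: Mesh, table: dict) -> LayerAssignment:
    """Attach layer materials and cylindrical fiber frames to a tube mesh.

    Fibers run at +/- alpha to the local circumferential direction in each
    element's theta-z tangent plane, with alpha taken from that layer's
    material constants.

    Raises
    ------
    KeyError
        If a region tag present in the mesh is missing from ``table``.
    """
    tags = np.unique(mesh.region)
    missing = [int(t) for t in tags if t not in table]
    if missing:
        raise KeyError(
            f"region tags {missing} missing from the layer table (present: {sorted(table)})"
        )
    cent = mesh.centroids()
    theta = np.arctan2(cent[:, 1], cent[:, 0])
    e_theta = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    e_z = np.tile([0.0, 0.0, 1.0], (len(cent), 1))
    alpha = np.empty(len(cent))
    for tag in tags:
        alpha[mesh.region == tag] = table[int(tag)][0].alpha
    a = np.deg2rad(alpha)[:, None]
    M = np.cos(a) * e_theta + np.sin(a) * e_z
    Mp = np.cos(a) * e_theta - np.sin(a) * e_z
    return LayerAssignment(materials={int(t): table[int(t)] for t in tags},
                           frames=FiberFrame(M=M, Mp=Mp))
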