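"""Mesh container and exchange formats.

A :class:`Mesh` holds nodes, homogeneous connectivity (4-node quadrilaterals
for plane strain, 4-node tetrahedra in 3-D), per-element region tags (layer
ids) and named node/facet sets used for boundary conditions.

Exchange formats are all plain text: a native JSON mesh, a compact Gmsh MSH
v4.1 ASCII writer/reader (nodes + elements, one entity block per region),
and VTK unstructured-grid XML (.vtu) output with point and cell data plus a
.pvd collection for time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Mesh", "write_vtu", "write_pvd"]

# VTK / Gmsh cell ids for the two supported element types
_VTK_ID = {"quad": 9, "tet": 10}
_GMSH_ID = {"quad": 3, "tet": 4}
_GMSH_ID_INV = {v: k for k, v in _GMSH_ID.items()}


@dataclass
class Mesh:
    nodes: np.ndarray          # (nn, dim) coordinates, mm
    elements: np.ndarray       # (ne, 4) connectivity
    cell_type: str             # "quad" or "tet"
    region: np.ndarray = None  # (ne,) int region/layer tag
    node_sets: dict = field(default_factory=dict)   # name -> (k,) node ids
    facet_sets: dict = field(default_factory=dict)  # name -> (f, dim) node tuples

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.cell_type not in _VTK_ID:
            raise ValueError(f"unsupported cell type {self.cell_type!r}")
        if self.region is None:
            self.region = np.zeros(len(self.elements), dtype=np.int64)
        self.region = np.asarray(self.region, dtype=np.int64)

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    # ------------------------------------------------------------------ JSON
    def to_json(self, path) -> None:
        payload = {
            "cell_type": self.cell_type,
            "nodes": self.nodes.tolist(),
            "elements": self.elements.tolist(),
            "region": self.region.tolist(),
            "node_sets": {k: np.asarray(v).tolist() for k, v in self.node_sets.items()},
            "facet_sets": {k: np.asarray(v).tolist() for k, v in self.facet_sets.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "Mesh":
        payload = json.loads(Path(path).read_text())
        return cls(
            nodes=np.asarray(payload["nodes"], dtype=float),
            elements=np.asarray(payload["elements"], dtype=np.int64),
            cell_type=payload["cell_type"],
            region=np.asarray(payload["region"], dtype=np.int64),
            node_sets={k: np.asarray(v, dtype=np.int64) for k, v in payload["node_sets"].items()},
            facet_sets={k: np.asarray(v, dtype=np.int64) for k, v in payload["facet_sets"].items()},
        )

    # ------------------------------------------------------------- Gmsh MSH
    def to_msh(self, path) -> None:
        """Write Gmsh MSH v4.1 ASCII (nodes + one element block per region).

        Node/facet sets are not representable without physical groups and are
        dropped; use the JSON format for a lossless round trip.
        """
        lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
        nn = self.n_nodes
        dim = self.dim
        # single 3-entity node block
        lines += ["$Nodes", f"1 {nn} 1 {nn}", f"{3} 1 0 {nn}"]
        lines += [str(i + 1) for i in range(nn)]
        for x in self.nodes:
            xyz = np.zeros(3)
            xyz[:dim] = x
            lines.append(f"{xyz[0]:.16g} {xyz[1]:.16g} {xyz[2]:.16g}")
        lines.append("$EndNodes")
        tags = np.unique(self.region)
        ne = self.n_elements
        lines += ["$Elements", f"{len(tags)} {ne} 1 {ne}"]
        gdim = 2 if self.cell_type == "quad" else 3
        eid = 1
        for tag in tags:
            idx = np.flatnonzero(self.region == tag)
            lines.append(f"{gdim} {int(tag) + 1} {_GMSH_ID[self.cell_type]} {len(idx)}")
            for e in idx:
                conn = " ".join(str(n + 1) for n in self.elements[e])
                lines.append(f"{eid} {conn}")
                eid += 1
        lines.append("$EndElements")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_msh(cls, path) -> "Mesh":
        """Read the subset of Gmsh MSH v4.1 ASCII written by :meth:`to_msh`."""
        tok = Path(path).read_text().split("\n")
        it = iter(tok)

        def seek(section):
            for line in it:
                if line.strip() == section:
                    return
            raise ValueError(f"section {section} not found in MSH file")

        seek("$Nodes")
        header = next(it).split()
        n_blocks, nn = int(header[0]), int(header[1])
        coords = np.empty((nn, 3))
        pos = 0
        for _ in range(n_blocks):
            bh = next(it).split()
            n_in_block = int(bh[3])
            ids = [int(next(it)) for _ in range(n_in_block)]
            for k in range(n_in_block):
                coords[ids[k] - 1] = [float(v) for v in next(it).split()]
            pos += n_in_block
        seek("$Elements")
        header = next(it).split()
        n_blocks = int(header[0])
        elems, regions, cell_type = [], [], None
        for _ in range(n_blocks):
            bh = next(it).split()
            tag, etype, n_in_block = int(bh[1]) - 1, int(bh[2]), int(bh[3])
            cell_type = _GMSH_ID_INV[etype]
            for _ in range(n_in_block):
                parts = [int(v) for v in next(it).split()]
                elems.append([v - 1 for v in parts[1:]])
                regions.append(tag)
        elems = np.asarray(elems, dtype=np.int64)
        dim = 2 if cell_type == "quad" else 3
        return cls(nodes=coords[:, :dim], elements=elems, cell_type=cell_type,
                   region=np.asarray(regions))

    # ------------------------------------------------------------ facets
    def boundary_facets(self) -> np.ndarray:
        """Facets (edges in 2-D, triangles in 3-D) on the mesh boundary.

        A facet is on the boundary iff it belongs to exactly one element.
        Returned with the orientation induced by its element.
        """
        if self.cell_type == "quad":
            local = [(0, 1), (1, 2), (2, 3), (3, 0)]
        else:
            # faces of tet (0,1,2,3) with outward orientation
            local = [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)]
        faces = np.concatenate([self.elements[:, f] for f in local], axis=0)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]


# --------------------------------------------------------------------- VTK
def _fmt_array(name, data, n_comp):
    body = " ".join(f"{v:.7g}" for v in np.asarray(data, dtype=float).ravel())
    return (
        f'<DataArray type="Float64" Name="{name}" '
        f'NumberOfComponents="{n_comp}" format="ascii">{body}</DataArray>'
    )


def write_vtu(mesh: Mesh, path, point_data=None, cell_data=None) -> None:
    """Write an ASCII VTK unstructured-grid (.vtu) file.

    ``point_data``/``cell_data`` map names to arrays of shape (n, ) or
    (n, k); 2-D displacement fields are padded to 3 components.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    nn, ne = mesh.n_nodes, mesh.n_elements
    xyz = np.zeros((nn, 3))
    xyz[:, : mesh.dim] = mesh.nodes
    conn = " ".join(str(v) for v in mesh.elements.ravel())
    offs = " ".join(str(v) for v in (np.arange(1, ne + 1) * mesh.elements.shape[1]))
    types = " ".join([str(_VTK_ID[mesh.cell_type])] * ne)

    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">',
        "<Points>", _fmt_array("points", xyz, 3), "</Points>",
        "<Cells>",
        f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>',
        f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>',
        f'<DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>',
        "</Cells>",
    ]
    parts.append("<PointData>")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            arr = np.hstack([arr, np.zeros((len(arr), 1))])
        n_comp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(_fmt_array(name, arr, n_comp))
    parts.append("</PointData>")
    parts.append("<CellData>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        n_comp = 1 if arr.ndim == 1 else arr.shape[1]
        parts.append(_fmt_array(name, arr, n_comp))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def write_pvd(path, entries) -> None:
    """Write a ParaView collection; ``entries`` is a list of (time, filename)."""
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="Collection" version="0.1">',
        "<Collection>",
    ]
    for t, fname in entries:
        lines.append(f'<DataSet timestep="{t:.6g}" file="{fname}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))
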