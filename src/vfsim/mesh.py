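"""Tetrahedral mesh container and plain-text mesh export.

Coordinate convention used throughout the package: ``x`` is axial
(streamwise, inferior -> superior), ``y`` is anterior-posterior, ``z`` is
lateral (the direction of vocal-fold vibration).  All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshGenerationError

# facet tag codes
TAG_FIXED = 0
TAG_LUMEN = 1

# element layer codes
LAYER_BODY = 0
LAYER_COVER = 1

# local faces of a positively oriented tet, outward-wound
_TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


@dataclass
class LarynxGeometry:
    """Bilateral vocal-fold solid mesh embedded in a straight airway duct.

    The solid mesh covers the two vocal folds; the downstream ventricle,
    false vocal fold and supraglottal duct are rigid and enter only through
    the lumen area profile (``rigid_half_gap``).

    Attributes
    ----------
    nodes : (n_nodes, 3) float
        Reference coordinates in metres.
    elements : (n_elem, 4) int
        Tetrahedral connectivity, 0-based, positively oriented.
    layer_labels : (n_elem,) int
        ``LAYER_BODY`` or ``LAYER_COVER`` per element.
    boundary_facets : (n_facet, 3) int
        Boundary triangles wound so the normal points out of the solid
        (into the lumen for lumen facets).
    boundary_tags : (n_facet,) int
        ``TAG_FIXED`` or ``TAG_LUMEN`` per boundary facet.
    lumen_axis : (n_station,) float
        Ordered axial station coordinates spanning inlet to outlet.
    medial_grids : tuple of (nx+1, ny+1) int arrays
        Structured node-id grids of the two medial (lumen) surfaces,
        index 0 = right fold (z > 0), index 1 = left fold.
    rigid_half_gap : (n_station,) float
        Half-gap of the rigid duct wall at each lumen-axis station; inside
        the fold axial extent it holds the *rest* fold half-gap (the moving
        surface overrides it when a displacement field is supplied).
    """

    nodes: np.ndarray
    elements: np.ndarray
    layer_labels: np.ndarray
    boundary_facets: np.ndarray
    boundary_tags: np.ndarray
    lumen_axis: np.ndarray
    medial_grids: tuple
    rigid_half_gap: np.ndarray
    span: float                      # anterior-posterior duct depth (m)
    fold_x_range: tuple              # axial extent (x_lo, x_hi) of the solid mesh
    rest_min_area: float             # rest glottal (minimum) lumen area (m^2)
    marker_node: int                 # node id used for the vibration trace
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def lumen_facets(self) -> np.ndarray:
        return self.boundary_facets[self.boundary_tags == TAG_LUMEN]

    @property
    def fixed_nodes(self) -> np.ndarray:
        """Sorted ids of nodes on the fixed exterior boundary."""
        return np.unique(self.boundary_facets[self.boundary_tags == TAG_FIXED])

    def element_volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.elements)


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for proper orientation)."""
    x = nodes[elements]                    # (ne, 4, 3)
    d = x[:, 1:] - x[:, :1]                # (ne, 3, 3)
    return np.linalg.det(d) / 6.0


def extract_boundary(elements: np.ndarray):
    """Outward-oriented boundary triangles of a tet mesh.

    Returns (facets, owner_elements); facets keep the winding inherited
    from their owning tet, so their normals point out of the solid.
    """
    ne = elements.shape[0]
    faces = np.concatenate(
        [elements[:, f] for f in _TET_FACES], axis=0
    )                                          # (4*ne, 3)
    owners = np.tile(np.arange(ne), 4)
    key = np.sort(faces, axis=1)
    # boundary faces occur exactly once
    _, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    mask = counts[inv] == 1
    return faces[mask], owners[mask]


def facet_areas_normals(nodes: np.ndarray, facets: np.ndarray):
    """Per-facet area and unit outward normal on (possibly deformed) nodes."""
    p = nodes[facets]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    a2 = np.linalg.norm(cross, axis=1)
    if np.any(a2 <= 0):
        raise MeshGenerationError("degenerate boundary facet with zero area")
    return 0.5 * a2, cross / a2[:, None]


def check_watertight(geometry: LarynxGeometry, tol: float = 1e-9) -> None:
    """Closed-surface check: boundary facet area-vectors must sum to ~0."""
    areas, normals = facet_areas_normals(geometry.nodes, geometry.boundary_facets)
    net = np.abs((areas[:, None] * normals).sum(axis=0)).max()
    if net > tol * areas.sum():
        raise MeshGenerationError(
            f"boundary is not closed: net area vector {net:.3e}"
        )


# ---------------------------------------------------------------------------
# plain-text export (VTU XML, STL, and a simple node/element/tag format)
# ---------------------------------------------------------------------------

def write_vtu(path, geometry: LarynxGeometry, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the volume mesh as an ASCII VTK unstructured grid (.vtu)."""
    nodes, elems = geometry.nodes, geometry.elements
    nn, ne = len(nodes), len(elems)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("layer", geometry.layer_labels)

    def arr(a, per_line=1):
        a = np.asarray(a)
        flat = a.reshape(a.shape[0], -1)
        return "\n".join(" ".join(repr(v) for v in row) for row in flat)

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(nodes),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(elems),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(4 * (i + 1)) for i in range(ne)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join("10" for _ in range(ne)),
        "</DataArray>", "</Cells>",
    ]
    if point_data:
        lines.append("<PointData>")
        for name, data in point_data.items():
            data = np.asarray(data)
            nc = 1 if data.ndim == 1 else data.shape[1]
            lines += [
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{nc}" format="ascii">',
                arr(data), "</DataArray>",
            ]
        lines.append("</PointData>")
    lines.append("<CellData>")
    for name, data in cell_data.items():
        lines += [
            f'<DataArray type="Float64" Name="{name}" format="ascii">',
            arr(np.asarray(data, dtype=float)), "</DataArray>",
        ]
    lines.append("</CellData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_vtu_series(directory, geometry: LarynxGeometry, states,
                     stride: int = 1) -> list:
    """Export a sequence of solid states as numbered VTU files.

    ``states`` is an iterable of SolidState-like objects (or displacement
    arrays); displacement and velocity are written as point data.  Returns
    the written paths.
    """
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, st in enumerate(states):
        if i % stride:
            continue
        u = getattr(st, "displacement", st)
        pd = {"displacement": u}
        v = getattr(st, "velocity", None)
        if v is not None:
            pd["velocity"] = v
        path = directory / f"solid_{i:05d}.vtu"
        write_vtu(path, geometry, point_data=pd)
        written.append(path)
    return written


def write_stl(path, geometry: LarynxGeometry, tag: int | None = TAG_LUMEN,
              displacements: np.ndarray | None = None) -> None:
    """Export boundary facets (by default the lumen surface) as ASCII STL."""
    facets = geometry.boundary_facets
    if tag is not None:
        facets = geometry.boundary_facets[geometry.boundary_tags == tag]
    nodes = geometry.nodes
    if displacements is not None:
        nodes = nodes + displacements
    _, normals = facet_areas_normals(nodes, facets)
    with open(path, "w") as fh:
        fh.write("solid vfsim\n")
        for f, n in zip(facets, normals):
            fh.write(f"facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write(" outer loop\n")
            for nid in f:
                p = nodes[nid]
                fh.write(f"  vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid vfsim\n")


def write_mesh_text(path, geometry: LarynxGeometry) -> None:
    """Plain node/element/tag listing (one section per block, SI units)."""
    with open(path, "w") as fh:
        fh.write("# vfsim mesh (SI units; x axial, y anterior-posterior, z lateral)\n")
        fh.write(f"nodes {geometry.n_nodes}\n")
        for p in geometry.nodes:
            fh.write(f"{p[0]:.12e} {p[1]:.12e} {p[2]:.12e}\n")
        fh.write(f"elements {geometry.n_elements}\n")
        for e, lab in zip(geometry.elements, geometry.layer_labels):
            fh.write(f"{e[0]} {e[1]} {e[2]} {e[3]} {int(lab)}\n")
        fh.write(f"boundary_facets {len(geometry.boundary_facets)}\n")
        for f, t in zip(geometry.boundary_facets, geometry.boundary_tags):
            fh.write(f"{f[0]} {f[1]} {f[2]} {int(t)}\n")
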