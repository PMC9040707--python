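"""Parameterized synthetic larynx geometry.

Generates an idealized bilateral vocal fold embedded in a straight
rectangular airway duct, standing in for an MRI-reconstructed larynx.  The
generated fold reproduces the anatomical features that drive the
fluid-structure interaction: a long, gently converging inferior surface, a
narrow glottal gap with a short diverging superior surface, a thin compliant
cover layer over a stiffer body, an oblique (inclined) fold orientation, and
a rigid downstream ventricle / false-vocal-fold / supraglottal expansion.

The medial surface half-gap is, per fold and before mirroring,

    g(x, y) = clip( g0(s) * (1 + taper * xi^2), ., w_att ),
    s  = clip(x - (y - y_c) tan(theta), 0, L_fold),
    xi = 2 (y - y_c) / duct_depth,

where ``g0`` is the convergent-divergent axial profile, ``theta`` the
inclination of the fold plane from the transverse axis, and ``taper``
opens the gap toward the anterior/posterior ends (the posterior gap of a
real larynx never closes completely).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import MeshGenerationError, VfsimError
from .mesh import (
    LarynxGeometry, extract_boundary, tet_volumes,
    LAYER_BODY, LAYER_COVER, TAG_FIXED, TAG_LUMEN,
)

# fraction of the duct half-width at which the fold attaches to the wall
_ATTACH_FRAC = 0.9
# divergence angle of the short superior surface (degrees from duct axis)
_SUPERIOR_ANGLE = 55.0
# fraction of fold_thickness taken by the flat glottal tip
_TIP_FRAC = 0.3

# 6-tet decomposition of a hexahedron, all sharing the 0-6 diagonal
_HEX_TO_TETS = (
    (0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
    (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6),
)


@dataclass
class GeometryParams:
    """Synthetic larynx parameters (SI units; angles in degrees).

    Defaults approximate a rabbit larynx: a duct a few millimetres wide
    with a sub-millimetre rest glottal gap.
    """

    duct_length_sub: float = 8.0e-3
    duct_length_sup: float = 8.0e-3
    duct_width: float = 8.0e-3        # lateral (z) extent
    duct_depth: float = 6.0e-3        # anterior-posterior (y) extent
    fold_thickness: float = 2.6e-3    # axial extent of tip + superior surface
    inferior_slope_angle: float = 30.0
    glottal_half_gap: float = 0.12e-3  # adducted rest gap
    cover_thickness: float = 1.4e-3
    inclination_theta: float = 30.0
    false_fold_gap: float = 0.8e-3    # half-gap at the false vocal fold
    ventricle_length: float = 1.5e-3
    longitudinal_taper: float = 0.3
    mesh_resolution: float = 0.5e-3
    seed: int = 0
    perturbation: float = 0.0         # optional surface noise, fraction of half gap

    def validate(self) -> None:
        lengths = dict(
            duct_length_sub=self.duct_length_sub,
            duct_length_sup=self.duct_length_sup,
            duct_width=self.duct_width, duct_depth=self.duct_depth,
            fold_thickness=self.fold_thickness,
            glottal_half_gap=self.glottal_half_gap,
            cover_thickness=self.cover_thickness,
            false_fold_gap=self.false_fold_gap,
            ventricle_length=self.ventricle_length,
            mesh_resolution=self.mesh_resolution,
        )
        for name, val in lengths.items():
            if not val > 0:
                raise MeshGenerationError(f"{name} must be positive, got {val}")
        if not (self.glottal_half_gap < self.false_fold_gap
                < self.duct_width / 2):
            raise MeshGenerationError(
                "requires glottal_half_gap < false_fold_gap < duct_width/2"
            )
        if not 0.0 <= self.inclination_theta <= 60.0:
            raise MeshGenerationError(
                f"inclination_theta must be in [0, 60] degrees, "
                f"got {self.inclination_theta}"
            )
        if not 0.0 < self.inferior_slope_angle < 80.0:
            raise MeshGenerationError("inferior_slope_angle out of (0, 80)")
        if not 0.0 <= self.longitudinal_taper <= 1.0:
            raise MeshGenerationError("longitudinal_taper out of [0, 1]")
        depth = _ATTACH_FRAC * self.duct_width / 2 - self.glottal_half_gap
        if not self.cover_thickness < depth:
            raise MeshGenerationError(
                f"cover_thickness {self.cover_thickness} must be smaller than "
                f"the fold lateral depth {depth:.3e}"
            )

    # derived axial measures -------------------------------------------------
    @property
    def attach_half_gap(self) -> float:
        return _ATTACH_FRAC * self.duct_width / 2

    @property
    def inferior_length(self) -> float:
        slope = np.tan(np.radians(self.inferior_slope_angle))
        return (self.attach_half_gap - self.glottal_half_gap) / slope

    @property
    def fold_profile_length(self) -> float:
        return self.inferior_length + self.fold_thickness


@dataclass(frozen=True)
class SamplePreset:
    """Per-sample driving pressure, layer moduli and fold inclination."""

    sample_id: int
    inlet_pressure: float   # Pa
    E_body: float           # Pa
    E_cover: float          # Pa
    theta: float            # degrees


# inlet pressure (Pa), body/cover Young's moduli (Pa), inclination (deg)
_PRESETS = {
    1: SamplePreset(1, 1050.0, 60e3, 12e3, 41.0),
    2: SamplePreset(2, 780.0, 80e3, 8e3, 24.0),
    3: SamplePreset(3, 720.0, 80e3, 8e3, 43.0),
    4: SamplePreset(4, 1000.0, 90e3, 9e3, 20.0),
    5: SamplePreset(5, 980.0, 90e3, 9e3, 29.0),
}


def sample_preset(sample_id: int) -> SamplePreset:
    """Tabulated conditions for one of the five rabbit larynx samples."""
    try:
        return _PRESETS[int(sample_id)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(
            f"unknown sample id {sample_id!r}; valid ids are 1..5"
        ) from None


# ---------------------------------------------------------------------------
# half-gap field
# ---------------------------------------------------------------------------

def _axial_profile(params: GeometryParams, s: np.ndarray) -> np.ndarray:
    """Convergent-divergent rest half-gap g0(s) along the fold, s in [0, Lf]."""
    g_min = params.glottal_half_gap
    w_att = params.attach_half_gap
    L_inf = params.inferior_length
    t_tip = _TIP_FRAC * params.fold_thickness
    slope_inf = np.tan(np.radians(params.inferior_slope_angle))
    slope_sup = np.tan(np.radians(_SUPERIOR_ANGLE))

    s = np.asarray(s, dtype=float)
    g = np.where(
        s <= L_inf,
        g_min + (L_inf - s) * slope_inf,
        np.where(
            s <= L_inf + t_tip,
            g_min,
            g_min + (s - L_inf - t_tip) * slope_sup,
        ),
    )
    return np.minimum(g, w_att)


def half_gap_field(params: GeometryParams, x, y) -> np.ndarray:
    """Rest medial-surface half-gap g(x, y) of one fold (before mirroring).

    ``x`` is axial position within the fold extent, ``y`` anterior-posterior
    position in [0, duct_depth].  Used both by the mesher and, at fine
    quadrature, as the analytic reference for the solid volume.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    yc = params.duct_depth / 2
    shift = (y - yc) * np.tan(np.radians(params.inclination_theta))
    s = np.clip(x - shift, 0.0, params.fold_profile_length)
    xi = 2.0 * (y - yc) / params.duct_depth
    g = _axial_profile(params, s) * (1.0 + params.longitudinal_taper * xi ** 2)
    return np.minimum(g, params.attach_half_gap)


def fold_x_extent(params: GeometryParams) -> tuple:
    """Axial extent of the solid mesh, widened to hold the inclined fold."""
    delta = (params.duct_depth / 2) * np.tan(
        np.radians(params.inclination_theta))
    return (-delta, params.fold_profile_length + delta)


def station_shift(params_dict: dict, y) -> np.ndarray:
    """Axial offset of the inclined fold plane at anterior-posterior y.

    Cross-sections inside the fold are taken on planes following the fold
    inclination (the stand-in for streamline-normal planes), so a station
    at arc-length s cuts each y-row at x = s + station_shift(y).
    """
    yc = params_dict["duct_depth"] / 2
    return (np.asarray(y, dtype=float) - yc) * np.tan(
        np.radians(params_dict["inclination_theta"]))


def solid_volume_quadrature(params: GeometryParams, n: int = 400) -> float:
    """Analytic (fine-quadrature) volume of the bilateral fold solid."""
    x_lo, x_hi = fold_x_extent(params)
    x = np.linspace(x_lo, x_hi, n)
    y = np.linspace(0.0, params.duct_depth, n)
    X, Y = np.meshgrid(x, y, indexing="ij")
    thickness = params.duct_width / 2 - half_gap_field(params, X, Y)
    return 2.0 * float(np.trapezoid(
        np.trapezoid(thickness, y, axis=1), x))


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

def build_geometry(params: GeometryParams | None = None,
                   **overrides) -> LarynxGeometry:
    """Generate the tagged tetrahedral solid mesh plus lumen description.

    Deterministic for fixed parameters and seed.  Raises
    :class:`MeshGenerationError` naming the violated constraint for
    degenerate parameter combinations.
    """
    if params is None:
        params = GeometryParams(**overrides)
    elif overrides:
        params = GeometryParams(**{**asdict(params), **overrides})
    params.validate()

    x_lo, x_hi = fold_x_extent(params)
    res = params.mesh_resolution
    nx = max(8, int(np.ceil((x_hi - x_lo) / res)))
    ny = max(6, int(np.ceil(params.duct_depth / res)))
    depth_max = params.duct_width / 2 - params.glottal_half_gap
    nk = max(3, int(np.ceil(depth_max / (1.5 * res))))

    nk = max(4, nk)
    xg = np.linspace(x_lo, x_hi, nx + 1)
    yg = np.linspace(0.0, params.duct_depth, ny + 1)
    X, Y = np.meshgrid(xg, yg, indexing="ij")
    g = half_gap_field(params, X, Y)                      # (nx+1, ny+1)

    if params.perturbation > 0.0:
        rng = np.random.default_rng(params.seed)
        bump = params.perturbation * params.glottal_half_gap
        noise = [rng.standard_normal(g.shape) * bump for _ in range(2)]
    else:
        noise = [np.zeros_like(g)] * 2

    w_half = params.duct_width / 2
    # lateral grading concentrates element layers at the medial surface so
    # the thin compliant cover stays resolved even at coarse resolution
    t = ((np.arange(nk + 1) / nk) ** 1.6)[None, None, :]

    node_blocks, grids = [], []
    offset = 0
    for side, dn in zip((+1.0, -1.0), noise):
        g_s = np.clip(g + dn, 0.2 * params.glottal_half_gap,
                      params.attach_half_gap)
        z = g_s[:, :, None] + (w_half - g_s)[:, :, None] * t   # (nx+1,ny+1,nk+1)
        pts = np.empty((nx + 1, ny + 1, nk + 1, 3))
        pts[..., 0] = X[:, :, None]
        pts[..., 1] = Y[:, :, None]
        pts[..., 2] = side * z
        ids = offset + np.arange(pts[..., 0].size).reshape(pts.shape[:3])
        node_blocks.append(pts.reshape(-1, 3))
        grids.append(ids)
        offset = ids.max() + 1
    nodes = np.concatenate(node_blocks, axis=0)

    elements, layers = [], []
    for f, ids in enumerate(grids):
        hexes = np.stack([
            ids[:-1, :-1, :-1], ids[1:, :-1, :-1],
            ids[1:, 1:, :-1], ids[:-1, 1:, :-1],
            ids[:-1, :-1, 1:], ids[1:, :-1, 1:],
            ids[1:, 1:, 1:], ids[:-1, 1:, 1:],
        ], axis=-1).reshape(-1, 8)
        for pat in _HEX_TO_TETS:
            tet = hexes[:, pat]
            if f == 1:   # mirrored fold: restore positive orientation
                tet = tet[:, [0, 2, 1, 3]]
            elements.append(tet)
    elements = np.concatenate(elements, axis=0)

    vols = tet_volumes(nodes, elements)
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        raise MeshGenerationError(
            f"degenerate parameter combination: element {bad} has "
            f"non-positive volume {vols[bad]:.3e} m^3 (medial surface too "
            f"steep for mesh_resolution)"
        )

    # layer labels from centroid distance to the medial surface
    cent = nodes[elements].mean(axis=1)
    g_cent = half_gap_field(params, cent[:, 0], cent[:, 1])
    dist = np.abs(cent[:, 2]) - g_cent
    layer_labels = np.where(dist < params.cover_thickness,
                            LAYER_COVER, LAYER_BODY).astype(np.int32)

    # boundary facets; lumen = facets whose 3 nodes lie on a medial grid
    facets, _ = extract_boundary(elements)
    medial_ids = np.concatenate([grd[:, :, 0].ravel() for grd in grids])
    on_medial = np.zeros(nodes.shape[0], dtype=bool)
    on_medial[medial_ids] = True
    tags = np.where(on_medial[facets].all(axis=1),
                    TAG_LUMEN, TAG_FIXED).astype(np.int32)

    lumen_axis, rigid_half = _build_lumen_axis(params)

    # marker: medial node of the +z fold nearest the glottal tip at mid-span
    x_marker = params.inferior_length + 0.5 * _TIP_FRAC * params.fold_thickness
    grid0 = grids[0][:, :, 0]
    i_m = int(np.argmin(np.abs(xg - x_marker)))
    j_m = ny // 2
    marker_node = int(grid0[i_m, j_m])

    geom = LarynxGeometry(
        nodes=nodes, elements=elements, layer_labels=layer_labels,
        boundary_facets=facets, boundary_tags=tags,
        lumen_axis=lumen_axis,
        medial_grids=(grids[0][:, :, 0], grids[1][:, :, 0]),
        rigid_half_gap=rigid_half, span=params.duct_depth,
        fold_x_range=(0.0, params.fold_profile_length),
        rest_min_area=0.0, marker_node=marker_node,
        params=asdict(params),
    )
    prof = extract_lumen_profile(geom, area_floor=0.0)
    geom.rest_min_area = float(prof.area.min())
    return geom


def _build_lumen_axis(params: GeometryParams):
    """Arc-length stations and rigid-wall half-gap from inlet to outlet.

    The arc-length coordinate equals the mid-span axial position; inside
    the fold extent [0, L_fold] the stations correspond to inclined
    cutting planes (see :func:`station_shift`).
    """
    w_att = params.attach_half_gap
    lf = params.fold_profile_length
    # anterior-posterior mean of the taper factor: <1 + taper xi^2> = 1 + taper/3
    taper_mean = 1.0 + params.longitudinal_taper / 3.0

    # subglottal duct
    xs = [np.linspace(-params.duct_length_sub, 0.0, 12, endpoint=False)]
    hs = [np.full(12, w_att)]
    # fold region at twice the mesh axial density
    n_fold = 2 * max(8, int(np.ceil(lf / params.mesh_resolution)))
    x_fold = np.linspace(0.0, lf, n_fold + 1)
    xs.append(x_fold)
    hs.append(np.minimum(_axial_profile(params, x_fold) * taper_mean, w_att))
    # ventricle expansion -> false fold -> supraglottal duct (rigid)
    w_vent = 0.35 * params.duct_width
    g_end = hs[-1][-1]
    ff_ramp, ff_plateau, ff_out = 0.8e-3, 0.4e-3, 1.2e-3
    x0 = lf
    seg = [
        (params.ventricle_length, g_end, w_vent, 6),
        (ff_ramp, w_vent, params.false_fold_gap, 6),
        (ff_plateau, params.false_fold_gap, params.false_fold_gap, 3),
        (ff_out, params.false_fold_gap, w_att, 6),
        (params.duct_length_sup, w_att, w_att, 8),
    ]
    for length, h0, h1, n in seg:
        xe = np.linspace(x0, x0 + length, n + 1)[1:]
        xs.append(xe)
        hs.append(np.linspace(h0, h1, n + 1)[1:])
        x0 += length
    return np.concatenate(xs), np.concatenate(hs)


# ---------------------------------------------------------------------------
# lumen profile extraction
# ---------------------------------------------------------------------------

@dataclass
class LumenProfile:
    """Axial stations of the (possibly deformed) lumen.

    ``area`` is the geometric cross-sectional area after the floor;
    ``half_gap`` = area / (2 span) is the slot-equivalent half opening used
    for the loss model's shape descriptors.
    """

    x: np.ndarray            # arc length stations (m), strictly increasing
    area: np.ndarray         # m^2
    area_dot: np.ndarray     # dA/dt (m^2/s)
    half_gap: np.ndarray     # m
    hydraulic_diameter: np.ndarray  # m
    dhdx: np.ndarray         # local convergence(-)/divergence(+) slope
    span: float              # anterior-posterior width (m)
    glottis_x: float         # rest minimum-area station
    fold_x_range: tuple = (0.0, 0.0)

    @property
    def aspect_ratio(self) -> np.ndarray:
        """Gap aspect ratio span/(2 half_gap) per station."""
        return self.span / (2.0 * self.half_gap)

    @property
    def i_min(self) -> int:
        return int(np.argmin(self.area))

    def classify(self, x: float) -> str:
        """Segment of a station: inferior / glottal_gap / supraglottal."""
        lo, hi = self.fold_x_range
        tip_lo = self.glottis_x - 0.4e-3
        if x < tip_lo:
            return "inferior"
        if x <= hi:
            return "glottal_gap"
        return "supraglottal"


def extract_lumen_profile(geometry: LarynxGeometry,
                          displacements: np.ndarray | None = None,
                          velocities: np.ndarray | None = None,
                          area_floor: float | None = None,
                          station_refine: int = 1) -> LumenProfile:
    """Slice the (deformed) lumen into cross-sectional areas A(x).

    Within the fold axial extent the moving medial surfaces are sliced with
    planes normal to the straight centerline; rigid duct segments are
    evaluated from the stored wall profile.  ``area_floor`` (m^2; default
    1% of the rest glottal area) represents incomplete glottal closure.

    Raises :class:`VfsimError` for a self-intersecting deformed surface.
    """
    if area_floor is None:
        area_floor = 0.01 * geometry.rest_min_area
    x = np.asarray(geometry.lumen_axis, dtype=float)
    for _ in range(station_refine - 1):
        x = np.sort(np.concatenate([x, 0.5 * (x[1:] + x[:-1])]))
    span = geometry.span
    area = 2.0 * np.interp(x, geometry.lumen_axis,
                           geometry.rigid_half_gap) * span
    area_dot = np.zeros_like(area)

    u = displacements
    if u is None:
        u = np.zeros_like(geometry.nodes)
    v = velocities

    x_lo, x_hi = geometry.fold_x_range
    in_fold = (x >= x_lo) & (x <= x_hi)
    st = x[in_fold]
    if st.size:
        ny1 = geometry.medial_grids[0].shape[1]
        yg = np.linspace(0.0, span, ny1)
        shift = station_shift(geometry.params, yg)
        z_sides, vz_sides = [], []
        for f, grid in enumerate(geometry.medial_grids):
            zrows = np.empty((ny1, st.size))
            vrows = np.zeros((ny1, st.size))
            for j in range(ny1):
                ids = grid[:, j]
                xr = geometry.nodes[ids, 0] + u[ids, 0]
                zr = geometry.nodes[ids, 2] + u[ids, 2]
                if np.any(np.diff(xr) <= 0):
                    raise VfsimError(
                        "deformed lumen surface is self-intersecting "
                        f"(non-monotone axial coordinate, fold {f}, row {j})"
                    )
                # inclined cutting plane: row j is cut at x = s + shift(y_j)
                zrows[j] = np.interp(st + shift[j], xr, zr)
                if v is not None:
                    vrows[j] = np.interp(st + shift[j], xr, v[ids, 2])
            z_sides.append(zrows)
            vz_sides.append(vrows)
        gap_rows = z_sides[0] - z_sides[1]            # (ny1, nst)
        if np.min(gap_rows) < -0.25 * span:
            raise VfsimError("deformed lumen surface is self-intersecting "
                             "(folds interpenetrate beyond tolerance)")
        gap_min = max(area_floor / span, 0.0)
        open_mask = gap_rows > gap_min
        gap_cl = np.maximum(gap_rows, gap_min)
        area[in_fold] = np.trapezoid(gap_cl, yg, axis=0)
        if v is not None:
            dg = (vz_sides[0] - vz_sides[1]) * open_mask
            area_dot[in_fold] = np.trapezoid(dg, yg, axis=0)

    area = np.maximum(area, max(area_floor, 1e-16))
    half_gap = area / (2.0 * span)
    perimeter = 2.0 * (span + area / span)
    if np.any(perimeter <= 0):
        raise VfsimError("station with zero wetted perimeter")
    d_h = 4.0 * area / perimeter
    dhdx = np.gradient(half_gap, x)
    i_rest = int(np.argmin(np.interp(
        x, geometry.lumen_axis, geometry.rigid_half_gap)))
    glottis_x = float(x[i_rest])
    return LumenProfile(
        x=x, area=area, area_dot=area_dot, half_gap=half_gap,
        hydraulic_diameter=d_h, dhdx=dhdx, span=span,
        glottis_x=glottis_x, fold_x_range=(x_lo, x_hi),
    )
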