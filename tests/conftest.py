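import numpy as np
import pytest

import vfsim as vf
import vfsim.mesh as vm


def make_block_geometry(nx=3, ny=3, nz=3, L=(1e-2, 1e-2, 1e-2),
                        clamp="x0", lumen="rest"):
    """Structured tet block wrapped as a LarynxGeometry for FEM tests.

    ``clamp`` selects which boundary facets are fixed ("x0" face, "none",
    or "all"); the remaining facets are tagged as the loaded (lumen)
    surface.
    """
    xs = [np.linspace(0, L[i], n + 1) for i, n in enumerate((nx, ny, nz))]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    ids = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    hexes = np.stack([
        ids[:-1, :-1, :-1], ids[1:, :-1, :-1], ids[1:, 1:, :-1],
        ids[:-1, 1:, :-1], ids[:-1, :-1, 1:], ids[1:, :-1, 1:],
        ids[1:, 1:, 1:], ids[:-1, 1:, 1:]], axis=-1).reshape(-1, 8)
    pats = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
            (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))
    elems = np.concatenate([hexes[:, p] for p in pats], axis=0)
    facets, _ = vm.extract_boundary(elems)
    cx = nodes[facets].mean(axis=1)[:, 0]
    if clamp == "x0":
        tags = np.where(np.isclose(cx, 0.0), vm.TAG_FIXED, vm.TAG_LUMEN)
    elif clamp == "all":
        tags = np.full(len(facets), vm.TAG_FIXED)
    else:
        tags = np.full(len(facets), vm.TAG_LUMEN)
    return vm.LarynxGeometry(
        nodes=nodes, elements=elems,
        layer_labels=np.zeros(len(elems), dtype=np.int32),
        boundary_facets=facets, boundary_tags=tags.astype(np.int32),
        lumen_axis=np.array([0.0, L[0]]),
        medial_grids=(np.zeros((1, 1), dtype=int),
                      np.zeros((1, 1), dtype=int)),
        rigid_half_gap=np.array([L[2] / 2, L[2] / 2]), span=L[1],
        fold_x_range=(0.0, L[0]), rest_min_area=L[1] * L[2],
        marker_node=0)


@pytest.fixture(scope="session")
def block_fem():
    geom = make_block_geometry()
    return vf.FoldDynamics(geom, vf.MaterialParams(E_body=10e3, E_cover=10e3,
                                                   rayleigh_beta=0.0))


@pytest.fixture(scope="session")
def coarse_params():
    """Coarse synthetic larynx for fast coupled tests."""
    return vf.GeometryParams(mesh_resolution=1.2e-3, inclination_theta=20.0)


@pytest.fixture(scope="session")
def coarse_geometry(coarse_params):
    return vf.build_geometry(coarse_params)


def uniform_profile(n=50, area=1e-5, length=1e-2, span=6e-3):
    """Rigid constant-area duct profile for flow tests."""
    x = np.linspace(0.0, length, n)
    return profile_from_area(x, np.full(n, area), span)


def profile_from_area(x, area, span=6e-3):
    area = np.asarray(area, dtype=float)
    h = area / (2 * span)
    per = 2 * (span + area / span)
    return vf.LumenProfile(
        x=np.asarray(x, float), area=area, area_dot=np.zeros_like(area),
        half_gap=h, hydraulic_diameter=4 * area / per,
        dhdx=np.gradient(h, x), span=span,
        glottis_x=float(x[np.argmin(area)]),
        fold_x_range=(float(x[0]), float(x[-1])))


def run_to_steady(profile, P_in, loss, dt=1e-6, n_steps=4000, **kw):
    state = vf.init_flow_state(profile, P_in=P_in, **kw)
    for _ in range(n_steps):
        state = vf.step_flow(state, profile, loss, dt)
    return state
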