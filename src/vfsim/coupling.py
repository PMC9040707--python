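"""Partitioned strong coupling of the 1D glottal flow and the tissue FEM.

Within every time step the two single-physics solvers are sub-iterated to a
fixed point of the interface (lumen-surface) displacement: flow solve on
the current lumen profile -> pressure mapped to surface tractions -> solid
solve -> updated lumen profile, with Aitken dynamic under-relaxation.  The
driving subglottal pressure is constant (optionally ramped from zero over a
short startup window); vocal-fold vibration and the pulsatile flow are
established by the coupled dynamics alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConvergenceError, VfsimError
from .flow import (FlowState, LossModel, default_loss_model, init_flow_state,
                   step_flow, RHO_AIR, MU_EFF_DEFAULT)
from .geometry import LumenProfile, extract_lumen_profile
from .mesh import LarynxGeometry
from .solid import FoldDynamics, MaterialParams, SolidState

log = logging.getLogger(__name__)


@dataclass
class CouplingConfig:
    """Time stepping and interface-iteration settings.

    The default time step of 1e-6 s (1e-4 centiseconds) resolves one
    vibration cycle with thousands of steps; desk-scale runs typically use
    a larger step with the implicit structural integrator.
    """

    dt: float = 1e-6                 # s
    t_end: float = 2e-2              # s
    max_subiter: int = 50
    interface_tol: float = 1e-6      # relative interface-displacement change
    interface_abs_tol: float = 1e-12  # m; accepts machine-level stagnation
    relaxation: str = "aitken"       # "aitken" | "fixed"
    omega: float = 1.0               # initial / fixed relaxation factor
    ramp_time: float = 1e-4          # s, inlet-pressure ramp from rest
    output_stride: int = 10          # record every this many steps
    newton_tol: float = 1e-9
    newton_max_iter: int = 30
    cfl_max: float = 5.0
    area_floor_frac: float = 0.01    # of the rest glottal area
    station_refine: int = 1
    snapshot_times: tuple = ()

    def validate(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise VfsimError("dt and t_end must be positive")
        if not 0.0 < self.omega <= 1.0:
            raise VfsimError("relaxation omega must be in (0, 1]")
        if self.interface_tol <= 0:
            raise VfsimError("interface_tol must be positive")
        if self.relaxation not in ("aitken", "fixed"):
            raise VfsimError(f"unknown relaxation scheme {self.relaxation!r}")


@dataclass
class SimulationRecord:
    """Recorded time series and snapshots of one coupled run."""

    time: np.ndarray
    marker_disp: np.ndarray       # lateral marker displacement (m)
    min_area: np.ndarray          # minimum glottal area (m^2)
    flux: np.ndarray              # inlet volume flux (m^3/s)
    work_rate: np.ndarray         # fluid-to-tissue power (W)
    work_acc: np.ndarray          # accumulated work (J), trapezoidal
    kinetic: np.ndarray           # tissue kinetic energy (J)
    strain: np.ndarray            # tissue strain energy (J)
    damping_acc: np.ndarray       # accumulated Rayleigh dissipation (J)
    subiters: np.ndarray          # sub-iterations per recorded step
    snapshots: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def series_dict(self) -> dict:
        return {
            "time": self.time, "marker_disp": self.marker_disp,
            "min_area": self.min_area, "flux": self.flux,
            "work_rate": self.work_rate, "work_acc": self.work_acc,
            "kinetic": self.kinetic, "strain": self.strain,
            "damping_acc": self.damping_acc, "subiters": self.subiters,
        }


def map_pressure_to_surface(profile: LumenProfile, flow: FlowState,
                            fem: FoldDynamics,
                            displacements: np.ndarray | None = None
                            ) -> np.ndarray:
    """Interpolate station pressures to lumen facet centroids (arc length).

    Facets outside the station range are clamped to the boundary stations.
    """
    from .geometry import station_shift
    centroids, _ = fem.lumen_facet_geometry(displacements)
    # station (arc-length) coordinate of each facet under the inclined planes
    cx = centroids[:, 0] - station_shift(fem.geometry.params, centroids[:, 1])
    n_out = np.count_nonzero((cx < flow.x[0]) | (cx > flow.x[-1]))
    if n_out:
        log.warning("%d lumen facets outside the station range; "
                    "clamped to boundary stations", n_out)
    return np.interp(cx, flow.x, flow.p)


def _interface_values(geometry: LarynxGeometry, u: np.ndarray) -> np.ndarray:
    ids = np.concatenate([g.ravel() for g in geometry.medial_grids])
    return u[ids].ravel()


def advance_timestep(fem: FoldDynamics, solid: SolidState, flow: FlowState,
                     config: CouplingConfig,
                     loss: LossModel | None = None,
                     area_prev: np.ndarray | None = None):
    """One strongly coupled step; returns (solid, flow, profile, p_facets, diag).

    The interface fixed-point residual is the relative change of the
    lumen-surface displacement between sub-iterations.  Exceeding
    ``max_subiter`` raises :class:`ConvergenceError` with the residual
    trace — the signature of an added-mass-type instability; the remedy is
    a smaller dt or stronger under-relaxation.
    """
    if loss is None:
        loss = default_loss_model()
    geometry = fem.geometry
    dt = config.dt
    floor = config.area_floor_frac * geometry.rest_min_area
    if area_prev is None:
        area_prev = extract_lumen_profile(
            geometry, solid.displacement, area_floor=floor,
            station_refine=config.station_refine).area

    # predictor: free-flight extrapolation of the current velocity
    u_guess = solid.displacement + dt * solid.velocity
    omega = config.omega
    r_prev = None
    residuals = []
    i_sep_pin = None      # separation station fixed after the 1st sub-iter
    for k in range(config.max_subiter):
        profile = extract_lumen_profile(
            geometry, u_guess, area_floor=floor,
            station_refine=config.station_refine)
        profile.area_dot = (profile.area - area_prev) / dt
        flow_k = step_flow(flow, profile, loss, dt, cfl_max=config.cfl_max,
                           i_sep_pin=i_sep_pin)
        i_sep_pin = flow_k.i_sep
        p_facets = map_pressure_to_surface(profile, flow_k, fem, u_guess)
        solid_k = fem.newmark_step(
            solid, lambda u: fem.apply_traction(p_facets, u), dt,
            tol=config.newton_tol, max_iter=config.newton_max_iter)
        r_full = solid_k.displacement - u_guess
        r = _interface_values(geometry, r_full)
        d_new = _interface_values(geometry, solid_k.displacement)
        rel = np.linalg.norm(r) / max(np.linalg.norm(d_new), 1e-30)
        residuals.append(rel)
        if rel < config.interface_tol \
                or np.max(np.abs(r)) < config.interface_abs_tol:
            diag = {"subiters": k + 1, "residuals": residuals}
            return solid_k, flow_k, profile, p_facets, diag
        if config.relaxation == "aitken" and r_prev is not None:
            dr = r - r_prev
            denom = float(dr @ dr)
            if denom > 0:
                omega = -omega * float(r_prev @ dr) / denom
            omega = float(np.clip(omega, 0.05, 1.0))
        # stagnation fallback: if the fixed point orbits instead of
        # contracting, force stronger under-relaxation
        if k >= 6 and len(residuals) >= 4 \
                and residuals[-1] > 0.9 * min(residuals[:-3]):
            omega = max(0.2 * omega, 0.01)
        u_guess = u_guess + omega * r_full
        r_prev = r
    raise ConvergenceError(
        f"interface iteration exceeded max_subiter={config.max_subiter} "
        "(added-mass-type instability; reduce dt or relaxation omega)",
        residual_history=residuals)


def _ramp(P_in: float, t: float, ramp_time: float) -> float:
    if ramp_time <= 0 or t >= ramp_time:
        return P_in
    return P_in * 0.5 * (1.0 - np.cos(np.pi * t / ramp_time))


def run_simulation(geometry: LarynxGeometry, material: MaterialParams,
                   config: CouplingConfig, P_in: float, P_out: float = 0.0,
                   rho: float = RHO_AIR, mu_eff: float = MU_EFF_DEFAULT,
                   loss: LossModel | None = None,
                   checkpoint_path=None, checkpoint_stride: int = 0,
                   restart_state: dict | None = None) -> SimulationRecord:
    """Time-march the coupled system from rest under constant inlet pressure.

    Deterministic for fixed inputs.  ``restart_state`` (as produced by
    :func:`vfsim.records.read_checkpoint`) resumes a run bitwise at a
    checkpoint boundary.
    """
    config.validate()
    material.validate()
    if loss is None:
        loss = default_loss_model()
    fem = FoldDynamics(geometry, material)
    floor = config.area_floor_frac * geometry.rest_min_area

    n_steps = int(round(config.t_end / config.dt))
    if restart_state is None:
        solid = SolidState.rest(geometry.n_nodes)
        profile0 = extract_lumen_profile(
            geometry, area_floor=floor, station_refine=config.station_refine)
        flow = init_flow_state(profile0, P_in=0.0, P_out=P_out,
                               rho=rho, mu_eff=mu_eff)
        step0 = 0
        series = {k: [] for k in ("time", "marker_disp", "min_area", "flux",
                                  "work_rate", "work_acc", "kinetic",
                                  "strain", "damping_acc", "subiters")}
        work_acc = 0.0
        damp_acc = 0.0
        prev_power = 0.0
        prev_dpow = 0.0
        snapshots = []
    else:
        solid = restart_state["solid"]
        flow = restart_state["flow"]
        step0 = int(restart_state["step"])
        series = {k: list(v) for k, v in restart_state["series"].items()}
        work_acc = float(restart_state["work_acc"])
        damp_acc = float(restart_state["damping_acc"])
        prev_power = float(restart_state["prev_power"])
        prev_dpow = float(restart_state["prev_dpow"])
        snapshots = list(restart_state.get("snapshots", []))

    area_prev = extract_lumen_profile(
        geometry, solid.displacement, area_floor=floor,
        station_refine=config.station_refine).area
    snap_times = [t for t in sorted(config.snapshot_times)
                  if t > (step0 + 0.5) * config.dt]

    for step in range(step0, n_steps):
        t_new = (step + 1) * config.dt
        flow.P_in = _ramp(P_in, t_new, config.ramp_time)
        try:
            solid, flow, profile, p_facets, diag = advance_timestep(
                fem, solid, flow, config, loss, area_prev)
        except VfsimError as exc:
            exc.add_note(f"while advancing step {step} (t={t_new:.6e} s)")
            raise
        area_prev = profile.area
        solid.time = t_new
        flow.time = t_new

        # fluid-to-tissue power on the deformed surface
        _, an = fem.lumen_facet_geometry(solid.displacement)
        v_f = solid.velocity[fem.geometry.lumen_facets].mean(axis=1)
        power = float(np.einsum("fi,fi->", -p_facets[:, None] * an, v_f))
        dpow = float(np.sum(solid.velocity
                            * fem.damping_force(solid.displacement,
                                                solid.velocity)))
        work_acc += 0.5 * (prev_power + power) * config.dt
        damp_acc += 0.5 * (prev_dpow + dpow) * config.dt
        prev_power, prev_dpow = power, dpow

        if (step + 1) % config.output_stride == 0 or step + 1 == n_steps:
            series["time"].append(t_new)
            series["marker_disp"].append(
                solid.displacement[geometry.marker_node, 2])
            lo, hi = geometry.fold_x_range
            in_fold = (profile.x >= lo) & (profile.x <= hi)
            series["min_area"].append(float(profile.area[in_fold].min()))
            series["flux"].append(flow.Q)
            series["work_rate"].append(power)
            series["work_acc"].append(work_acc)
            series["kinetic"].append(fem.kinetic_energy(solid.velocity))
            series["strain"].append(fem.strain_energy(solid.displacement))
            series["damping_acc"].append(damp_acc)
            series["subiters"].append(diag["subiters"])

        while snap_times and t_new >= snap_times[0] - 0.5 * config.dt:
            snap_times.pop(0)
            snapshots.append({
                "time": t_new, "x": flow.x.copy(), "area": flow.area.copy(),
                "u": flow.u.copy(), "p": flow.p.copy(),
                "tau": flow.tau.copy(), "p_total": flow.p_total.copy(),
            })

        if checkpoint_path and checkpoint_stride \
                and (step + 1) % checkpoint_stride == 0:
            from .records import write_checkpoint
            write_checkpoint(checkpoint_path, solid, flow, step + 1, series,
                             work_acc, damp_acc, prev_power, prev_dpow,
                             snapshots)

    meta = {"P_in": P_in, "P_out": P_out, "rho": rho, "mu_eff": mu_eff,
            "marker_node": int(geometry.marker_node),
            "config": asdict(config), "n_nodes": geometry.n_nodes,
            "n_elements": geometry.n_elements}
    return SimulationRecord(
        time=np.array(series["time"]),
        marker_disp=np.array(series["marker_disp"]),
        min_area=np.array(series["min_area"]),
        flux=np.array(series["flux"]),
        work_rate=np.array(series["work_rate"]),
        work_acc=np.array(series["work_acc"]),
        kinetic=np.array(series["kinetic"]),
        strain=np.array(series["strain"]),
        damping_acc=np.array(series["damping_acc"]),
        subiters=np.array(series["subiters"]),
        snapshots=snapshots, meta=meta)
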