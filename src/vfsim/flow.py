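"""Quasi-1D unsteady glottal flow on the moving lumen.

Solves the area-averaged continuity and momentum equations

    dA/dt + d(A u)/dx = 0,
    rho du/dt + rho u du/dx = -dp/dx + dtau/dx,

on fixed axial stations with prescribed A(x, t) and dA/dt(x, t) from the
deforming lumen.  The flow is incompressible, so continuity fixes the flux
profile Q(x) = Q_in - int dA/dt dx' up to the single unknown inlet flux;
the momentum balance integrated from the inlet (p = P_in) to the jet
separation station (p = P_out) closes the problem as one scalar implicit
equation per time step.  Downstream of separation the jet is detached: the
pressure is pinned at the outlet value and the jet cross-section is frozen
at the separation-station area (no pressure recovery).

``tau`` is the accumulated pressure loss.  Its closed form is supplied by a
pluggable :class:`LossModel`; the default combines a plane-Poiseuille
viscous loss for a rectangular slot with the divergence-angle separation
rule above.  Machine-learned non-dimensional loss/entrance functions can be
dropped in through the same interface.

Air properties follow the convention of the reference conditions:
rho = 1.0 kg/m^3 and an effective viscosity of four times that of air
(mu_eff = 7.2e-5 Pa s) to lower the Reynolds number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import CFLError, VfsimError
from .geometry import LumenProfile

RHO_AIR = 1.0                 # kg/m^3
MU_AIR = 1.8e-5               # Pa s
MU_EFF_DEFAULT = 4.0 * MU_AIR
# plane Poiseuille between plates a gap h apart: dp/dx = -12 mu u / h^2.
# On the hydraulic diameter of an infinitely wide slot (D_h = 2h) this is
# C_v = 48; the default loss model rescales by the actual gap aspect ratio.
POISEUILLE_SLOT_COEFF = 48.0


def _slot_poiseuille_coeff(Re, profile):
    """C_v such that C_v mu u / D_h^2 equals the plane-Poiseuille gradient
    12 mu u / gap^2 of the station's rectangular slot."""
    gap = 2.0 * profile.half_gap
    return 12.0 * (profile.hydraulic_diameter / gap) ** 2
SEPARATION_ANGLE_DEG = 10.0   # jet detaches past this divergence angle


def reynolds_number(u, d_h, rho: float = RHO_AIR,
                    mu_eff: float = MU_EFF_DEFAULT):
    """Station Reynolds number rho |u| D_h / mu_eff."""
    return rho * np.abs(u) * np.asarray(d_h) / mu_eff


@dataclass
class LossModel:
    """Pluggable entrance-effect and pressure-loss closures.

    ``entrance_correction(Re, profile) -> factor in (0, 1]`` shrinks the
    effective area on the contraction segment; ``pressure_loss(Re, profile)
    -> C_v`` gives the per-station dimensionless viscous loss coefficient in
    dtau = -C_v mu_eff u / D_h^2 dx.  Both receive the station Reynolds
    numbers and the :class:`LumenProfile` (shape descriptors).
    """

    entrance_correction: Callable = lambda Re, profile: 1.0
    pressure_loss: Callable = field(default=lambda Re, profile:
                                    _slot_poiseuille_coeff(Re, profile))
    separation_angle_deg: float = SEPARATION_ANGLE_DEG


def default_loss_model() -> LossModel:
    """Physics-based default: slot Poiseuille viscous loss + separation rule."""
    return LossModel()


def no_loss_model(separation_angle_deg: float = SEPARATION_ANGLE_DEG
                  ) -> LossModel:
    """Inviscid closure (tau = 0, Bernoulli limit).

    The separation rule is part of the jet kinematics, not of tau, so it is
    kept; pass ``separation_angle_deg=90`` for a fully attached solve.
    """
    return LossModel(
        entrance_correction=lambda Re, profile: 1.0,
        pressure_loss=lambda Re, profile: np.zeros(len(profile.x)),
        separation_angle_deg=separation_angle_deg)


def effective_area(a_geometric: np.ndarray, entrance_factor: float,
                   i_min: int | None = None) -> np.ndarray:
    """Entrance-effect area correction on the contraction segment.

    The factor applies from the inlet to the minimum-area station (the
    converging part of the stream); downstream stations are unchanged.
    """
    a = np.asarray(a_geometric, dtype=float)
    if np.any(a <= 0):
        raise VfsimError("non-positive geometric area")
    if not 0.0 < entrance_factor <= 1.0:
        raise VfsimError(
            f"entrance factor must be in (0, 1], got {entrance_factor}")
    if i_min is None:
        i_min = int(np.argmin(a))
    out = a.copy()
    out[: i_min + 1] *= entrance_factor
    return out


@dataclass
class FlowState:
    """1D flow fields on the lumen stations at one instant."""

    x: np.ndarray            # stations (m), strictly increasing
    area: np.ndarray         # effective area (m^2)
    u: np.ndarray            # m/s
    p: np.ndarray            # Pa
    tau: np.ndarray          # accumulated pressure loss (Pa, <= 0)
    Q: float                 # inlet volume flux (m^3/s)
    rho: float = RHO_AIR
    mu_eff: float = MU_EFF_DEFAULT
    P_in: float = 0.0
    P_out: float = 0.0
    time: float = 0.0
    i_sep: int = -1          # separation station index
    u_avg: np.ndarray | None = None   # area-averaged velocity q/A

    def __post_init__(self):
        if self.u_avg is None:
            self.u_avg = self.u.copy()

    @property
    def p_total(self) -> np.ndarray:
        """Total pressure p + rho V^2 / 2 per station."""
        return self.p + 0.5 * self.rho * self.u ** 2

    def copy(self) -> "FlowState":
        return FlowState(self.x.copy(), self.area.copy(), self.u.copy(),
                         self.p.copy(), self.tau.copy(), self.Q, self.rho,
                         self.mu_eff, self.P_in, self.P_out, self.time,
                         self.i_sep, self.u_avg.copy())


def init_flow_state(profile: LumenProfile, P_in: float = 0.0,
                    P_out: float = 0.0, rho: float = RHO_AIR,
                    mu_eff: float = MU_EFF_DEFAULT) -> FlowState:
    """Quiescent flow state on the profile's stations."""
    n = len(profile.x)
    return FlowState(
        x=np.asarray(profile.x, dtype=float), area=profile.area.copy(),
        u=np.zeros(n), p=np.zeros(n), tau=np.zeros(n), Q=0.0,
        rho=rho, mu_eff=mu_eff, P_in=P_in, P_out=P_out)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def find_separation(profile: LumenProfile, angle_deg: float,
                    area: np.ndarray | None = None) -> int:
    """First station past the minimum area whose divergence angle exceeds
    the threshold; the outlet if the flow never detaches."""
    a = profile.area if area is None else area
    i_min = int(np.argmin(a))
    thresh = np.tan(np.radians(angle_deg))
    idx = np.nonzero(profile.dhdx[i_min + 1:] > thresh)[0]
    return int(i_min + 1 + idx[0]) if idx.size else len(a) - 1


def steady_bernoulli(area: np.ndarray, P_in: float, P_out: float = 0.0,
                     rho: float = RHO_AIR, i_sep: int | None = None):
    """Closed-form steady lossless solution on a rigid area profile.

    Flux is constant, total pressure is conserved from the inlet to the
    separation (default: minimum-area) station, and the downstream jet
    carries the outlet pressure.  Returns ``(u, p)`` station arrays.
    """
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise VfsimError("non-positive area")
    if i_sep is None:
        i_sep = int(np.argmin(a))
    a_s, a_0 = a[i_sep], a[0]
    dp = P_in - P_out
    denom = 1.0 / a_s ** 2 - 1.0 / a_0 ** 2
    if denom <= 0:
        # uniform duct: no unique steady flux; zero-velocity solution
        return np.zeros_like(a), np.full_like(a, P_in)
    Q = np.sign(dp) * np.sqrt(2.0 * abs(dp) / (rho * denom))
    a_jet = np.minimum(a, a_s)
    u = np.where(np.arange(len(a)) <= i_sep, Q / a, Q / a_jet)
    p = np.where(np.arange(len(a)) <= i_sep,
                 P_in - 0.5 * rho * (u ** 2 - u[0] ** 2),
                 P_out)
    return u, p


def step_flow(state: FlowState, profile: LumenProfile,
              loss: LossModel | None = None, dt: float = 1e-6,
              cfl_max: float = 5.0, i_sep_pin: int | None = None) -> FlowState:
    """Advance the 1D flow one time step on the updated lumen profile.

    The discrete continuity constraint is satisfied exactly in conservative
    form by construction of the flux profile; the inlet flux solves the
    momentum integral between the pressure boundary values with a scalar
    Newton iteration (viscous and convective terms treated implicitly).
    ``i_sep_pin`` freezes the separation station (used by the partitioned
    coupling to keep the per-step fixed point smooth).
    """
    if dt <= 0:
        raise VfsimError("dt must be positive")
    if loss is None:
        loss = default_loss_model()
    x = np.asarray(profile.x, dtype=float)
    if len(x) != len(state.x) or np.any(np.diff(x) <= 0):
        raise VfsimError("profile stations must match the flow state grid "
                         "and be strictly increasing")
    a_geo = np.asarray(profile.area, dtype=float)
    if np.any(a_geo <= 0):
        raise VfsimError("negative or zero lumen area")

    u_face = 0.5 * np.abs(state.u_avg[:-1] + state.u_avg[1:])
    cfl = np.max(u_face * dt / np.diff(x))
    if cfl > cfl_max:
        raise CFLError(
            f"advective CFL {cfl:.2f} exceeds {cfl_max}; "
            f"reduce dt below {cfl_max * dt / cfl:.2e} s")

    rho, mu = state.rho, state.mu_eff
    Re = reynolds_number(state.u, profile.hydraulic_diameter, rho, mu)

    i_min = int(np.argmin(a_geo))
    factor = float(loss.entrance_correction(Re, profile))
    a = effective_area(a_geo, factor, i_min)
    adot = np.asarray(profile.area_dot, dtype=float).copy()
    adot[: i_min + 1] *= factor

    if i_sep_pin is not None:
        i_sep = int(i_sep_pin)
    else:
        i_sep = find_separation(profile, loss.separation_angle_deg, a)
    c_v = np.asarray(loss.pressure_loss(Re, profile), dtype=float)

    c = _cumtrapz(adot, x)                    # flux deficit Q(x) = Q_in - c
    I1 = _cumtrapz(1.0 / a, x)                # inertance integrand
    I2 = _cumtrapz(c / a, x)
    w = c_v * mu / (profile.hydraulic_diameter ** 2 * a)
    w[i_sep:] = 0.0          # detached jet: no wall friction past separation
    K1 = _cumtrapz(w, x)                      # viscous loss, linear in Q
    K2 = _cumtrapz(w * c, x)
    U_old = _cumtrapz(state.u_avg, x)

    s = i_sep
    last = len(a) - 1
    dP = state.P_in - state.P_out

    # The momentum balance is integrated over the whole duct: the unsteady
    # (air-column inertance) term acts everywhere, while past the
    # separation station the convective (Bernoulli) term is frozen at its
    # separation value — the detached jet recovers no pressure.
    def g_and_dg(Q):
        u_s = (Q - c[s]) / a[s]
        u_0 = Q / a[0]
        g = (rho / dt * (Q * I1[last] - I2[last] - U_old[last])
             + 0.5 * rho * (u_s * abs(u_s) - u_0 * abs(u_0))
             + (Q * K1[last] - K2[last]) - dP)
        dg = (rho / dt * I1[last]
              + rho * (abs(u_s) / a[s] - abs(u_0) / a[0]) + K1[last])
        return g, dg

    Q = state.Q
    for _ in range(50):
        g, dg = g_and_dg(Q)
        if dg <= 0:
            dg = rho / dt * I1[last] + K1[last] + 1e-30
        dQ = -g / dg
        Q = Q + dQ
        if abs(dQ) <= 1e-12 * max(abs(Q), 1e-9):
            break
    else:
        raise VfsimError("inlet-flux Newton iteration failed to converge")

    q = Q - c
    idx = np.arange(len(a))
    u_avg = q / a
    # reported velocity: past separation the jet core keeps the
    # separation-station area (it cannot widen with the duct)
    u = np.where(idx <= s, u_avg, q / np.minimum(a, a[s]))
    # kinetic pressure head frozen at the separation value downstream
    u_kin = np.where(idx <= s, u_avg, u_avg[s])
    tau_visc = -(Q * K1 - K2)
    p = (state.P_in - rho / dt * (Q * I1 - I2 - U_old)
         - 0.5 * rho * (u_kin * np.abs(u_kin) - u_avg[0] * abs(u_avg[0]))
         + tau_visc)
    # report tau as the accumulated total-pressure loss along the duct
    tau = p + 0.5 * rho * u * np.abs(u) - (state.P_in
                                           + 0.5 * rho * u_avg[0] ** 2)

    return FlowState(x=x, area=a, u=u, p=p, tau=tau, Q=float(Q),
                     rho=rho, mu_eff=mu, P_in=state.P_in, P_out=state.P_out,
                     time=state.time + dt, i_sep=s, u_avg=u_avg)


def continuity_residual(state_old: FlowState, state_new: FlowState,
                        dt: float) -> float:
    """Max cell-wise conservative-form residual |dA/dt + dQ/dx| (m^2/s).

    Zero to round-off by construction of :func:`step_flow`; exposed as a
    conservation diagnostic.
    """
    x = state_new.x
    idx = np.arange(len(x))
    a_jet = np.minimum(state_new.area, state_new.area[state_new.i_sep])
    a_flux = np.where(idx <= state_new.i_sep, state_new.area, a_jet)
    q_new = state_new.u * a_flux
    # cell integral form: d/dt int_cell A dx + (Q_right - Q_left)
    dadt_cell = 0.5 * (state_new.area[:-1] + state_new.area[1:]
                       - state_old.area[:-1] - state_old.area[1:]) / dt
    cell = dadt_cell * np.diff(x) + np.diff(q_new)
    return float(np.max(np.abs(cell)))
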