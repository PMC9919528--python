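"""Planar dynamics of the Ostraciiform robotic fish.

The rigid body moves in the horizontal plane under Kirchhoff's equations
with added-mass effects; the oscillating caudal fin forces it via the
reactive (virtual-mass) tail force of Lighthill's large-amplitude
elongated-body theory, evaluated at the tail tip.

Body-frame surge/sway/yaw (u, v, r) evolve as::

    (mb - Xu') u' = (mb - Yv') v r + Fx
    (mb - Yv') v' = -(mb - Xu') u r + Fy
    (Jbz - Nr') r' = (Yv' - Xu') u v + Mz

(the sway equation carries the minus sign required by Ṗ = P x ω; see
docs/methods.md) with optional quadratic drag, and world pose follows
``Ẋ = u cos a - v sin a``, ``Ẏ = u sin a + v cos a``, ``ȧ = r``.

Tail force: with the tail a rigid plate of length L hinged at the
peduncle, deflected by θ from the negative body x-axis (unit vectors
m̂ along the tail, n̂ perpendicular), the fluid reaction at the tip is::

    F = m_v w (V·m̂) n̂ - 1/2 m_v w² m̂,      w = V·n̂

where V is the tip velocity relative to still water and m_v the tail's
virtual (added) mass per unit length.  The -m̂ component is thrust; the
force vanishes when tail and body are at rest.  Moment about G is
``Mz = x_tip Fy - y_tip Fx``.

Integration is classical fixed-step 4th-order Runge-Kutta (reproducible,
4th-order convergent).  Headings are integrated unwrapped; wrap with
:func:`wrap_angle` for display.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .swarm_synth import wrap_angle

__all__ = [
    "BodyParams",
    "RobotState",
    "TailState",
    "ForceMoment",
    "TailSegment",
    "TailProgram",
    "tail_force",
    "step",
    "simulate_maneuver",
    "ManeuverTrajectory",
    "mirror_trajectory_check",
    "c_turn_program",
    "s_turn_program",
    "straight_program",
    "heading_change_per_period",
]

THETA_MAX = np.pi / 3  # mechanical tail deflection limit, rad


@dataclass
class BodyParams:
    """Rigid-body and hydrodynamic parameters.

    Defaults are sized for the 20 cm x 15 cm rigid body: mass 1.2 kg,
    yaw inertia 6e-3 kg m^2, added-mass derivatives of the usual negative
    sign, an 8 cm tail hinged 10 cm behind G, and tail virtual mass
    rho*pi*d^2/4 for a ~6 cm deep fin.  Quadratic drag keeps terminal
    speeds in the ~0.2 m/s range typical of desk-scale robotic fish;
    set ``drag_coeffs=(0, 0, 0)`` for the pure-equation tests.
    """

    mb: float = 1.2  # kg, body incl. pectoral fins
    Jbz: float = 6e-3  # kg m^2
    Xu_dot: float = -0.3  # kg
    Yv_dot: float = -0.6  # kg
    Nr_dot: float = -4e-3  # kg m^2
    tail_length: float = 0.08  # m
    tail_virtual_mass: float = 2.8  # kg / m
    tail_pivot: float = 0.10  # m, hinge distance behind G
    drag_coeffs: tuple[float, float, float] = (5.0, 10.0, 0.05)

    def __post_init__(self) -> None:
        if self.mb <= 0 or self.Jbz <= 0:
            raise ValueError("mb and Jbz must be > 0")
        if self.m_u <= 0 or self.m_v_eff <= 0 or self.j_r <= 0:
            raise ValueError("effective masses must be > 0 (check added-mass signs)")
        if self.tail_length <= 0 or self.tail_virtual_mass < 0:
            raise ValueError("tail geometry invalid")

    @property
    def m_u(self) -> float:
        return self.mb - self.Xu_dot

    @property
    def m_v_eff(self) -> float:
        return self.mb - self.Yv_dot

    @property
    def j_r(self) -> float:
        return self.Jbz - self.Nr_dot


@dataclass(frozen=True)
class RobotState:
    """Planar state: body velocities (u, v, r) and world pose (X, Y, alpha).

    ``alpha`` is kept unwrapped (continuous) so maneuvers can be
    analysed; ``heading`` gives the wrapped value in [-pi, pi).
    """

    u: float = 0.0
    v: float = 0.0
    r: float = 0.0
    X: float = 0.0
    Y: float = 0.0
    alpha: float = 0.0

    @property
    def heading(self) -> float:
        return float(wrap_angle(self.alpha))

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v, self.r, self.X, self.Y, self.alpha])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RobotState":
        return cls(*map(float, arr))

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


@dataclass(frozen=True)
class TailState:
    """Tail deflection θ (rad, from the negative body x-axis) and rate."""

    theta: float
    theta_dot: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.theta) > THETA_MAX + 1e-9:
            raise ValueError(f"|theta| exceeds the mechanical limit {THETA_MAX:.3f} rad")

    @property
    def m_hat(self) -> np.ndarray:
        """Unit vector along the tail (from hinge toward tip)."""
        return np.array([-np.cos(self.theta), np.sin(self.theta)])

    @property
    def n_hat(self) -> np.ndarray:
        """Unit vector perpendicular to the tail."""
        return np.array([np.sin(self.theta), np.cos(self.theta)])


@dataclass(frozen=True)
class ForceMoment:
    Fx: float = 0.0
    Fy: float = 0.0
    Mz: float = 0.0


def tail_force(params: BodyParams, tail: TailState, state: RobotState) -> ForceMoment:
    """Lighthill reactive force of the tail on the body, body frame."""
    if not state.is_finite():
        raise ValueError("robot state contains non-finite values")
    L, d = params.tail_length, params.tail_pivot
    m_hat, n_hat = tail.m_hat, tail.n_hat
    tip = np.array([-d, 0.0]) + L * m_hat
    # tip velocity relative to still water: body translation + rotation + flap
    v_tip = np.array([
        state.u - state.r * tip[1],
        state.v + state.r * tip[0],
    ]) + tail.theta_dot * L * np.array([np.sin(tail.theta), np.cos(tail.theta)])
    w = float(v_tip @ n_hat)
    v_m = float(v_tip @ m_hat)
    force = params.tail_virtual_mass * w * v_m * n_hat \
        - 0.5 * params.tail_virtual_mass * w * w * m_hat
    mz = tip[0] * force[1] - tip[1] * force[0]
    return ForceMoment(Fx=float(force[0]), Fy=float(force[1]), Mz=float(mz))


def _derivatives(
    y: np.ndarray, params: BodyParams, tail: TailState,
    extra_force: ForceMoment | None,
) -> np.ndarray:
    u, v, r, _, _, alpha = y
    state = RobotState(u=u, v=v, r=r, alpha=alpha)
    f = tail_force(params, tail, state)
    fx, fy, mz = f.Fx, f.Fy, f.Mz
    if extra_force is not None:
        fx += extra_force.Fx
        fy += extra_force.Fy
        mz += extra_force.Mz
    du_c, dv_c, dr_c = params.drag_coeffs
    fx -= du_c * u * abs(u)
    fy -= dv_c * v * abs(v)
    mz -= dr_c * r * abs(r)
    u_dot = (params.m_v_eff * v * r + fx) / params.m_u
    v_dot = (-params.m_u * u * r + fy) / params.m_v_eff
    r_dot = ((params.Yv_dot - params.Xu_dot) * u * v + mz) / params.j_r
    x_dot = u * np.cos(alpha) - v * np.sin(alpha)
    y_dot = u * np.sin(alpha) + v * np.cos(alpha)
    return np.array([u_dot, v_dot, r_dot, x_dot, y_dot, r])


def step(
    state: RobotState,
    params: BodyParams,
    tail,
    dt: float,
    extra_force: ForceMoment | None = None,
) -> RobotState:
    """One RK4 step.

    ``tail`` is either a frozen :class:`TailState` or a callable
    ``tau -> TailState`` giving the tail state ``tau`` seconds into the
    step (needed to keep 4th-order accuracy under a moving tail).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tail_at = tail if callable(tail) else (lambda _tau: tail)
    y0 = state.as_array()
    k1 = _derivatives(y0, params, tail_at(0.0), extra_force)
    k2 = _derivatives(y0 + 0.5 * dt * k1, params, tail_at(0.5 * dt), extra_force)
    k3 = _derivatives(y0 + 0.5 * dt * k2, params, tail_at(0.5 * dt), extra_force)
    k4 = _derivatives(y0 + dt * k3, params, tail_at(dt), extra_force)
    y1 = y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return RobotState.from_array(y1)


# ---------------------------------------------------------------------------
# tail programs and maneuvers


@dataclass(frozen=True)
class TailSegment:
    """One sinusoidal stroke segment: θ(τ) = bias + amplitude sin(2π f τ + phase)."""

    duration: float
    bias: float = 0.0
    amplitude: float = 0.0
    freq: float = 2.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if abs(self.bias) + self.amplitude > THETA_MAX + 1e-9:
            raise ValueError("bias + amplitude exceeds the tail deflection limit")

    def tail_state(self, tau: float) -> TailState:
        w = 2 * np.pi * self.freq
        return TailState(
            theta=self.bias + self.amplitude * np.sin(w * tau + self.phase),
            theta_dot=self.amplitude * w * np.cos(w * tau + self.phase),
        )


@dataclass(frozen=True)
class TailProgram:
    """A sequence of stroke segments; the last segment extends past its end."""

    segments: tuple[TailSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("program needs at least one segment")

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def tail_state(self, t: float) -> TailState:
        tau = t
        for seg in self.segments[:-1]:
            if tau < seg.duration:
                return seg.tail_state(tau)
            tau -= seg.duration
        return self.segments[-1].tail_state(tau)

    def negated(self) -> "TailProgram":
        """The θ -> -θ program (bias negated, flap phase shifted by π)."""
        return TailProgram(tuple(
            replace(s, bias=-s.bias, phase=s.phase + np.pi) for s in self.segments
        ))


def straight_program(amplitude: float = np.pi / 6, freq: float = 2.0,
                     duration: float = 10.0) -> TailProgram:
    """Symmetric flapping: forward swimming, no net turn."""
    return TailProgram((TailSegment(duration, 0.0, amplitude, freq),))


def c_turn_program(bias: float = np.pi / 5, amplitude: float = np.pi / 12,
                   freq: float = 2.0, duration: float = 8.0) -> TailProgram:
    """C-shape turn: sustained one-sided tail bias while flapping."""
    return TailProgram((TailSegment(duration, bias, amplitude, freq),))


def s_turn_program(bias: float = np.pi / 5, amplitude: float = np.pi / 12,
                   freq: float = 2.0, duration: float = 8.0) -> TailProgram:
    """S-shape maneuver: the bias sign reverses at the midpoint."""
    half = duration / 2.0
    return TailProgram((
        TailSegment(half, bias, amplitude, freq),
        TailSegment(half, -bias, amplitude, freq),
    ))


@dataclass
class ManeuverTrajectory:
    """Time series of robot states with the commanded tail angle."""

    times: np.ndarray  # (T,)
    states: np.ndarray  # (T, 6): u, v, r, X, Y, alpha (alpha unwrapped)
    theta: np.ndarray  # (T,)

    columns = ("u", "v", "r", "X", "Y", "alpha")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    def final_state(self) -> RobotState:
        return RobotState.from_array(self.states[-1])


def simulate_maneuver(
    program: TailProgram,
    params: BodyParams | None = None,
    duration: float = 10.0,
    dt: float = 0.005,
    initial: RobotState | None = None,
    extra_force: ForceMoment | None = None,
) -> ManeuverTrajectory:
    """Integrate a tail program from an initial state; deterministic."""
    if params is None:
        params = BodyParams()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if initial is None:
        initial = RobotState()
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    states = np.empty((n_steps + 1, 6))
    theta = np.empty(n_steps + 1)
    state = initial
    states[0] = state.as_array()
    theta[0] = program.tail_state(0.0).theta
    for k in range(n_steps):
        t0 = k * dt
        state = step(state, params, lambda tau: program.tail_state(t0 + tau), dt,
                     extra_force=extra_force)
        if not state.is_finite():
            raise RuntimeError(f"simulation became non-finite at step {k + 1}")
        states[k + 1] = state.as_array()
        theta[k + 1] = program.tail_state(t0 + dt).theta
    return ManeuverTrajectory(times=times, states=states, theta=theta)


def heading_change_per_period(traj: ManeuverTrajectory, freq: float) -> np.ndarray:
    """Net heading change over each whole flap period (stroboscopic view).

    Within a stroke the yaw rate oscillates; the per-period differences
    expose the maneuver-scale turn direction.
    """
    period = 1.0 / freq
    dt = traj.times[1] - traj.times[0]
    stride = max(1, int(round(period / dt)))
    alpha = traj.column("alpha")[::stride]
    return np.diff(alpha)


def mirror_trajectory_check(
    program: TailProgram,
    params: BodyParams | None = None,
    duration: float = 5.0,
    dt: float = 0.005,
    rtol: float = 1e-8,
    asymmetric_force: ForceMoment | None = None,
) -> bool:
    """True iff the θ-negated program yields the y-mirrored trajectory.

    The body is symmetric about its xz-plane, so (Y, alpha, v, r) must
    negate while (X, u) are preserved, up to ``rtol`` relative error.
    ``asymmetric_force`` applies a constant body-frame offset force to
    both runs; any lateral component breaks the symmetry, which serves
    as a sensitivity control for the check itself.
    """
    if params is None:
        params = BodyParams()
    a = simulate_maneuver(program, params, duration, dt, extra_force=asymmetric_force)
    b = simulate_maneuver(program.negated(), params, duration, dt,
                          extra_force=asymmetric_force)
    mirror = b.states * np.array([1.0, -1.0, -1.0, 1.0, -1.0, -1.0])
    scale = np.abs(a.states).max(axis=0) + 1e-12
    return bool(np.all(np.abs(a.states - mirror) / scale <= rtol))
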