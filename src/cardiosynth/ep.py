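"""Monodomain Aliev-Panfilov electrophysiology with mechano-electric feedback.

The transmembrane potential is evolved as a reaction-diffusion system on a
triangle surface mesh or a 1D cable.  The nondimensional potential ``phi``
(0 at rest, 1 fully excited) and recovery variable ``r`` follow the
two-variable Aliev-Panfilov kinetics

    I_e(phi, r) = c*phi*(phi - alpha)*(phi - 1) + r*phi
    dr/dtau     = (gamma + mu1*r/(mu2 + phi)) * (-r - c*phi*(phi - b - 1))

with an optional stretch-induced current ``I_m`` that is active only under
fiber tension (stretch ratio above 1).  The dimensional potential is the
affine map ``Phi = beta_phi*phi + delta_phi`` (defaults map [0, 1] onto
[-80, +20] mV) and local time runs as ``t = beta_t(x) * tau`` where the
time scale ``beta_t`` shrinks with the apex-to-base activation time, so
regions that depolarize last repolarize first.

Electrical activation drives an active contraction stress ``S_a`` through a
first-order relaxation toward ``k_T*(Phi - Phi_r)`` gated by a smooth
double-exponential delay function; ``S_a`` enters the second Piola-Kirchhoff
stress along the fiber, sheet and sheet-normal directions.

Conductivity is isotropic plus a fiber-aligned rank-one part; the discrete
diffusion operator uses mass-lumped linear finite elements with natural
(zero-flux) boundaries and explicit forward-Euler time stepping below the
spectral stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .geometry import TriMesh


@dataclass
class EPParams:
    """All model constants, with literature-standard defaults.

    Units: potentials mV, times ms, conductivities mm^2/ms (in model units
    ``chi_m`` and ``C_m`` default to 1 so the tensor scale is just
    ``d_iso``/``d_ani``); stresses kPa.
    """

    chi_m: float = 1.0          # surface-to-volume ratio (model units)
    C_m: float = 1.0            # membrane capacitance (model units)
    d_iso: float = 0.2          # isotropic conductivity scalar
    d_ani: float = 0.4          # fiber-aligned conductivity scalar
    beta_phi: float = 100.0     # potential scale, mV
    delta_phi: float = -80.0    # potential offset, mV (resting potential)
    c: float = 8.0              # excitation strength
    alpha: float = 0.15         # excitation threshold
    b: float = 0.15             # recovery threshold
    gamma: float = 0.002        # recovery base rate
    mu1: float = 0.2
    mu2: float = 0.3
    G_s: float = 10.0           # stretch-channel conductance
    phi_s: float = 0.6          # stretch reversal potential (nondimensional)
    t_alpha: float = 40.0       # apex-to-base activation span, ms
    t_beta: float = 12.9        # base time scale, ms
    tau0: float = 0.5
    t0: float = 0.0             # ms
    t1: float = 40.0            # ms
    k_T: float = 0.5            # contractility, kPa/mV
    Phi_r: float = -80.0        # resting potential, mV
    eps0: float = 0.1           # delay-function floor, 1/ms
    eps1: float = 1.0           # delay-function ceiling, 1/ms
    zeta: float = 0.1           # delay-function steepness, 1/mV
    Phi_t: float = 0.0          # delay-function threshold, mV
    eta1: float = 1.0           # active-stress weight along fibers
    eta2: float = 0.4           # ... along sheets
    eta3: float = 0.2           # ... along sheet normals

    def __post_init__(self) -> None:
        if self.beta_phi <= 0:
            raise ValueError("beta_phi must be positive")
        if self.mu2 <= 0:
            raise ValueError("mu2 must be positive")
        if not (self.eps1 >= self.eps0 > 0):
            raise ValueError("need eps1 >= eps0 > 0")
        if self.zeta <= 0:
            raise ValueError("zeta must be positive")


@dataclass
class FiberField:
    """Orthonormal fiber (a0), sheet (s0) and sheet-normal (n0) directions
    per mesh element."""

    a0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    def __post_init__(self) -> None:
        self.a0 = np.asarray(self.a0, dtype=float).reshape(-1, 3)
        self.s0 = np.asarray(self.s0, dtype=float).reshape(-1, 3)
        self.n0 = np.asarray(self.n0, dtype=float).reshape(-1, 3)
        for u, v in ((self.a0, self.s0), (self.a0, self.n0), (self.s0, self.n0)):
            if np.abs(np.einsum("ij,ij->i", u, v)).max() > 1e-6:
                raise ValueError("fiber triple is not orthogonal")
        for u in (self.a0, self.s0, self.n0):
            if np.abs(np.linalg.norm(u, axis=1) - 1.0).max() > 1e-6:
                raise ValueError("fiber directions must be unit vectors")


def circumferential_fibers(mesh: TriMesh, helix_angle: float = 0.0) -> FiberField:
    """Generic fiber map on an LV surface: circumferential fibers, optionally
    rotated in the tangent plane by a helix angle (radians)."""
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    normal = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nrm = np.linalg.norm(normal, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    n0 = normal / nrm
    zhat = np.array([0.0, 0.0, 1.0])
    circ = np.cross(np.broadcast_to(zhat, n0.shape), centroids)
    # project onto the element plane
    circ = circ - np.einsum("ij,ij->i", circ, n0)[:, None] * n0
    norms = np.linalg.norm(circ, axis=1, keepdims=True)
    fallback = np.cross(n0, np.broadcast_to(zhat, n0.shape))
    fb_norms = np.linalg.norm(fallback, axis=1, keepdims=True)
    fb_norms[fb_norms == 0] = 1.0
    degenerate = norms[:, 0] < 1e-9
    circ[degenerate] = (fallback / fb_norms)[degenerate]
    norms = np.linalg.norm(circ, axis=1, keepdims=True)
    a0 = circ / norms
    s0 = np.cross(n0, a0)
    if helix_angle != 0.0:
        ca, sa = np.cos(helix_angle), np.sin(helix_angle)
        a0, s0 = ca * a0 + sa * s0, -sa * a0 + ca * s0
    return FiberField(a0=a0, s0=s0, n0=n0)


# ---------------------------------------------------------------------------
# pointwise kinetics
# ---------------------------------------------------------------------------

def dimensionalize_potential(phi, params: EPParams = EPParams()):
    """Phi = beta_phi * phi + delta_phi (mV); defaults map 0 -> -80, 1 -> +20."""
    return params.beta_phi * np.asarray(phi, dtype=float) + params.delta_phi


def activation_time(Z, Z_apex: float, t_alpha: float):
    """Apex-to-base activation time t_a = t_alpha * (1 - Z/Z_apex) (ms).

    With Z measured from the base, the apex (Z = Z_apex) activates at 0 and
    the base at ``t_alpha``.
    """
    if Z_apex == 0:
        raise ValueError("Z_apex must be non-zero")
    return t_alpha * (1.0 - np.asarray(Z, dtype=float) / Z_apex)


def local_time_scale(t_a, params: EPParams = EPParams()):
    """beta_t = t_beta * (1 - tau0*(t_a - t0)/(t1 - t0)) (ms), positive."""
    if params.t1 == params.t0:
        raise ValueError("t1 must differ from t0")
    beta = params.t_beta * (1.0 - params.tau0 * (np.asarray(t_a, dtype=float) - params.t0) / (params.t1 - params.t0))
    if np.any(beta <= 0):
        raise ValueError("activation-time rescaling produced a non-positive time scale")
    return beta


def electric_current(phi, r, params: EPParams = EPParams()):
    """Aliev-Panfilov cubic plus recovery coupling (nondimensional)."""
    phi = np.asarray(phi, dtype=float)
    return params.c * phi * (phi - params.alpha) * (phi - 1.0) + np.asarray(r, dtype=float) * phi


def recovery_rate(phi, r, params: EPParams = EPParams()):
    """dr/dtau of the recovery variable."""
    phi = np.asarray(phi, dtype=float)
    r = np.asarray(r, dtype=float)
    return (params.gamma + params.mu1 * r / (params.mu2 + phi)) * (
        -r - params.c * phi * (phi - params.b - 1.0)
    )


def stretch_current(lambda_f, phi, params: EPParams = EPParams()):
    """Stretch-induced current, gated by the Heaviside tension switch.

    I_m = H(lambda - 1) * G_s * (lambda - 1) * (phi - phi_s): stretch-
    activated channels conduct only under tension.
    """
    lam = np.asarray(lambda_f, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("fiber stretch must be positive")
    gate = (lam > 1.0).astype(float)
    return gate * params.G_s * (lam - 1.0) * (np.asarray(phi, dtype=float) - params.phi_s)


def ionic_current(phi, r, lambda_f=1.0, beta_t=None, params: EPParams = EPParams()):
    """Dimensional ionic current I_ion = C_m*(beta_phi/beta_t)*(I_e + I_m)."""
    if beta_t is None:
        beta_t = params.t_beta
    beta_t = np.asarray(beta_t, dtype=float)
    if np.any(beta_t <= 0):
        raise ValueError("beta_t must be positive")
    ie = electric_current(phi, r, params)
    im = stretch_current(lambda_f, phi, params)
    return params.C_m * (params.beta_phi / beta_t) * (ie + im)


def delay_function(Phi, params: EPParams = EPParams()):
    """Smooth bounded delay eps(Phi) = eps0 + (eps1-eps0)*exp(-exp(-zeta*(Phi-Phi_t)))."""
    Phi = np.asarray(Phi, dtype=float)
    arg = np.clip(-params.zeta * (Phi - params.Phi_t), -700.0, 700.0)  # avoid exp overflow at saturated tails
    return params.eps0 + (params.eps1 - params.eps0) * np.exp(-np.exp(arg))


def active_stress_rate(Phi, S_a, params: EPParams = EPParams()):
    """dS_a/dt = eps(Phi) * (k_T*(Phi - Phi_r) - S_a) (kPa/ms).

    For constant Phi the steady state is k_T*(Phi - Phi_r).
    """
    return delay_function(Phi, params) * (
        params.k_T * (np.asarray(Phi, dtype=float) - params.Phi_r) - np.asarray(S_a, dtype=float)
    )


def active_stress_tensor(S_passive: np.ndarray, S_a, fibers: FiberField, params: EPParams = EPParams()) -> np.ndarray:
    """Total second Piola-Kirchhoff stress with anisotropic active addition.

    S = S_passive + S_a * (eta1 a0 x a0 + eta2 s0 x s0 + eta3 n0 x n0),
    evaluated per element; the added term has eigenvalues
    S_a * {eta1, eta2, eta3}.
    """
    S_passive = np.asarray(S_passive, dtype=float)
    S_a = np.atleast_1d(np.asarray(S_a, dtype=float))
    add = (
        params.eta1 * np.einsum("ei,ej->eij", fibers.a0, fibers.a0)
        + params.eta2 * np.einsum("ei,ej->eij", fibers.s0, fibers.s0)
        + params.eta3 * np.einsum("ei,ej->eij", fibers.n0, fibers.n0)
    )
    total = S_passive + S_a[:, None, None] * add
    return total[0] if total.shape[0] == 1 and S_passive.ndim == 2 else total


def conductivity_tensor(params: EPParams, a0: np.ndarray) -> np.ndarray:
    """Per-element tensor D = (d_iso*C_m/chi_m) I + (d_ani*C_m/chi_m) a0 x a0."""
    a0 = np.asarray(a0, dtype=float)
    scale = params.C_m / params.chi_m
    if a0.ndim == 1:
        return scale * (params.d_iso * np.eye(3) + params.d_ani * np.outer(a0, a0))
    return scale * (params.d_iso * np.eye(3)[None] + params.d_ani * np.einsum("ei,ej->eij", a0, a0))


# ---------------------------------------------------------------------------
# spatial discretisation
# ---------------------------------------------------------------------------


@dataclass
class Cable1D:
    """A 1D cable domain of ``length`` mm with ``n_nodes`` equispaced nodes."""

    length: float
    n_nodes: int

    def __post_init__(self) -> None:
        if self.length <= 0 or self.n_nodes < 3:
            raise ValueError("cable needs positive length and >= 3 nodes")
        self.x = np.linspace(0.0, self.length, self.n_nodes)


@dataclass
class DiffusionOperator:
    """Mass-lumped FEM diffusion: symmetric stiffness K (zero row sums), lumped
    mass vector, spectral estimate and the explicit stability step."""

    K: sp.csr_matrix
    mass: np.ndarray
    lambda_max: float
    dt_stable: float

    def matvec(self, phi: np.ndarray) -> np.ndarray:
        """d(phi)/dt contribution: -M^-1 K phi (units 1/ms)."""
        return -(self.K @ phi) / self.mass


def _power_iteration_lambda_max(K: sp.spmatrix, mass: np.ndarray, iters: int = 60) -> float:
    rng = np.random.default_rng(12345)  # fixed: the bound must be deterministic
    v = rng.standard_normal(K.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(iters):
        w = (K @ v) / mass
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        lam = nw
        v = w / nw
    return float(lam)


def assemble_diffusion(domain, params: EPParams = EPParams(), fibers: FiberField | None = None) -> DiffusionOperator:
    """Assemble the discrete diffusion operator on a Cable1D or TriMesh.

    Linear elements, per-element conductivity tensor (isotropic plus
    fiber-aligned part projected onto the element plane), lumped mass and
    natural zero-flux boundaries.  The operator annihilates constants and
    ``-K`` is negative semidefinite.
    """
    scale = params.C_m / params.chi_m
    if isinstance(domain, Cable1D):
        n = domain.n_nodes
        h = domain.length / (n - 1)
        d = scale * (params.d_iso + (params.d_ani if fibers is not None else 0.0))
        main = np.full(n, 2.0 * d / h)
        main[0] = main[-1] = d / h
        K = sp.diags([np.full(n - 1, -d / h), main, np.full(n - 1, -d / h)], [-1, 0, 1], format="csr")
        mass = np.full(n, h)
        mass[0] = mass[-1] = h / 2.0
    elif isinstance(domain, TriMesh):
        mesh = domain
        tri = mesh.vertices[mesh.faces]
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        normal = np.cross(e1, e2)
        area2 = np.linalg.norm(normal, axis=1)
        if np.any(area2 <= 0):
            raise ValueError("degenerate face in mesh")
        nhat = normal / area2[:, None]
        area = 0.5 * area2
        if fibers is None:
            D = scale * params.d_iso * np.broadcast_to(np.eye(3), (len(tri), 3, 3))
        else:
            D = conductivity_tensor(params, fibers.a0)
        # P1 basis gradients in the element plane: grad lambda_i = (n x opposite edge)/(2A)
        edges = np.stack([tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2], tri[:, 1] - tri[:, 0]], axis=1)
        grads = np.cross(nhat[:, None, :], edges) / (2.0 * area)[:, None, None]
        Dg = np.einsum("eab,ejb->eja", D, grads)
        Ke = np.einsum("eia,eja,e->eij", grads, Dg, area)
        rows = np.repeat(mesh.faces, 3, axis=1).reshape(-1)
        cols = np.tile(mesh.faces, (1, 3)).reshape(-1)
        K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)), shape=(mesh.n_vertices, mesh.n_vertices)).tocsr()
        mass = np.zeros(mesh.n_vertices)
        for k in range(3):
            np.add.at(mass, mesh.faces[:, k], area / 3.0)
        n_comp, _ = connected_components(sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=K.shape), directed=False)
        if n_comp > 1:
            raise ValueError("mesh is disconnected")
    else:
        raise TypeError("domain must be a Cable1D or TriMesh")
    K = (K + K.T) * 0.5  # enforce exact symmetry against roundoff
    lam = _power_iteration_lambda_max(K, mass)
    dt = 0.9 * 2.0 / lam if lam > 0 else np.inf
    return DiffusionOperator(K=K.tocsr(), mass=mass, lambda_max=lam, dt_stable=float(dt))


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------


@dataclass
class Stimulus:
    """External excitation: additive d(phi)/dt of ``amplitude`` (1/ms) on
    ``nodes`` for ``duration`` ms starting at ``start``."""

    nodes: np.ndarray
    amplitude: float = 0.5
    duration: float = 2.0
    start: float = 0.0


@dataclass
class EPResult:
    """Sampled trajectories of the monodomain simulation."""

    times: np.ndarray            # ms
    phi: np.ndarray              # (n_samples, n_nodes), nondimensional
    r: np.ndarray
    S_a: np.ndarray              # kPa
    Phi: np.ndarray              # mV
    activation_times: np.ndarray  # ms, first crossing of phi = 0.5 (nan if never)
    dt: float
    beta_t: np.ndarray


def simulate_monodomain(
    domain,
    params: EPParams = EPParams(),
    fibers: FiberField | None = None,
    stimulus: Stimulus | None = None,
    T_end: float = 100.0,
    dt: float | None = None,
    n_samples: int = 51,
    z_coords: np.ndarray | None = None,
    lambda_f: np.ndarray | float = 1.0,
    pure_diffusion: bool = False,
    phi0: np.ndarray | None = None,
    r0: np.ndarray | None = None,
) -> EPResult:
    """Explicit monodomain integration of phi, r and S_a in dimensional time.

    ``z_coords`` (mm, base at 0) enables the apex-to-base activation-time
    rescaling of the local time scale ``beta_t``; without it the uniform
    scale ``t_beta`` at ``t_a = t0`` is used.  ``pure_diffusion`` switches
    the reaction terms off (used for conservation checks).  Integration
    aborts with a diagnostic if the potential leaves [-2, 2].
    """
    op = assemble_diffusion(domain, params, fibers)
    n = op.mass.shape[0]
    if dt is None:
        # reaction time scale ~ beta_t/c limits the step alongside diffusion
        dt = min(op.dt_stable, params.t_beta / (2.0 * params.c))
    elif dt > op.dt_stable:
        raise ValueError(f"dt={dt:g} exceeds the explicit stability bound {op.dt_stable:g} ms")
    if z_coords is not None:
        t_a = activation_time(np.asarray(z_coords, dtype=float), float(np.max(z_coords)), params.t_alpha)
        beta_t = local_time_scale(t_a, params)
    else:
        beta_t = np.full(n, local_time_scale(params.t0, params))
    phi = np.zeros(n) if phi0 is None else np.asarray(phi0, dtype=float).copy()
    r = np.zeros(n) if r0 is None else np.asarray(r0, dtype=float).copy()
    S_a = np.zeros(n)
    lam = np.broadcast_to(np.asarray(lambda_f, dtype=float), (n,))

    n_steps = max(1, int(np.ceil(T_end / dt)))
    sample_idx = np.unique(np.linspace(0, n_steps, n_samples).round().astype(int))
    times, phis, rs, sas = [], [], [], []
    activation = np.full(n, np.nan)

    def record(step: int) -> None:
        times.append(step * dt)
        phis.append(phi.copy())
        rs.append(r.copy())
        sas.append(S_a.copy())

    record(0)
    sample_set = set(sample_idx.tolist()) - {0}
    stim_nodes = None
    if stimulus is not None:
        stim_nodes = np.asarray(stimulus.nodes, dtype=int)
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        dphi = op.matvec(phi)
        if not pure_diffusion:
            ie = electric_current(phi, r, params)
            im = stretch_current(lam, phi, params)
            dphi = dphi - (ie + im) / beta_t
            dr = recovery_rate(phi, r, params) / beta_t
            Phi_now = dimensionalize_potential(phi, params)
            dSa = active_stress_rate(Phi_now, S_a, params)
        if stim_nodes is not None and stimulus.start <= t < stimulus.start + stimulus.duration:
            dphi[stim_nodes] = dphi[stim_nodes] + stimulus.amplitude
        phi = phi + dt * dphi
        if not pure_diffusion:
            r = r + dt * dr
            S_a = S_a + dt * dSa
        newly = np.isnan(activation) & (phi >= 0.5)
        activation[newly] = step * dt
        if np.max(np.abs(phi)) > 2.0:
            raise RuntimeError(
                f"monodomain integration unstable at t={step * dt:g} ms "
                f"(max |phi| = {np.max(np.abs(phi)):g}); reduce dt or conductivity"
            )
        if step in sample_set:
            record(step)

    phis = np.array(phis)
    return EPResult(
        times=np.array(times),
        phi=phis,
        r=np.array(rs),
        S_a=np.array(sas),
        Phi=dimensionalize_potential(phis, params),
        activation_times=activation,
        dt=float(dt),
        beta_t=np.asarray(beta_t),
    )


def front_speed(result: EPResult, x: np.ndarray, x_from: float, x_to: float) -> float:
    """Wave speed (mm/ms) between two probe positions on a 1D cable, from the
    recorded activation times."""
    x = np.asarray(x, dtype=float)
    i = int(np.argmin(np.abs(x - x_from)))
    j = int(np.argmin(np.abs(x - x_to)))
    t_i, t_j = result.activation_times[i], result.activation_times[j]
    if np.isnan(t_i) or np.isnan(t_j) or t_j == t_i:
        raise ValueError("wave did not traverse both probe positions")
    return float(abs(x[j] - x[i]) / (t_j - t_i))
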