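"""Spring systems, distance-covariant random forces, and static relaxation.

Each band (ring) of the NPC is an independent spring system: its s nodes
are anchored to the central axis by radial springs (standing in for the
nuclear envelope) and connected to their 2h nearest same-band neighbours
by circumferential springs (standing in for protein-protein contacts).
Shorter circumferential springs are stiffer than longer ones, and radial
springs are less stiff than the shortest circumferential spring.

Irregular deformation comes from scalar forces drawn from a zero-mean
multivariate normal whose covariance decays with the distance between
nodes (an RBF kernel), so forces on nearby nodes - including nodes of
different bands - are similar.  The scalar forces are turned into purely
radial, planar force vectors (which exert no net torque, avoiding whole-
model rotations) and each band is relaxed to its static equilibrium by
direct minimization of the total potential.  Correlated axial offsets are
drawn from the same kernel, independently, and added to z without any
spring interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, DegenerateGeometryError, ValidationError
from .npc_assembly import NPCModel, SimulationConfig, mean_radius

__all__ = [
    "SpringSystem",
    "ForceField",
    "AxialOffsetField",
    "build_springs",
    "force_covariance",
    "sample_scalar_forces",
    "radialize",
    "relax",
    "sample_axial_offsets",
    "deform_npc",
    "STIFFNESS_SCALE",
]

#: Global stiffness scale K: circumferential springs get k = K / rest_length
#: (so shorter springs are stiffer) and radial springs get half the
#: stiffness of the longest (weakest) circumferential spring.  K is
#: calibrated so that a uniform radial force of magnitude 10 dilates the
#: default ring (radius 53.7 nm, s=8, h=2) by 2 nm; the effective ring
#: stiffness is k_eff = K/r * [1/(4 sin(pi h/s)) + 2 sum_{h'} sin(pi h'/s)],
#: giving K = 5 * 53.7 / 2.53313 = 106.0.  See docs/methods.md.
STIFFNESS_SCALE = 106.0

#: Equilibrium tolerance: maximum per-node net-force norm after relaxation.
RESIDUAL_TOL = 1e-6


@dataclass
class SpringSystem:
    """One band's nodes plus its radial and circumferential springs.

    Rest lengths equal the geometry the system is built from (zero initial
    tension).  ``pairs`` holds the circumferential spring endpoints as
    (i, j) node indices within the band; ``pair_order`` the neighbour
    order h' of each spring.
    """

    rest_positions: np.ndarray  # (s, 3)
    h: int
    k_radial: float
    pairs: np.ndarray  # (n_springs, 2) int
    pair_order: np.ndarray  # (n_springs,) int
    k_circ: np.ndarray  # (n_springs,) stiffness per spring
    rest_radial: np.ndarray = field(init=False)  # (s,)
    rest_circ: np.ndarray = field(init=False)  # (n_springs,)

    def __post_init__(self):
        xy = self.rest_positions[:, :2]
        self.rest_radial = np.hypot(xy[:, 0], xy[:, 1])
        d = self.rest_positions[self.pairs[:, 0]] - self.rest_positions[self.pairs[:, 1]]
        self.rest_circ = np.linalg.norm(d, axis=1)

    @property
    def n_nodes(self) -> int:
        return self.rest_positions.shape[0]

    def stiffness_by_order(self) -> dict[int, float]:
        """Mean circumferential stiffness per neighbour order h'."""
        return {
            int(o): float(np.mean(self.k_circ[self.pair_order == o]))
            for o in np.unique(self.pair_order)
        }


def build_springs(
    band_nodes: np.ndarray,
    h: int,
    stiffness_scale: float = STIFFNESS_SCALE,
    k_radial: float | None = None,
) -> SpringSystem:
    """Build the spring system of one band from its current node positions.

    Parameters
    ----------
    band_nodes : (s, 3) positions ordered by spoke.
    h : neighbour order; each node connects to its 2h nearest same-band
        neighbours (h=2 by default at the config level: larger h costs
        compute, smaller h gives overly jagged deformations).
    stiffness_scale : the constant K in k = K / rest_length.
    k_radial : radial spring stiffness; defaults to half the weakest
        circumferential stiffness (or K / mean radius when h=0).
    """
    band_nodes = np.asarray(band_nodes, dtype=float)
    s = band_nodes.shape[0]
    if not 0 <= h <= s // 2:
        raise ValidationError(f"h must be in 0..floor(s/2)={s // 2}, got {h}")

    seen: set[tuple[int, int]] = set()
    pairs, orders = [], []
    for hp in range(1, h + 1):
        for i in range(s):
            j = (i + hp) % s
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(key)
            orders.append(hp)
    pairs_arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
    orders_arr = np.asarray(orders, dtype=int)
    if len(pairs):
        rest = np.linalg.norm(band_nodes[pairs_arr[:, 0]] - band_nodes[pairs_arr[:, 1]], axis=1)
        if np.any(rest <= 0):
            raise ValidationError("coincident nodes: zero-length circumferential spring")
        k_circ = stiffness_scale / rest
        default_kr = 0.5 * float(k_circ.min())
    else:
        k_circ = np.empty(0)
        default_kr = stiffness_scale / float(np.mean(np.hypot(band_nodes[:, 0], band_nodes[:, 1])))
    return SpringSystem(
        rest_positions=band_nodes,
        h=h,
        k_radial=default_kr if k_radial is None else float(k_radial),
        pairs=pairs_arr,
        pair_order=orders_arr,
        k_circ=k_circ,
    )


@dataclass
class ForceField:
    """Scalar and radialized vector forces per node plus their covariance."""

    scalar: np.ndarray  # (m,)
    vectors: np.ndarray  # (m, 3), z component 0
    cov: np.ndarray  # (m, m) scaled covariance
    dmag: float
    sigma_kernel: float


@dataclass
class AxialOffsetField:
    """Correlated per-node z offsets o_i; offset vectors are (0, 0, o_i)."""

    offsets: np.ndarray  # (m,)
    omag: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        out = coords.copy()
        out[:, 2] += self.offsets
        return out


def _equalized_positions(positions: np.ndarray) -> np.ndarray:
    """Replace every node's lateral radius by the global mean radius.

    Angles and z are kept.  Distances computed on the equalized cloud make
    the force field blind to radius differences between bands, which
    preserves band concentricity during deformation.
    """
    positions = np.asarray(positions, dtype=float)
    r = np.hypot(positions[:, 0], positions[:, 1])
    rbar = float(np.mean(r))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, rbar / r, 0.0)
    eq = positions.copy()
    eq[:, 0] *= scale
    eq[:, 1] *= scale
    return eq


def force_covariance(
    positions: np.ndarray, dmag: float, sigma_kernel: float
) -> np.ndarray:
    """Scaled RBF covariance of scalar forces between all node pairs.

    cov'_ij = (dmag/3)^2 * exp(-||xi - xj||^2 / (2 sigma^2)) with distances
    taken on radius-equalized positions.  The marginal SD is dmag/3, so
    +-dmag covers ~99.7% of the sampling range.
    """
    if dmag < 0:
        raise ValidationError(f"dmag must be >= 0, got {dmag}")
    if sigma_kernel <= 0:
        raise ValidationError(f"sigma_kernel must be > 0, got {sigma_kernel}")
    eq = _equalized_positions(positions)
    d2 = np.sum((eq[:, None, :] - eq[None, :, :]) ** 2, axis=-1)
    var = (dmag / 3.0) ** 2
    return var * np.exp(-d2 / (2.0 * sigma_kernel**2))


def sample_scalar_forces(cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw f ~ N(0, cov) via Cholesky with minimal diagonal jitter.

    Jitter (<= 1e-10 relative to the largest diagonal entry) is added only
    if factorization fails; covariances that stay non-PSD beyond that are
    a numerical error.
    """
    m = cov.shape[0]
    scale = float(np.max(np.diag(cov)))
    if scale == 0.0:
        return np.zeros(m)
    jitters = [0.0, 1e-14, 1e-12, 1e-10]
    chol = None
    for j in jitters:
        try:
            chol = np.linalg.cholesky(cov + j * scale * np.eye(m))
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise np.linalg.LinAlgError(
            "force covariance is not positive semi-definite within jitter tolerance"
        )
    return chol @ rng.standard_normal(m)


def radialize(scalar_forces: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Turn scalar forces into radial, planar force vectors.

    f_vec_i = f_i * (lateral unit vector of node i), z component 0.  Radial
    forces exert no torque about the central axis, so the model neither
    rotates nor flips.
    """
    positions = np.asarray(positions, dtype=float)
    scalar_forces = np.asarray(scalar_forces, dtype=float)
    r = np.hypot(positions[:, 0], positions[:, 1])
    if np.any(r < 1e-9):
        raise DegenerateGeometryError("node on the central axis: no radial direction")
    vec = np.zeros((positions.shape[0], 3))
    vec[:, 0] = scalar_forces * positions[:, 0] / r
    vec[:, 1] = scalar_forces * positions[:, 1] / r
    return vec


def _potential_and_grad(
    xy_flat: np.ndarray, springs: SpringSystem, forces_xy: np.ndarray
) -> tuple[float, np.ndarray]:
    """Total potential U and its gradient w.r.t. lateral positions.

    U = sum_radial 1/2 k (l - l0)^2 + sum_circ 1/2 k (l - l0)^2 - sum f.x
    with z frozen at the rest values.
    """
    s = springs.n_nodes
    xy = xy_flat.reshape(s, 2)
    z = springs.rest_positions[:, 2]

    r = np.hypot(xy[:, 0], xy[:, 1])
    r_safe = np.maximum(r, 1e-12)
    dr = r - springs.rest_radial
    u = 0.5 * springs.k_radial * np.sum(dr**2)
    grad = (springs.k_radial * dr / r_safe)[:, None] * xy

    if len(springs.pairs):
        i, j = springs.pairs[:, 0], springs.pairs[:, 1]
        dxy = xy[i] - xy[j]
        dz = z[i] - z[j]
        ell = np.sqrt(np.sum(dxy**2, axis=1) + dz**2)
        ell_safe = np.maximum(ell, 1e-12)
        de = ell - springs.rest_circ
        u += 0.5 * np.sum(springs.k_circ * de**2)
        gvec = (springs.k_circ * de / ell_safe)[:, None] * dxy
        np.add.at(grad, i, gvec)
        np.add.at(grad, j, -gvec)

    u -= float(np.sum(forces_xy * xy))
    grad -= forces_xy
    return float(u), grad.ravel()


def relax(
    springs: SpringSystem,
    external_forces: np.ndarray,
    residual_tol: float = RESIDUAL_TOL,
) -> np.ndarray:
    """Static equilibrium of one band under external force vectors.

    Minimizes the total potential (spring energy minus work of the
    external forces) over the lateral coordinates with z frozen, by
    quasi-Newton descent with the analytic gradient.  Returns the (s, 3)
    equilibrium positions; raises ConvergenceError if the residual
    per-node net force exceeds ``residual_tol``.
    """
    external_forces = np.asarray(external_forces, dtype=float)
    if not np.all(np.isfinite(external_forces)):
        raise ValidationError("external forces must be finite")
    forces_xy = external_forces[:, :2]
    if np.allclose(forces_xy, 0.0):
        return springs.rest_positions.copy()

    x = springs.rest_positions[:, :2].ravel()
    x, resid = _newton_solve(x, springs, forces_xy)
    if resid >= residual_tol:
        # fall back to quasi-Newton from rest, then polish again
        res = optimize.minimize(
            _potential_and_grad,
            springs.rest_positions[:, :2].ravel(),
            args=(springs, forces_xy),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "gtol": 1e-8, "ftol": 1e-15},
        )
        x, resid = _newton_solve(res.x, springs, forces_xy)
    if resid >= residual_tol:
        raise ConvergenceError(
            f"relaxation residual {resid:.3e} exceeds tolerance {residual_tol:.1e}"
        )
    out = springs.rest_positions.copy()
    out[:, :2] = x.reshape(-1, 2)
    return out


def _hessian(xy: np.ndarray, springs: SpringSystem) -> np.ndarray:
    """Analytic Hessian of the spring potential w.r.t. lateral positions.

    Each spring of stiffness k, length l, rest length l0 and lateral unit
    separation contributes the standard block
    k * (d d^T / l^2) + k (l - l0) * (I / l - d d^T / l^3)
    with d the lateral separation (z is frozen, so the out-of-plane part
    of circumferential springs only enters through l).
    """
    s = springs.n_nodes
    n = 2 * s
    H = np.zeros((n, n))
    z = springs.rest_positions[:, 2]

    # radial springs: the other endpoint is the fixed center
    r = np.hypot(xy[:, 0], xy[:, 1])
    r_safe = np.maximum(r, 1e-12)
    for i in range(s):
        d = xy[i] / r_safe[i]
        outer = np.outer(d, d)
        blk = springs.k_radial * (
            outer + (r[i] - springs.rest_radial[i]) / r_safe[i] * (np.eye(2) - outer)
        )
        H[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] += blk

    for sp_idx in range(len(springs.pairs)):
        i, j = springs.pairs[sp_idx]
        k = springs.k_circ[sp_idx]
        l0 = springs.rest_circ[sp_idx]
        dxy = xy[i] - xy[j]
        dz = z[i] - z[j]
        ell = np.sqrt(dxy @ dxy + dz * dz)
        ell = max(ell, 1e-12)
        outer = np.outer(dxy, dxy)
        blk = k * (outer / ell**2 + (ell - l0) * (np.eye(2) / ell - outer / ell**3))
        for a, bb, sign in ((i, i, 1.0), (j, j, 1.0), (i, j, -1.0), (j, i, -1.0)):
            H[2 * a : 2 * a + 2, 2 * bb : 2 * bb + 2] += sign * blk
    return H


def _newton_solve(
    x: np.ndarray, springs: SpringSystem, forces_xy: np.ndarray, max_iter: int = 30
) -> tuple[np.ndarray, float]:
    """Damped Newton on grad U = 0; returns (solution, residual norm)."""
    u, g = _potential_and_grad(x, springs, forces_xy)
    resid = float(np.max(np.linalg.norm(g.reshape(-1, 2), axis=1)))
    for _ in range(max_iter):
        if resid < 1e-9:
            break
        H = _hessian(x.reshape(-1, 2), springs)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = -g
        t = 1.0
        improved = False
        for _ in range(25):
            u_new, g_new = _potential_and_grad(x + t * step, springs, forces_xy)
            r_new = float(np.max(np.linalg.norm(g_new.reshape(-1, 2), axis=1)))
            if r_new < resid or u_new < u - 1e-15:
                x = x + t * step
                u, g, resid = u_new, g_new, r_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return x, resid


def sample_axial_offsets(
    positions: np.ndarray,
    omag: float,
    sigma_kernel: float,
    rng: np.random.Generator,
) -> AxialOffsetField:
    """Correlated axial offsets, drawn exactly like scalar forces.

    Same RBF kernel on radius-equalized distances, marginal SD omag/3,
    independent random stream; applied additively to z with no spring
    interaction.
    """
    if omag < 0:
        raise ValidationError(f"omag must be >= 0, got {omag}")
    m = np.asarray(positions).shape[0]
    if omag == 0:
        return AxialOffsetField(offsets=np.zeros(m), omag=0.0)
    cov = force_covariance(positions, omag, sigma_kernel)
    return AxialOffsetField(offsets=sample_scalar_forces(cov, rng), omag=omag)


def deform_npc(
    model: NPCModel,
    config: SimulationConfig,
    rng_forces: np.random.Generator,
    rng_axial: np.random.Generator,
    rng_elongation: np.random.Generator | None = None,
    elongation_q: float | None = None,
) -> NPCModel:
    """Apply irregular deformation to an assembled NPC.

    One scalar-force field is sampled jointly over all nodes of all bands
    (shared covariance, radius-equalized distances) so that deformations
    are continuous across bands; elongation forces are added if q < 1;
    forces are radialized; each band is then relaxed separately against
    its own spring system.  Correlated axial offsets are applied last.
    """
    q = config.elongation_q if elongation_q is None else elongation_q
    rbar = mean_radius(model)
    sigma = config.kernel_fraction * rbar
    omag = config.effective_omag

    out = model.copy()
    scalars = np.zeros(model.m)
    if config.dmag > 0:
        cov = force_covariance(model.coords, config.dmag, sigma)
        scalars = sample_scalar_forces(cov, rng_forces)
    if q < 1.0:
        from .geometric_variability import elongation_forces

        if rng_elongation is None:
            raise ValidationError("elongation requested but no elongation rng provided")
        scalars = scalars + elongation_forces(model, q, rng_elongation)

    if np.any(scalars != 0.0):
        vectors = radialize(scalars, model.coords)
        for j in range(model.g):
            idx = model.band_nodes(j)
            springs = build_springs(model.coords[idx], h=min(config.h, len(idx) // 2))
            out.coords[idx] = relax(springs, vectors[idx])

    if omag > 0:
        off = sample_axial_offsets(model.coords, omag, sigma, rng_axial)
        out.coords = off.apply(out.coords)

    out.provenance.update({"dmag": config.dmag, "omag": omag, "elongation_q": q})
    return out
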