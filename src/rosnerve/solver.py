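"""Explicit finite-difference solver for single-species ROS reaction-diffusion.

One scalar concentration field (superoxide or hydrogen peroxide, in nM) is
integrated on the anisotropic voxel grid with a forward-Euler / central
difference (FTCS) scheme:

    dc/dt = div(D grad c) + RP - RS * c

where D is a per-voxel diffusion triple (Dxx = Dyy, Dzz) in µm²/s, RP a
per-voxel production rate (nM/s, nonzero only at mitochondrion voxels or
configured extra-axonal sources) and RS a per-voxel first-order scavenging
rate (1/s).  Membrane voxels carry the species' membrane permeability as an
in-plane diffusion coefficient via D_m = P_m · L (L = one voxel edge) and
are axially blocking (Dzz = 0).  Face fluxes use harmonic means, so a zero
membrane diffusion is exactly impermeable; domain boundaries are no-flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import geometry as geo
from ._kernels import face_coefficients, run_chunk

__all__ = [
    "ConcentrationField", "CoefficientMaps", "SteadyResult", "StabilityError",
    "membrane_diffusion", "myelin_folds", "myelin_permeability",
    "assemble_coefficients", "stability_dt", "step", "run_steps",
    "run_to_steady_state", "solve_steady_state",
]


class StabilityError(RuntimeError):
    """The explicit update produced NaN or negative concentrations."""


@dataclass
class ConcentrationField:
    """Scalar concentration per voxel in nM, with species tag and bio time."""

    values: np.ndarray            # float64 (nx, ny, nz)
    species: str = "h2o2"         # "h2o2" | "o2minus"
    t: float = 0.0                # biological seconds

    @classmethod
    def uniform(cls, shape, c0_nM: float = 0.0, species: str = "h2o2"):
        return cls(np.full(shape, float(c0_nM)), species=species, t=0.0)

    def total_amount(self) -> float:
        """Sum of voxel values (proportional to total moles on a fixed grid)."""
        return float(self.values.sum())


@dataclass
class CoefficientMaps:
    """Per-voxel coefficients of the discretized reaction-diffusion system.

    ``dxx`` doubles for the Y direction (the coronal plane is isotropic);
    ``dzz`` is the axial coefficient, zero in all membrane-class voxels.
    ``rp`` is in nM/s, ``rs`` in 1/s.  Face-rate arrays are derived lazily
    and cached; they depend only on the diffusion maps, so production updates
    during a simulation do not invalidate them.
    """

    dxx: np.ndarray
    dzz: np.ndarray
    rp: np.ndarray
    rs: np.ndarray
    res_xy: float
    res_z: float

    @cached_property
    def faces(self):
        return face_coefficients(self.dxx, self.dzz, self.res_xy, self.res_z)


# ---------------------------------------------------------------------------
# permeability calibration
# ---------------------------------------------------------------------------

def membrane_diffusion(p_m_um_s: float, res_xy: float) -> float:
    """Membrane-voxel diffusion coefficient from membrane permeability.

    Permeability and diffusion are related by P_m = D_m / L with L the
    membrane thickness; here the membrane is one voxel, L = 1/res_xy, so
    D_m = P_m / res_xy (µm²/s).
    """
    if p_m_um_s < 0 or res_xy <= 0:
        raise ValueError("need P_m >= 0 and res_xy > 0")
    return p_m_um_s / res_xy


def myelin_folds(myelin_thickness_um: float = 0.2,
                 membrane_thickness_um: float = 0.01) -> float:
    """Number of myelin folds: each fold is two membranes thick."""
    if myelin_thickness_um <= 0 or membrane_thickness_um <= 0:
        raise ValueError("thicknesses must be positive")
    return myelin_thickness_um / (2.0 * membrane_thickness_um)


def myelin_permeability(p_m_membrane: float, myelin_thickness_um: float = 0.2,
                        membrane_thickness_um: float = 0.01) -> float:
    """Permeability through a myelin wrap.

    A wrap of n folds stacks 2n membranes in series, attenuating the single
    membrane permeability by 2n; the default thicknesses (0.2 µm myelin,
    10 nm membrane) give 10 folds and hence a 20x reduction.
    """
    folds = myelin_folds(myelin_thickness_um, membrane_thickness_um)
    return p_m_membrane / (2.0 * folds)


# ---------------------------------------------------------------------------
# coefficient assembly
# ---------------------------------------------------------------------------

def diffusion_maps(model: geo.NerveModel, params) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (Dxx=Dyy, Dzz) from compartment labels and zone permeability."""
    p_m = params.p_m_um_s
    p_node = params.p_m_node_um_s if params.p_m_node_um_s is not None else p_m
    d_m = membrane_diffusion(p_m, model.res_xy)
    d_my = membrane_diffusion(p_m / params.myelin_attenuation, model.res_xy)
    d_nd = membrane_diffusion(p_node, model.res_xy)

    lut = np.zeros(5)
    lut[geo.EXTRA_AXONAL] = params.d_free_um2_s
    lut[geo.AXON_INTERIOR] = params.d_free_um2_s
    lut[geo.AXON_MEMBRANE] = d_m
    lut[geo.MYELIN] = d_my
    lut[geo.NODE_GAP] = d_nd
    dxx = lut[model.labels]
    dzz = np.where(model.is_membrane_like(), 0.0,
                   np.full(model.grid_shape, params.d_free_um2_s))
    return dxx, dzz


def scavenging_map(model: geo.NerveModel, params) -> np.ndarray:
    """Per-voxel first-order scavenging rate (1/s).

    Interior voxels scavenge at the intracellular rate, extra-axonal voxels
    at the extra-axonal rate, membrane-class voxels not at all (a membrane's
    only medium property is its diffusion).  Mitochondrion voxels scavenge at
    ``rs_mito_factor`` times the local rate (mitochondrial matrix antioxidant
    systems).  Per-zone multipliers scale whole z-slabs, e.g. a 30 % reduced
    internodal scavenging scenario uses ``zone_rs={"internodal": 0.7}``.
    """
    rs = np.zeros(model.grid_shape)
    rs[model.labels == geo.AXON_INTERIOR] = params.rs_intra
    rs[model.labels == geo.EXTRA_AXONAL] = params.rs_extra
    if params.zone_rs:
        zfac = np.ones(model.grid_shape[2])
        for name, fac in params.zone_rs.items():
            code = {v: k for k, v in geo.ZONE_NAMES.items()}[name]
            zfac[model.zone_z == code] = fac
        rs *= zfac[None, None, :]
    rs[model.mito] *= params.rs_mito_factor
    return rs


def assemble_coefficients(model: geo.NerveModel, params,
                          states=None) -> CoefficientMaps:
    """Assemble the full coefficient maps for a model and parameter set.

    Production is placed at mitochondrion voxels from the host unit's state
    and the configured production model (dead hosts produce nothing); if
    ``states`` is omitted every unit is treated as healthy.
    """
    from . import dynamics  # runtime import avoids a module cycle

    dxx, dzz = diffusion_maps(model, params)
    rs = scavenging_map(model, params)
    units = dynamics.build_units(model, params)
    rp = units.production_map(states)
    if (model.labels[model.labels > 4]).size:
        raise ValueError("unclassified voxels in model")
    return CoefficientMaps(dxx=dxx, dzz=dzz, rp=rp, rs=rs,
                           res_xy=model.res_xy, res_z=model.res_z)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def stability_dt(coeffs: CoefficientMaps, safety: float = 0.9,
                 dt_cap: float = 1.0) -> float:
    """Largest stable forward-Euler step for the assembled coefficients.

    Standard FTCS bound with the voxel's reaction rate included:

        dt = safety / (4 * maxD_xy * res_xy^2 + 2 * maxD_z * res_z^2 + maxRS)

    which guarantees non-negative, non-oscillatory updates (face rates never
    exceed the per-voxel maxima entering the bound).  Returns ``dt_cap`` for
    an all-zero system.
    """
    max_dxy = float(coeffs.dxx.max()) if coeffs.dxx.size else 0.0
    max_dz = float(coeffs.dzz.max()) if coeffs.dzz.shape[2] > 1 else 0.0
    max_rs = float(coeffs.rs.max()) if coeffs.rs.size else 0.0
    denom = (2.0 * max_dxy * (2.0 * coeffs.res_xy**2)
             + 2.0 * max_dz * coeffs.res_z**2 + max_rs)
    if denom <= 0:
        return dt_cap
    return min(safety / denom, dt_cap)


def _validate(values: np.ndarray, t: float) -> None:
    bad = ~np.isfinite(values)
    if bad.any() or (values < 0).any():
        vmin = float(np.nanmin(values))
        raise StabilityError(
            f"update produced {'NaN' if bad.any() else 'negative'} "
            f"concentrations at t={t:.6g} s (min={vmin:.3g} nM); "
            "the time step likely violates the stability bound")


def run_steps(field: ConcentrationField, coeffs: CoefficientMaps, dt: float,
              nsteps: int, check: bool = True) -> ConcentrationField:
    """Advance ``nsteps`` explicit steps; validates the result unless asked not to."""
    fx, fy, fz = coeffs.faces
    values = run_chunk(field.values, fx, fy, fz, coeffs.rp, coeffs.rs,
                       dt, nsteps)
    t = field.t + dt * nsteps
    if check:
        _validate(values, t)
    return ConcentrationField(values, species=field.species, t=t)


def step(field: ConcentrationField, coeffs: CoefficientMaps,
         dt: float) -> ConcentrationField:
    """One forward-Euler update of the concentration field."""
    return run_steps(field, coeffs, dt, 1)


def solve_steady_state(coeffs: CoefficientMaps, c0_nM: float = 0.0,
                       tol: float = 1e-10,
                       maxiter: int = 20000) -> ConcentrationField:
    """Direct steady state of the frozen-coefficient system.

    Solves (RS − div D grad) c = RP by conjugate gradients; the operator is
    symmetric positive definite wherever voxels are scavenged or coupled.
    Voxels that are completely isolated *and* unscavenged (e.g. membrane
    voxels of an impermeable species) have no dynamics and keep ``c0_nM``.
    Only valid while production is frozen (no state transitions); the
    time-stepping route remains the reference for dynamic runs.
    """
    from scipy.sparse.linalg import LinearOperator, cg

    shape = coeffs.dxx.shape
    fx, fy, fz = coeffs.faces
    diag = coeffs.rs.copy()
    diag[:-1, :, :] += fx
    diag[1:, :, :] += fx
    diag[:, :-1, :] += fy
    diag[:, 1:, :] += fy
    if fz.size:
        diag[:, :, :-1] += fz
        diag[:, :, 1:] += fz
    iso = diag <= 0

    def matvec(v):
        c = v.reshape(shape)
        y = coeffs.rs * c
        d = fx * (c[1:, :, :] - c[:-1, :, :])
        y[:-1, :, :] -= d
        y[1:, :, :] += d
        d = fy * (c[:, 1:, :] - c[:, :-1, :])
        y[:, :-1, :] -= d
        y[:, 1:, :] += d
        if fz.size:
            d = fz * (c[:, :, 1:] - c[:, :, :-1])
            y[:, :, :-1] -= d
            y[:, :, 1:] += d
        y[iso] = c[iso]
        return y.ravel()

    n = int(np.prod(shape))
    b = coeffs.rp.copy()
    b[iso] = c0_nM
    pre = 1.0 / np.where(iso, 1.0, diag)
    op = LinearOperator((n, n), matvec=matvec, dtype=float)
    mop = LinearOperator((n, n), matvec=lambda v: pre.ravel() * v, dtype=float)
    x, info = cg(op, b.ravel(), rtol=tol, atol=0.0, maxiter=maxiter, M=mop)
    if info != 0:
        raise RuntimeError(f"steady-state CG did not converge (info={info})")
    values = x.reshape(shape)
    values[np.abs(values) < 1e-300] = 0.0
    np.maximum(values, 0.0, out=values)
    return ConcentrationField(values, t=float("inf"))


@dataclass
class SteadyResult:
    field: ConcentrationField
    t_bio: float
    converged: bool
    rate: float = float("nan")   # last observed max relative change per second


def run_to_steady_state(field: ConcentrationField, coeffs: CoefficientMaps,
                        tol: float = 1e-4, t_max: float = 10.0,
                        dt: float | None = None,
                        check_every: int = 200) -> SteadyResult:
    """Integrate until the field is steady or ``t_max`` biological seconds.

    Convergence: the maximum absolute change per second across voxels,
    relative to the field's current maximum, drops below ``tol`` (1/s).  A
    zero-production, zero-initial field converges immediately.  Returns the
    field either way, flagging non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if dt is None:
        dt = stability_dt(coeffs)
    t0 = field.t
    rate = float("inf")
    if field.values.max() <= 0 and coeffs.rp.max() <= 0:
        return SteadyResult(field, 0.0, True, 0.0)
    while field.t - t0 < t_max:
        n = min(check_every, max(1, int(round((t_max - (field.t - t0)) / dt))))
        prev = field.values
        field = run_steps(field, coeffs, dt, n)
        scale = max(float(field.values.max()), 1e-12)
        rate = float(np.abs(field.values - prev).max()) / (n * dt * scale)
        if rate < tol:
            return SteadyResult(field, field.t - t0, True, rate)
    return SteadyResult(field, field.t - t0, False, rate)
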