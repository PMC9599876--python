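"""Independent reference solutions used to validate the solver and dynamics.

Everything here is deliberately implemented without touching the voxel
solver's code paths: closed forms, scalar ODE integration and plain
arithmetic only, so agreement between the two routes is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


def uniform_steady_oracle(rp_uM_s: float, rs_per_s: float) -> float:
    """Fixed point of the well-mixed reaction system, in nM.

    dc/dt = RP - RS*c has the steady state c* = RP/RS; with RP in µM/s and
    RS in 1/s the result is RP/RS * 1000 nM.
    """
    if rs_per_s <= 0:
        raise ValueError("no steady state without scavenging (RS must be > 0)")
    return rp_uM_s / rs_per_s * 1e3


@dataclass(frozen=True)
class TwoBoxSolution:
    """Closed-form equilibration of two well-mixed boxes across a membrane."""

    v_in: float       # µm³
    v_out: float      # µm³
    area: float       # µm²
    p_m: float        # µm/s
    c_in0: float      # nM
    c_out0: float     # nM

    @property
    def rate(self) -> float:
        """Exponential equilibration rate P_m * A * (1/V_in + 1/V_out), 1/s."""
        return self.p_m * self.area * (1.0 / self.v_in + 1.0 / self.v_out)

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.rate

    @property
    def c_eq(self) -> float:
        """Conserved-amount mean both boxes relax to."""
        return (self.c_in0 * self.v_in + self.c_out0 * self.v_out) \
            / (self.v_in + self.v_out)

    def concentrations(self, t: float) -> tuple[float, float]:
        d = (self.c_in0 - self.c_out0) * math.exp(-self.rate * t)
        ceq = self.c_eq
        return (ceq + d * self.v_out / (self.v_in + self.v_out),
                ceq - d * self.v_in / (self.v_in + self.v_out))


def two_box_permeability_oracle(v_in: float, v_out: float, area: float,
                                p_m: float, c_in0: float,
                                c_out0: float) -> TwoBoxSolution:
    if min(v_in, v_out, area) <= 0 or p_m < 0:
        raise ValueError("volumes and area must be positive, P_m >= 0")
    return TwoBoxSolution(v_in, v_out, area, p_m, c_in0, c_out0)


def gaussian_spread_oracle(d_um2_s: float, t: float, source_mass: float,
                           coords: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Free-diffusion heat kernel at distance(s) ``coords`` from the source.

    Returns the concentration profile of a point mass after time t in an
    unbounded ``ndim``-dimensional medium; per-axis variance is 2*D*t.
    """
    if d_um2_s <= 0 or t <= 0:
        raise ValueError("need D > 0 and t > 0")
    r2 = np.asarray(coords, dtype=float) ** 2
    return source_mass / (4.0 * math.pi * d_um2_s * t) ** (ndim / 2.0) \
        * np.exp(-r2 / (4.0 * d_um2_s * t))


# ---------------------------------------------------------------------------
# per-axon zero-dimensional degeneration oracle
# ---------------------------------------------------------------------------

@dataclass
class AxonFate:
    dead: bool
    status: str
    c_final_nM: float


def axon_zero_d_oracle(volume_voxels: float, rs_sum_per_s: float,
                       rp_total_nM_s: float,
                       stress_nM: float, death_nM: float, dwell_s: float,
                       stress_factor: float, t_max: float,
                       dt: float, allow_recovery: bool = True,
                       c0_nM: float = 0.0) -> AxonFate:
    """Fate of one membrane-sealed axon treated as a well-mixed pool.

    With an impermeable membrane the axon exchanges nothing with its
    surroundings, so its interior follows a scalar balance: total production
    ``rp_total_nM_s`` (summed over its mitochondrion voxels, state factor
    applied) against the axon's summed scavenging conductance
    ``rs_sum_per_s`` (Σ over voxels of their scavenging rates, e.g.
    RS·(n_interior + (mito_factor−1)·n_mito)), all diluted into
    ``volume_voxels`` voxels of storage (interior plus membrane):

        dc/dt = (RP_tot * f(state) - RS_sum * c) / V

    The same H/S/D rules as the voxel model are stepped explicitly.  The
    arithmetic here is scalar forward integration, independent of the 3D
    stencil code.
    """
    vol = volume_voxels
    c = c0_nM
    status, clock = "H", 0.0
    t = 0.0
    while t < t_max:
        fac = {"H": 1.0, "S": stress_factor, "D": 0.0}[status]
        c += dt * (rp_total_nM_s * fac - rs_sum_per_s * c) / vol
        t += dt
        if status == "D":
            continue
        if c >= death_nM:
            status = "D"
            continue
        if status == "S":
            if allow_recovery and c < stress_nM:
                status, clock = "H", 0.0
            else:
                clock += dt
                if clock >= dwell_s:
                    status = "D"
                    continue
        elif status == "H" and c >= stress_nM:
            status = "S"
    return AxonFate(dead=(status == "D"), status=status, c_final_nM=c)


def two_box_numeric(v_in: float, v_out: float, area: float, p_m: float,
                    c_in0: float, c_out0: float, t_eval: np.ndarray):
    """ODE-integrated two-box model (independent of the closed form too)."""
    def rhs(_, y):
        j = p_m * area * (y[0] - y[1])
        return [-j / v_in, j / v_out]

    sol = solve_ivp(rhs, (0.0, float(t_eval[-1])), [c_in0, c_out0],
                    t_eval=t_eval, rtol=1e-10, atol=1e-12)
    return sol.y
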