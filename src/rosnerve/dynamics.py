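"""ROS production models, oxidative-stress state machine, simulation loop.

Axonal segments (and individual glial mitochondria) are finite-state units:
Healthy [H], Oxidative Stress [S] or Dead [D].  Transitions are driven by
the unit's representative hydrogen-peroxide (or superoxide) concentration —
by default the mean over the segment's interior voxels:

* H -> S when c >= stress_threshold (oxidative distress, ~100 nM for H2O2)
* S -> H when c < stress_threshold (optional recovery; stress clock resets)
* any -> D when c >= death_threshold (~1 µM for H2O2)
* S -> D when the accumulated time in S reaches the stress dwell timer
* D is absorbing; production at a dead unit's mitochondria ceases.

Two mitochondrial production hypotheses are implemented.  RP_SAME gives
every mitochondrion the same rate RP_H (µM/s per mitochondrion voxel),
independent of its axon.  RP_FCONST ties production to conduction energy at
constant firing frequency: the rate is alpha * f / (R * mito%), inversely
proportional to the axon radius R, so two axons with radii R1 < R2 satisfy
RP(R1) = (R2/R1) * RP(R2).  In the Stress state production is scaled by a
factor limited to ±30 %: 0.7 (NF_RP, production falls under stress) or
1.0 / 1.3 (PF_RP, production holds or rises).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from . import geometry as geo
from . import solver as sv

__all__ = [
    "HEALTHY", "STRESSED", "DEAD", "STATUS_NAMES",
    "BiochemParams", "UnitStates", "Units", "Event", "SimulationResult",
    "base_production", "stress_production_factor", "build_units",
    "update_states", "run_simulation", "simulate", "calibrate_production",
]

HEALTHY, STRESSED, DEAD = 0, 1, 2
STATUS_NAMES = {HEALTHY: "H", STRESSED: "S", DEAD: "D"}

@dataclass(frozen=True)
class BiochemParams:
    """Biochemical constants of one single-species run.

    Concentrations are handled in nM; production rates are accepted in µM/s
    (the conventional unit for mitochondrial ROS output) and converted
    internally.  ``p_m_um_s`` is the membrane permeability of the active
    species (~2-200 µm/s for hydrogen peroxide, 0 for superoxide, which does
    not cross membranes); myelinated membrane voxels attenuate it by
    ``myelin_attenuation`` (20x for ~10 myelin folds).
    """

    d_free_um2_s: float = 2000.0        # free diffusion in tissue water
    p_m_um_s: float = 20.0              # unmyelinated membrane permeability
    p_m_node_um_s: float | None = None  # node-gap permeability (default: p_m)
    myelin_attenuation: float = 20.0
    rs_intra: float = 10.0              # intracellular scavenging, 1/s
    rs_extra: float = 10.0              # extra-axonal scavenging, 1/s
    rs_mito_factor: float = 5.0         # matrix antioxidants vs cytosol
    zone_rs: dict = dc_field(default_factory=dict)   # e.g. {"internodal": 0.7}
    rp_h: float = 10.0                  # µM/s per mitochondrion voxel (RP_SAME)
    production_model: str = "RP_SAME"   # "RP_SAME" | "RP_FCONST"
    alpha: float = 1.0                  # µM·µm·%/s lumped constant (RP_FCONST)
    firing_rate_hz: float = 1.0
    mito_axon_pct: float = 4.0          # nominal mito volume ratio in the law
    stress_mode: str = "NF_RP"          # "NF_RP" | "PF_RP"
    stress_factor: float | None = None  # default 0.7 (NF) / 1.0 (PF)
    glia_rp_h: float | None = None      # µM/s per glial mitochondrion
    glia_stress_mode: str | None = None
    glia_stress_factor: float | None = None
    stress_threshold_nM: float = 100.0
    death_threshold_nM: float = 1000.0
    stress_dwell_s: float = 60.0
    allow_recovery: bool = True
    paranodal_fraction: float = 0.75    # share of segment energy near the node
    internodal_fraction: float = 0.05   # internodal rate as fraction of nodal
    c0_nM: float = 0.0
    segment_aggregate: str = "mean"     # "mean" | "max_mito"

    def __post_init__(self):
        if not 0 < self.stress_threshold_nM < self.death_threshold_nM:
            raise ValueError("need 0 < stress_threshold < death_threshold")
        for mode, fac in ((self.stress_mode, self.stress_factor),
                          (self.glia_stress_mode, self.glia_stress_factor)):
            if mode is None:
                continue
            if mode not in ("NF_RP", "PF_RP"):
                raise ValueError(f"unknown stress mode {mode!r}")
            f = fac if fac is not None else (0.7 if mode == "NF_RP" else 1.0)
            if mode == "NF_RP" and not 0.7 <= f < 1.0:
                raise ValueError("NF_RP stress factor must be in [0.7, 1.0)")
            if mode == "PF_RP" and not 1.0 <= f <= 1.3:
                raise ValueError("PF_RP stress factor must be in [1.0, 1.3]")
        if self.production_model not in ("RP_SAME", "RP_FCONST"):
            raise ValueError(f"unknown production model {self.production_model!r}")

    def resolved_stress_factor(self, glial: bool = False) -> float:
        mode = (self.glia_stress_mode or self.stress_mode) if glial \
            else self.stress_mode
        fac = (self.glia_stress_factor if glial and
               self.glia_stress_factor is not None else
               (self.stress_factor if not glial else None))
        if glial and self.glia_stress_mode is None and \
                self.glia_stress_factor is None:
            fac = self.stress_factor
        if fac is None:
            fac = 0.7 if mode == "NF_RP" else 1.0
        return fac


def base_production(radius_um: float, mito_axon_pct: float,
                    model: str = "RP_FCONST", alpha: float = 1.0,
                    f: float = 1.0, rp_h: float = 10.0) -> float:
    """Healthy-state production per mitochondrion voxel, in µM/s.

    RP_SAME returns ``rp_h`` regardless of the axon.  RP_FCONST returns
    alpha * f / (R * mito%): at constant firing frequency the segment's
    conduction energy scales with its membrane area (~R) while mitochondrial
    volume scales with R² * mito%, so the per-mitochondrion rate falls as
    1/(R * mito%).
    """
    if model == "RP_SAME":
        return rp_h
    if model == "RP_FCONST":
        if radius_um <= 0 or mito_axon_pct <= 0:
            raise ValueError("RP_FCONST needs positive radius and mito%")
        return alpha * f / (radius_um * mito_axon_pct)
    raise ValueError(f"unknown production model {model!r}")


def stress_production_factor(mode: str, status: int | str,
                             stress_factor: float | None = None) -> float:
    """Production multiplier for a unit state: H 1.0, D 0.0, S mode-dependent."""
    code = {"H": HEALTHY, "S": STRESSED, "D": DEAD}.get(status, status)
    if code == DEAD:
        return 0.0
    if code == HEALTHY:
        return 1.0
    if code == STRESSED:
        if stress_factor is not None:
            return stress_factor
        if mode == "NF_RP":
            return 0.7
        if mode == "PF_RP":
            return 1.0
        raise ValueError(f"unknown stress mode {mode!r}")
    raise ValueError(f"unknown status {status!r}")


# ---------------------------------------------------------------------------
# units: segments + glial mitochondria
# ---------------------------------------------------------------------------

@dataclass
class UnitStates:
    """Status and stress dwell clock of every unit."""

    status: np.ndarray   # uint8
    clock: np.ndarray    # float64, seconds accumulated in S

    @classmethod
    def healthy(cls, n: int) -> "UnitStates":
        return cls(np.zeros(n, dtype=np.uint8), np.zeros(n))

    def copy(self) -> "UnitStates":
        return UnitStates(self.status.copy(), self.clock.copy())


@dataclass(frozen=True)
class Event:
    t: float
    unit: int
    old: str
    new: str
    trigger: str         # "threshold" | "timer" | "death_threshold"


class Units:
    """Flattened bookkeeping linking voxels to state-machine units.

    Units 0..n_segments-1 are axonal segments (in the model's segment
    order); the remaining units are individual glial mitochondria.  Arrays:

    * ``sense_flat`` / ``sense_unit``: voxels whose concentrations aggregate
      into each unit's representative value,
    * ``mito_flat`` / ``mito_unit`` / ``mito_base``: mitochondrion voxels,
      their host unit and their healthy-state production in nM/s (zone
      multipliers applied).
    """

    def __init__(self, model: geo.NerveModel, params: BiochemParams):
        self.model = model
        self.params = params
        nz = model.grid_shape[2]
        n_axons = model.n_axons
        n_slabs = max(1, len(model.segments) // n_axons) if n_axons else 0
        self.n_segments = len(model.segments)

        # z-slice -> segment slab index (uniform tiling from geometry)
        slab_of_z = np.zeros(nz, dtype=np.int64)
        if n_axons:
            for j, z0 in enumerate(sorted(s.z_lo
                                          for s in model.segments[:n_slabs])):
                slab_of_z[z0:] = j
        zz = np.broadcast_to(np.arange(nz), model.grid_shape)

        interior = model.labels == geo.AXON_INTERIOR
        seg_unit = np.where(
            model.axon_id >= 0,
            model.axon_id.astype(np.int64) * n_slabs + slab_of_z[zz], -1)

        glial_mask = model.mito & (model.labels == geo.EXTRA_AXONAL)
        glial_flat = np.flatnonzero(glial_mask.ravel())
        self.n_glia = glial_flat.size
        self.n_units = self.n_segments + self.n_glia

        # sensing: interior voxels -> their segment; glial mito -> itself
        int_flat = np.flatnonzero(interior.ravel())
        self.sense_flat = np.concatenate([int_flat, glial_flat])
        self.sense_unit = np.concatenate([
            seg_unit.ravel()[int_flat],
            self.n_segments + np.arange(self.n_glia)])
        self.sense_count = np.bincount(self.sense_unit,
                                       minlength=self.n_units).astype(float)
        if (self.sense_count[:self.n_segments] == 0).any():
            raise ValueError("segment without interior voxels")

        # production sites
        ax_mask = model.mito & interior
        ax_flat = np.flatnonzero(ax_mask.ravel())
        radii = model.radii()
        base_by_axon = np.array([
            base_production(r, params.mito_axon_pct, params.production_model,
                            params.alpha, params.firing_rate_hz, params.rp_h)
            for r in radii]) if n_axons else np.empty(0)
        ax_ids = model.axon_id.ravel()[ax_flat]
        z_of = zz.reshape(-1)[ax_flat]
        zone_of = model.zone_z[z_of]
        ax_base = base_by_axon[ax_ids] * 1e3                    # µM/s -> nM/s
        ax_base[zone_of == geo.ZONE_INTERNODAL] *= params.internodal_fraction
        ax_base[zone_of == geo.ZONE_NODE] = 0.0
        # Paranodal mitochondria share a fixed budget: they jointly supply
        # ``paranodal_fraction`` of the segment's conduction demand, which in
        # a myelinated axon is concentrated at the node.  The budget is the
        # production an unmyelinated stretch of the node's length would host
        # (expected mito count there x the nominal per-mito rate), so per-
        # mito rates fall as more paranodal mitochondria are present.
        para_sel = zone_of == geo.ZONE_PARANODAL
        if para_sel.any():
            is_node_z = (model.zone_z == geo.ZONE_NODE)[None, None, :]
            node_int = interior & is_node_z
            node_cnt = np.bincount(
                model.axon_id[node_int].ravel(), minlength=n_axons) \
                if node_int.any() else np.zeros(n_axons)
            n_para = np.bincount(ax_ids[para_sel], minlength=n_axons)
            m_node_exp = params.mito_axon_pct / 100.0 * node_cnt
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(n_para > 0,
                                 params.paranodal_fraction * m_node_exp
                                 / np.maximum(n_para, 1), 0.0)
            ax_base[para_sel] *= share[ax_ids[para_sel]]
        glia_rp = params.glia_rp_h if params.glia_rp_h is not None else params.rp_h
        gl_base = np.full(self.n_glia, glia_rp * 1e3)

        self.mito_flat = np.concatenate([ax_flat, glial_flat])
        self.mito_unit = np.concatenate([
            seg_unit.ravel()[ax_flat],
            self.n_segments + np.arange(self.n_glia)])
        self.mito_base = np.concatenate([ax_base, gl_base])

        self.is_glial = np.zeros(self.n_units, dtype=bool)
        self.is_glial[self.n_segments:] = True
        self.axon_of = np.full(self.n_units, -1, dtype=np.int64)
        if self.n_segments:
            self.axon_of[:self.n_segments] = np.repeat(
                np.arange(n_axons), n_slabs)

        self._s_factor = np.where(
            self.is_glial, params.resolved_stress_factor(glial=True),
            params.resolved_stress_factor(glial=False))

        if params.segment_aggregate == "max_mito":
            # representative concentration = max over mitochondrion voxels,
            # falling back to the interior mean for mito-free units
            self._agg_max = True
        elif params.segment_aggregate == "mean":
            self._agg_max = False
        else:
            raise ValueError("segment_aggregate must be 'mean' or 'max_mito'")

    # -- aggregation --------------------------------------------------------
    def unit_means(self, values: np.ndarray) -> np.ndarray:
        flat = values.ravel()
        sums = np.bincount(self.sense_unit, weights=flat[self.sense_flat],
                           minlength=self.n_units)
        means = sums / self.sense_count
        if self._agg_max:
            peak = np.zeros(self.n_units)
            np.maximum.at(peak, self.mito_unit, flat[self.mito_flat])
            has = np.zeros(self.n_units, dtype=bool)
            has[self.mito_unit] = True
            means = np.where(has, peak, means)
        return means

    # -- production ---------------------------------------------------------
    def production_factors(self, states: UnitStates | None) -> np.ndarray:
        if states is None:
            return np.ones(self.n_units)
        return np.where(states.status == DEAD, 0.0,
                        np.where(states.status == STRESSED, self._s_factor, 1.0))

    def production_map(self, states: UnitStates | None = None) -> np.ndarray:
        rp = np.zeros(self.model.grid_shape)
        self.apply_production(rp, states)
        return rp

    def apply_production(self, rp: np.ndarray, states: UnitStates | None) -> None:
        fac = self.production_factors(states)
        rp.ravel()[self.mito_flat] = self.mito_base * fac[self.mito_unit]


def build_units(model: geo.NerveModel, params: BiochemParams) -> Units:
    return Units(model, params)


# ---------------------------------------------------------------------------
# state transitions
# ---------------------------------------------------------------------------

def update_states(means: np.ndarray, states: UnitStates,
                  params: BiochemParams, dt: float, t: float,
                  events: list[Event] | None = None) -> bool:
    """Apply one state-machine update after ``dt`` seconds of exposure.

    ``means`` holds each unit's representative concentration (nM).  Returns
    True if any unit changed state.  Order of evaluation per unit: death by
    concentration, then recovery (S with c below the stress threshold, clock
    reset), then the stress dwell timer, then entry into S.
    """
    st, ck = states.status, states.clock
    alive = st != DEAD
    changed = False

    def _fire(mask, new, trigger):
        nonlocal changed
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return
        changed = True
        if events is not None:
            for u in idx:
                events.append(Event(t, int(u), STATUS_NAMES[int(st[u])],
                                    STATUS_NAMES[new], trigger))
        st[idx] = new
        if new != STRESSED:
            ck[idx] = 0.0

    _fire(alive & (means >= params.death_threshold_nM), DEAD,
          "death_threshold")
    alive = st != DEAD
    in_s = alive & (st == STRESSED)
    if params.allow_recovery:
        _fire(in_s & (means < params.stress_threshold_nM), HEALTHY,
              "threshold")
        in_s = (st == STRESSED)
    ck[in_s] += dt
    _fire(in_s & (ck >= params.stress_dwell_s), DEAD, "timer")
    _fire((st == HEALTHY) & (means >= params.stress_threshold_nM), STRESSED,
          "threshold")
    return changed


# ---------------------------------------------------------------------------
# simulation loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    model: geo.NerveModel
    params: BiochemParams
    field: sv.ConcentrationField
    states: UnitStates
    units: Units
    t_bio: float
    converged: bool
    events: list[Event]

    def dead_axon_mask(self) -> np.ndarray:
        """Boolean per axon: True if any of its segments died."""
        dead = np.zeros(self.model.n_axons, dtype=bool)
        seg_dead = self.states.status[:self.units.n_segments] == DEAD
        np.logical_or.at(dead, self.units.axon_of[:self.units.n_segments],
                         seg_dead)
        return dead

    @property
    def survival_fraction(self) -> float:
        n = self.model.n_axons
        return 1.0 - self.dead_axon_mask().sum() / n if n else 1.0

    def events_frame(self):
        import pandas as pd
        return pd.DataFrame([e.__dict__ for e in self.events],
                            columns=["t", "unit", "old", "new", "trigger"])


def run_simulation(model: geo.NerveModel, params: BiochemParams,
                   species: str = "h2o2", t_max: float = 10.0,
                   tol: float = 1e-4, cadence: int = 10,
                   dt: float | None = None, freeze_states: bool = False,
                   fast_forward_timers: bool = True,
                   record_events: bool = True) -> SimulationResult:
    """Couple the reaction-diffusion solver to the degeneration state machine.

    Alternates ``cadence`` explicit solver steps with one state update.  The
    run terminates when the field is steady (max relative change per second
    below ``tol``) and no further transitions are possible, or at ``t_max``
    biological seconds.  When the field is steady but stressed units are
    still accumulating dwell time, the loop jumps straight to the next timer
    expiry instead of integrating through the wait (``fast_forward_timers``),
    which is exact because a steady field keeps unit concentrations constant.
    """
    units = build_units(model, params)
    dxx, dzz = sv.diffusion_maps(model, params)
    rs = sv.scavenging_map(model, params)
    states = UnitStates.healthy(units.n_units)
    rp = units.production_map(None if freeze_states else states)
    coeffs = sv.CoefficientMaps(dxx=dxx, dzz=dzz, rp=rp, rs=rs,
                                res_xy=model.res_xy, res_z=model.res_z)
    if dt is None:
        dt = sv.stability_dt(coeffs)
    field = sv.ConcentrationField.uniform(model.grid_shape, params.c0_nM,
                                          species=species)
    events: list[Event] = []
    converged = False
    while field.t < t_max:
        n = max(1, min(cadence, int(round((t_max - field.t) / dt))))
        prev = field.values
        field = sv.run_steps(field, coeffs, dt, n)
        scale = max(float(field.values.max()), 1e-12)
        rate = float(np.abs(field.values - prev).max()) / (n * dt * scale)
        if freeze_states:
            if rate < tol:
                converged = True
                break
            continue
        means = units.unit_means(field.values)
        changed = update_states(means, states, params, n * dt, field.t,
                                events if record_events else None)
        if changed:
            units.apply_production(coeffs.rp, states)
            continue
        if rate >= tol:
            continue
        in_s = states.status == STRESSED
        if not in_s.any():
            converged = True
            break
        if not fast_forward_timers:
            continue
        # steady field, no transitions: jump to the next dwell expiry
        dt_skip = float((params.stress_dwell_s - states.clock[in_s]).min())
        dt_skip = max(dt_skip, 0.0) + 1e-12
        if field.t + dt_skip > t_max:
            field.t = t_max
            break
        field.t += dt_skip
        if update_states(means, states, params, dt_skip, field.t,
                         events if record_events else None):
            units.apply_production(coeffs.rp, states)
    return SimulationResult(model=model, params=params, field=field,
                            states=states, units=units, t_bio=field.t,
                            converged=converged, events=events)


def simulate(config) -> SimulationResult:
    """Run a full simulation from a :class:`~rosnerve.config.SimulationConfig`."""
    from . import config as cfgmod
    model = cfgmod.build_model(config)
    params = cfgmod.to_biochem_params(config)
    run = config.run
    return run_simulation(model, params, species=run.species,
                          t_max=run.t_max_s, tol=run.tol, cadence=run.cadence,
                          fast_forward_timers=run.fast_forward_timers)


def steady_field(model: geo.NerveModel, params: BiochemParams,
                 species: str = "h2o2") -> sv.ConcentrationField:
    """Steady concentration field with every unit held healthy.

    Uses the direct linear steady-state solve; the time-stepping loop is the
    reference for runs where states evolve.
    """
    units = build_units(model, params)
    dxx, dzz = sv.diffusion_maps(model, params)
    coeffs = sv.CoefficientMaps(dxx=dxx, dzz=dzz,
                                rp=units.production_map(None),
                                rs=sv.scavenging_map(model, params),
                                res_xy=model.res_xy, res_z=model.res_z)
    field = sv.solve_steady_state(coeffs, c0_nM=params.c0_nM)
    field.species = species
    return field


def calibrate_production(model: geo.NerveModel, params: BiochemParams,
                         target_mean_nM: float, species: str = "h2o2",
                         over: str = "axon_interior") -> tuple[BiochemParams, float]:
    """Solve for the production magnitude giving a target mean steady level.

    Runs one frozen-state simulation to steady state, measures the mean
    concentration over ``over`` voxels ("axon_interior", "extra_axonal" or
    "all") and rescales the active production constant (``rp_h`` for
    RP_SAME, ``alpha`` for RP_FCONST, plus the glial rate if set).  The
    steady field is linear in the production magnitudes, so one run
    suffices.  Returns the rescaled parameters and the scale factor.
    """
    field = steady_field(model, params)
    if over == "axon_interior":
        mask = model.labels == geo.AXON_INTERIOR
    elif over == "extra_axonal":
        mask = model.labels == geo.EXTRA_AXONAL
    elif over == "all":
        mask = np.ones(model.grid_shape, dtype=bool)
    else:
        raise ValueError(f"unknown averaging domain {over!r}")
    measured = float(field.values[mask].mean())
    if measured <= 0:
        raise ValueError("model produces no ROS; cannot calibrate")
    scale = target_mean_nM / measured
    new = replace(params, rp_h=params.rp_h * scale, alpha=params.alpha * scale,
                  glia_rp_h=(params.glia_rp_h * scale
                             if params.glia_rp_h is not None else None))
    return new, scale
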