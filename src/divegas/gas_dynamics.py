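"""Core simulator: lung, blood and tissue gas tensions over a depth profile.

Model
-----
Gas exchanges along the circulatory loop

    lung -> arterial blood -> {brain, fat/bone, central, muscle} -> mixed
    venous blood -> lung,

driven by partial-pressure (tension) gradients.  Each 1 Hz step moves a
small blood "package" (cardiac output x dt) around the loop:

1. the package leaves the venous pool at the mixed-venous tension;
2. at the lung, the unshunted fraction equilibrates with the faveolar
   gas (the shunted fraction passes through unchanged), debiting or
   crediting the lung gas store;
3. the package mixes into the arterial pool (33% of blood volume),
   whose tension feeds the tissues;
4. each compartment receives its flow share and its tension relaxes
   toward arterial with the perfusion-limited rate k = Q_i*S_b/(V_i*S_i)
   (analytic exponential within the step); O2 is consumed and CO2
   produced at the phase metabolic rate, drawing on dissolved and (in
   muscle) myoglobin-bound stores;
5. the compartment effluents merge into the venous pool (67% of blood).

The *arterial* tension - what an arterial blood sample reads - is the
lung effluent, (1 - shunt) * P_faveolar + shunt * P_venous per gas (at
the surface, breathing pins it to the surface constants); the *mixed
venous* tension - the quantity end-dive metrics score - is the
instantaneous flow-weighted confluence of the compartment effluents
(step 5), exactly as a pulmonary-artery sample would read it.  The
arterial and venous blood volumes (33%/67%) behind these sampling
points are capacitance reservoirs in the transport chain; their
(slower) tensions are recorded separately as ``*_arterial_pool`` /
``*_venous_pool`` and carry the blood's share of the gas inventory.

Every millilitre (STPD) of gas removed from one store is credited to
another, so total N2 is conserved exactly during submerged (sealed)
phases.  At the surface the system is open: breathing snaps the lung
and arterial blood to the fixed surface composition (N2/O2/CO2/H2O =
0.741/0.164/0.033/0.062 ATA) the instant depth reads 0, while tissue
recovery proceeds by the same perfusion equations at surface cardiac
output and metabolic rate.

O2 is carried by hemoglobin (Hill curve, h = 2.7) plus a dissolved
term; CO2 uses a single effective solubility; N2 is purely dissolved.
While the faveoli are collapsed (VfA = 0) the pulmonary shunt is 1 and
the lung store is frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lung_mechanics as lm
from .dive_records import DepthSeries
from .parameters import COMPARTMENTS, GasConstants, SpeciesParams, TurtleConfig

__all__ = [
    "GASES",
    "BodyGasState",
    "SimulationResult",
    "Simulator",
    "hill_saturation",
    "blood_o2_content",
    "blood_o2_tension",
    "surface_steady_state",
    "step",
    "simulate",
]

GASES = ("n2", "o2", "co2")

# compartment indices (order matches parameters.COMPARTMENTS)
_BRAIN, _FAT, _CENTRAL, _MUSCLE = range(4)


def hill_saturation(po2, p50: float, h: float = 2.7):
    """Fractional hemoglobin O2 saturation: PO2^h / (P50^h + PO2^h)."""
    po2 = np.asarray(po2, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("PO2 must be >= 0")
    ph = po2 ** h
    s = ph / (p50 ** h + ph)
    return s if s.ndim else float(s)


def blood_o2_content(po2, species: SpeciesParams, gas: GasConstants = GasConstants()):
    """Blood O2 content, ml O2 per ml blood: Hb-bound (Hill) + dissolved."""
    sat = hill_saturation(po2, species.p50_ata, species.hill_h)
    c = gas.hb_o2_capacity * species.hb_g_per_ml * sat + gas.sol_o2 * np.asarray(po2, dtype=float)
    return c if np.ndim(c) else float(c)


def blood_o2_tension(content, species: SpeciesParams, gas: GasConstants = GasConstants()):
    """Invert :func:`blood_o2_content` (vectorized, Newton-polished)."""
    c = np.atleast_1d(np.asarray(content, dtype=float))
    cap = gas.hb_o2_capacity * species.hb_g_per_ml
    p50, h = species.p50_ata, species.hill_h
    # bracketing grid seed, then Newton to machine precision
    grid_p = np.linspace(0.0, 30.0, 4096)
    grid_c = cap * grid_p ** h / (p50 ** h + grid_p ** h) + gas.sol_o2 * grid_p
    p = np.interp(np.clip(c, 0.0, grid_c[-1]), grid_c, grid_p)
    for _ in range(6):
        ph = p ** h
        f = cap * ph / (p50 ** h + ph) + gas.sol_o2 * p - c
        with np.errstate(divide="ignore", invalid="ignore"):
            dsdp = np.where(p > 0, cap * h * p ** (h - 1) * p50 ** h / (p50 ** h + ph) ** 2, 0.0)
        step = f / (dsdp + gas.sol_o2)
        p = np.maximum(0.0, p - step)
    return p if np.ndim(content) else float(p[0])


@dataclass
class BodyGasState:
    """Full instantaneous gas state.

    ``lung_store`` holds ml STPD of N2/O2/CO2 in the lung gas;
    ``p_tissue`` is a (4, 3) array of compartment tensions (ATA) in
    compartment order (brain, fat_bone, central, muscle) x gas order
    (N2, O2, CO2); ``o2_store_tissue`` carries the compartment O2
    stores (dissolved + myoglobin-bound in muscle, ml STPD), which are
    authoritative for the O2 tensions; ``c_arterial``/``c_venous`` are
    blood-pool gas contents per ml blood (tension x solubility for
    N2/CO2, the Hill content curve for O2).
    """

    lung_store: np.ndarray
    p_tissue: np.ndarray
    o2_store_tissue: np.ndarray
    c_arterial: np.ndarray
    c_venous: np.ndarray

    def copy(self) -> "BodyGasState":
        return BodyGasState(self.lung_store.copy(), self.p_tissue.copy(),
                            self.o2_store_tissue.copy(), self.c_arterial.copy(),
                            self.c_venous.copy())


@dataclass
class SimulationResult:
    """1 Hz state trajectory plus run bookkeeping.

    ``frame`` holds one row per series sample; O2 blood-pool columns are
    tensions (converted from the simulated contents).  ``events`` lists
    (time_s, label) store-exhaustion events (first occurrence per
    store).
    """

    frame: pd.DataFrame
    events: list = field(default_factory=list)
    config: TurtleConfig | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def n2_inventory(self) -> pd.Series:
        """Total N2 (ml STPD) in lung gas + every dissolved store per sample."""
        cfg = self.config
        gas = cfg.gas
        f = self.frame
        vols = cfg.compartment_volumes_ml()
        total = f["lung_n2_ml"].copy()
        for name in COMPARTMENTS:
            total += vols[name] * gas.n2_solubility(name) * f[f"pn2_{name}"]
        v_blood = cfg.blood_volume_ml()
        total += v_blood * cfg.body.arterial_fraction * gas.sol_n2_blood * f["pn2_arterial_pool"]
        total += v_blood * cfg.body.venous_fraction * gas.sol_n2_blood * f["pn2_venous_pool"]
        return total

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="time_s")


class Simulator:
    """Precomputes per-phase coefficients and advances the state at 1 Hz."""

    def __init__(self, config: TurtleConfig):
        self.config = config
        gas, sp = config.gas, config.species
        self.geometry = lm.LungGeometry.from_config(config)
        self._vd0 = self.geometry.vd0_ml
        self._vfa_max = self.geometry.vfa_max_ml
        shape = config.lung_shape
        self._fmin = shape.vd_min_fraction
        self._kp = -shape.kp
        self._n_exp = shape.n
        self._gamma = shape.shunt_gamma
        self._s0 = shape.shunt_s0
        self._ph2o = gas.ph2o
        self._surface_partials = (gas.surface_pn2, gas.surface_po2, gas.surface_pco2)
        self._lung_fill = [config.dlv_fraction * config.tlc_total_ml * p
                           for p in self._surface_partials]

        vols = config.compartment_volumes_ml()
        self._vol = [vols[c] for c in COMPARTMENTS]
        self._sol_n2 = [gas.n2_solubility(c) for c in COMPARTMENTS]
        self._cap_n2 = [v * s for v, s in zip(self._vol, self._sol_n2)]
        self._cap_co2 = [v * gas.sol_co2 for v in self._vol]
        self._cap_o2_dis = [v * gas.sol_o2 for v in self._vol]
        muscle_mass = config.body.muscle * config.body_mass
        self._mb_capacity = gas.mb_o2_capacity * sp.mb_g_per_kg * muscle_mass
        self._mb_p50 = gas.mb_p50_ata

        self._s_b_n2 = gas.sol_n2_blood
        self._s_b_co2 = gas.sol_co2
        self._hb_cap = gas.hb_o2_capacity * sp.hb_g_per_ml
        self._p50h = sp.p50_ata ** sp.hill_h
        self._h = sp.hill_h
        self._sol_o2 = gas.sol_o2

        v_blood = config.blood_volume_ml()
        self._v_art = config.body.arterial_fraction * v_blood
        self._v_ven = config.body.venous_fraction * v_blood

        self.dt = config.dt
        self.substeps = max(1, int(round(1.0 / config.dt)))
        self._phase = {}
        circ, met = config.circulation, config.metabolism
        for phase, sq, mr in (("surface", circ.surface_sqtot, met.surface_mr),
                              ("dive", circ.dive_sqtot,
                               met.surface_mr * met.dive_mr_fraction)):
            split = circ.surface_split if phase == "surface" else circ.dive_split
            q = sq * config.body_mass / 60.0          # ml blood / s
            dv = q * self.dt
            dvi = [split[c] * dv for c in COMPARTMENTS]
            g_n2 = [1.0 - math.exp(-(split[c] * q) * self._s_b_n2 * self.dt
                                   / (vols[c] * gas.n2_solubility(c)))
                    for c in COMPARTMENTS]
            # CO2 blood and tissue share one effective solubility
            g_co2 = [1.0 - math.exp(-(split[c] * q) * self.dt / vols[c])
                     for c in COMPARTMENTS]
            mr_dt = [mr / 60.0 * config.body.fractions()[c] * config.body_mass * self.dt
                     for c in COMPARTMENTS]
            self._phase[phase] = (dv, dvi, g_n2, g_co2, mr_dt)
        self._rq = met.rq

    # -- O2 carriage helpers (scalar, hot path) ------------------------------
    def _c_blood_o2(self, p: float) -> float:
        ph = p ** self._h if p > 0.0 else 0.0
        return self._hb_cap * ph / (self._p50h + ph) + self._sol_o2 * p

    def _muscle_o2_tension(self, store: float) -> float:
        # invert  store = Vm*So2*P + MbCap*P/(P + p50mb)   (quadratic in P)
        a = self._cap_o2_dis[_MUSCLE]
        b = a * self._mb_p50 + self._mb_capacity - store
        disc = b * b + 4.0 * a * store * self._mb_p50
        return (-b + math.sqrt(disc)) / (2.0 * a)

    def _muscle_o2_store(self, p: float) -> float:
        return self._cap_o2_dis[_MUSCLE] * p + self._mb_capacity * p / (p + self._mb_p50)

    def o2_tissue_tension(self, i: int, store: float) -> float:
        if i == _MUSCLE:
            return self._muscle_o2_tension(store)
        return store / self._cap_o2_dis[i]

    def o2_tissue_store(self, i: int, p: float) -> float:
        if i == _MUSCLE:
            return self._muscle_o2_store(p)
        return self._cap_o2_dis[i] * p

    # -- initial condition ----------------------------------------------------
    def surface_state(self) -> BodyGasState:
        """Exact fixed point of the discrete step map at the surface.

        N2 sits at the surface tension everywhere.  For O2 each
        compartment settles where per-step delivery balances demand;
        compartments whose demand exceeds the transport capacity of
        their blood flow are pinned at PO2 = 0 (delivery-limited).  CO2
        settles where washout balances production (scaled to the O2
        actually consumed).
        """
        gas = self.config.gas
        pn2, po2, pco2 = self._surface_partials
        dv, dvi, g_n2, g_co2, mr_dt = self._phase["surface"]
        c_a_o2 = self._c_blood_o2(po2)
        p_tis = np.zeros((4, 3))
        o2_store = np.zeros(4)
        p_tis[:, 0] = pn2
        cons_actual = np.zeros(4)
        for i in range(4):
            target = c_a_o2 - mr_dt[i] / dvi[i]
            if target <= 0.0:
                p_star, cons = 0.0, dvi[i] * c_a_o2
            else:
                p_star = blood_o2_tension(target, self.config.species, gas)
                cons = mr_dt[i]
            cons_actual[i] = cons
            p_tis[i, 1] = p_star
            o2_store[i] = self.o2_tissue_store(i, p_star)
            p_tis[i, 2] = pco2 + self._rq * cons / (g_co2[i] * self._cap_co2[i])
        c_art = np.array([self._s_b_n2 * pn2, c_a_o2, self._s_b_co2 * pco2])
        # venous pool fixed point: flow-weighted compartment effluents
        split_w = [dvi[i] / dv for i in range(4)]
        c_ven = np.array([
            self._s_b_n2 * pn2,
            sum(w * self._c_blood_o2(p_tis[i, 1]) for i, w in enumerate(split_w)),
            self._s_b_co2 * pco2
            + self._rq * sum(cons_actual[i] for i in range(4)) / dv,
        ])
        return BodyGasState(
            lung_store=np.array(self._lung_fill),
            p_tissue=p_tis,
            o2_store_tissue=o2_store,
            c_arterial=c_art,
            c_venous=c_ven,
        )

    # -- main loop ------------------------------------------------------------
    def run(self, depths: np.ndarray, state: BodyGasState | None = None,
            record: bool = True) -> SimulationResult:
        cfg = self.config
        if state is None:
            state = self.surface_state()
        else:
            state = state.copy()

        n = depths.size
        ncol = 34
        out = np.empty((n, ncol)) if record else None

        # unpack state into locals (hot loop)
        n_n2, n_o2, n_co2 = (float(x) for x in state.lung_store)
        p_t = [[float(state.p_tissue[i, g]) for g in range(3)] for i in range(4)]
        o2_s = [float(x) for x in state.o2_store_tissue]
        ca = [float(x) for x in state.c_arterial]
        cv = [float(x) for x in state.c_venous]

        vols, cap_n2, cap_co2 = self._vol, self._cap_n2, self._cap_co2
        s_b_n2, s_b_co2 = self._s_b_n2, self._s_b_co2
        ph2o = self._ph2o
        v0 = self.config.dlv_fraction * self.config.tlc_total_ml
        fav_share0 = (v0 - self._vd0) / v0
        sp_n2, sp_o2, sp_co2 = self._surface_partials
        fill_n2, fill_o2, fill_co2 = self._lung_fill
        v_art, v_ven = self._v_art, self._v_ven
        vfa_max, vd0 = self._vfa_max, self._vd0
        fmin, kp_abs, n_exp = self._fmin, self._kp, self._n_exp
        gamma, s0 = self._gamma, self._s0
        rq = self._rq
        c_blood_o2 = self._c_blood_o2
        substeps = self.substeps
        events: list = []
        exhausted = [False] * 4
        lung_o2_out = False
        ca_o2_surface = self._c_blood_o2(sp_o2)

        for t in range(n):
            depth = float(depths[t])
            diving = depth > 0.0
            p_amb = 1.0 + depth / 10.0
            dv, dvi, g_n2, g_co2, mr_dt = self._phase["dive" if diving else "surface"]

            for _ in range(substeps):
                if diving:
                    dry = n_n2 + n_o2 + n_co2
                    v_tot = dry / (p_amb - ph2o)
                    vd_struct = vd0 * (fmin + (1.0 - fmin)
                                       * (1.0 + (p_amb - 1.0) / kp_abs) ** -n_exp)
                    vd = vd_struct if vd_struct < v_tot else v_tot
                    vfa = v_tot - vd
                    if v_tot > 0.0:
                        r = vfa / (fav_share0 * v_tot)
                        if r > 1.0:
                            r = 1.0
                        shunt = s0 + (1.0 - s0) * (1.0 - r) ** gamma
                    else:
                        shunt = 1.0
                    if dry > 0.0:
                        p_fav_n2 = (p_amb - ph2o) * n_n2 / dry
                        p_fav_o2 = (p_amb - ph2o) * n_o2 / dry
                        p_fav_co2 = (p_amb - ph2o) * n_co2 / dry
                    else:
                        p_fav_n2 = p_fav_o2 = p_fav_co2 = 0.0
                    # package: venous -> lung -> arterial pool
                    w = 1.0 - shunt
                    c_in_n2, c_in_o2, c_in_co2 = cv[0], cv[1], cv[2]
                    if w > 0.0 and vfa > 0.0:
                        debit = dv * w * (s_b_n2 * p_fav_n2 - c_in_n2)
                        if debit > n_n2:
                            debit = n_n2
                        n_n2 -= debit
                        c_in_n2 += debit / dv
                        debit = dv * w * (c_blood_o2(p_fav_o2) - c_in_o2)
                        if debit > n_o2:
                            debit = n_o2
                            if not lung_o2_out:
                                events.append((t, "lung_o2_exhausted"))
                                lung_o2_out = True
                        n_o2 -= debit
                        c_in_o2 += debit / dv
                        debit = dv * w * (s_b_co2 * p_fav_co2 - c_in_co2)
                        if debit > n_co2:
                            debit = n_co2
                        n_co2 -= debit
                        c_in_co2 += debit / dv
                    ca[0] = (v_art * ca[0] + dv * c_in_n2) / (v_art + dv)
                    ca[1] = (v_art * ca[1] + dv * c_in_o2) / (v_art + dv)
                    ca[2] = (v_art * ca[2] + dv * c_in_co2) / (v_art + dv)
                else:
                    # breathing: lung and arterial snap to surface composition
                    n_n2, n_o2, n_co2 = fill_n2, fill_o2, fill_co2
                    p_fav_n2, p_fav_o2, p_fav_co2 = sp_n2, sp_o2, sp_co2
                    v_tot = v0
                    vd = vd0 if vd0 < v_tot else v_tot
                    vfa = v_tot - vd
                    shunt = s0          # full inflation while breathing
                    c_in_n2 = s_b_n2 * sp_n2
                    c_in_o2 = ca_o2_surface
                    c_in_co2 = s_b_co2 * sp_co2
                    ca[0] = c_in_n2
                    ca[1] = c_in_o2
                    ca[2] = c_in_co2

                pa_n2 = ca[0] / s_b_n2
                pa_co2 = ca[2] / s_b_co2
                c_a_o2 = ca[1]
                in_n2 = in_o2 = in_co2 = 0.0
                for i in range(4):
                    dvii = dvi[i]
                    row = p_t[i]
                    # N2
                    dp = (pa_n2 - row[0]) * g_n2[i]
                    row[0] += dp
                    in_n2 += dvii * s_b_n2 * pa_n2 - cap_n2[i] * dp
                    # CO2 exchange
                    dp = (pa_co2 - row[2]) * g_co2[i]
                    row[2] += dp
                    in_co2 += dvii * s_b_co2 * pa_co2 - cap_co2[i] * dp
                    # O2: package equilibrates to tissue tension
                    gain = dvii * (c_a_o2 - c_blood_o2(row[1]))
                    store = o2_s[i]
                    if gain < -store:
                        gain = -store
                    store += gain
                    cons = mr_dt[i]
                    if cons > store:
                        cons = store
                        if not exhausted[i]:
                            events.append((t, f"o2_exhausted_{COMPARTMENTS[i]}"))
                            exhausted[i] = True
                    store -= cons
                    o2_s[i] = store
                    row[1] = self.o2_tissue_tension(i, store)
                    in_o2 += dvii * c_a_o2 - gain
                    # CO2 production follows actual O2 consumption
                    row[2] += rq * cons / cap_co2[i]
                # instantaneous mixed venous: the confluence entering the pool
                mv_n2 = in_n2 / dv
                mv_o2 = in_o2 / dv
                mv_co2 = in_co2 / dv
                cv[0] = ((v_ven - dv) * cv[0] + in_n2) / v_ven
                cv[1] = ((v_ven - dv) * cv[1] + in_o2) / v_ven
                cv[2] = ((v_ven - dv) * cv[2] + in_co2) / v_ven

            if record:
                out[t] = (depth, p_amb, vfa, shunt,
                          p_fav_n2, p_fav_o2, p_fav_co2,
                          n_n2, n_o2, n_co2,
                          c_in_n2 / s_b_n2, c_in_o2, c_in_co2 / s_b_co2,
                          pa_n2, ca[1], pa_co2,
                          mv_n2 / s_b_n2, mv_o2, mv_co2 / s_b_co2,
                          cv[0] / s_b_n2, cv[1], cv[2] / s_b_co2,
                          p_t[0][0], p_t[1][0], p_t[2][0], p_t[3][0],
                          p_t[0][1], p_t[1][1], p_t[2][1], p_t[3][1],
                          p_t[0][2], p_t[1][2], p_t[2][2], p_t[3][2])

        state.lung_store[:] = (n_n2, n_o2, n_co2)
        for i in range(4):
            state.p_tissue[i] = p_t[i]
        state.o2_store_tissue[:] = o2_s
        state.c_arterial[:] = ca
        state.c_venous[:] = cv
        self.final_state = state

        if not record:
            return SimulationResult(frame=pd.DataFrame(), events=events, config=self.config)
        cols = (["depth_m", "p_amb", "vfa_ml", "shunt",
                 "pn2_fav", "po2_fav", "pco2_fav",
                 "lung_n2_ml", "lung_o2_ml", "lung_co2_ml",
                 "pn2_arterial", "po2_arterial", "pco2_arterial",
                 "pn2_arterial_pool", "po2_arterial_pool", "pco2_arterial_pool",
                 "pn2_venous", "po2_venous", "pco2_venous",
                 "pn2_venous_pool", "po2_venous_pool", "pco2_venous_pool"]
                + [f"pn2_{c}" for c in COMPARTMENTS]
                + [f"po2_{c}" for c in COMPARTMENTS]
                + [f"pco2_{c}" for c in COMPARTMENTS])
        frame = pd.DataFrame(out, columns=cols)
        # blood O2 was carried as content; convert to tension
        for col in ("po2_arterial", "po2_arterial_pool",
                    "po2_venous", "po2_venous_pool"):
            frame[col] = blood_o2_tension(frame[col].to_numpy(),
                                          self.config.species, self.config.gas)
        return SimulationResult(frame=frame, events=events, config=self.config)


def surface_steady_state(config: TurtleConfig) -> BodyGasState:
    """Surface-equilibrium state (exact fixed point of the step map)."""
    return Simulator(config).surface_state()


def step(state: BodyGasState, depth: float, dt: float, config: TurtleConfig) -> BodyGasState:
    """Advance one state by ``dt`` seconds at constant ``depth``.

    Convenience wrapper over :class:`Simulator` for single-step use; for
    whole profiles use :func:`simulate`, which amortizes setup.
    """
    if dt != config.dt:
        from dataclasses import replace
        config = replace(config, dt=dt)
    sim = Simulator(config)
    sim.substeps = 1          # exactly one dt-sized update
    sim.run(np.array([depth]), state=state, record=False)
    return sim.final_state


def simulate(series: DepthSeries, config: TurtleConfig,
             initial_state: BodyGasState | None = None,
             record: bool = True) -> SimulationResult:
    """Simulate a regularized 1 Hz depth series from surface equilibrium."""
    sim = Simulator(config)
    return sim.run(np.asarray(series.depths, dtype=float),
                   state=initial_state, record=record)
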