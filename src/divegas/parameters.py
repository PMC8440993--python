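"""Physiological parameters for the sea-turtle gas-dynamics model.

Everything the simulator needs to know about an animal lives in a
:class:`TurtleConfig`: species physiology (lung capacity, O2 carriage),
body composition (the four perfused compartments plus blood), the
circulation schedule (total cardiac output and its distribution at the
surface vs. while diving) and the metabolic schedule.  Constants are
shipped in ``data/species.yaml`` and mirrored here; every value is
overridable, and the model variants used in the cardiac-output and
body-condition experiments are produced by :func:`make_variant`.

Unit conventions
----------------
Pressures/tensions are atmospheres absolute (ATA).  Gas amounts are ml
STPD.  Solubilities are Ostwald-style, ml gas per ml tissue per ATA.
Cardiac output is mass-specific, ml blood min^-1 kg^-1 body mass.
Metabolic rate is ml O2 min^-1 kg^-1 of metabolizing tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "Species",
    "COMPARTMENTS",
    "SpeciesParams",
    "BodyComposition",
    "CirculationPlan",
    "MetabolicPlan",
    "GasConstants",
    "LungShape",
    "TurtleConfig",
    "VARIANTS",
    "species_params",
    "body_composition",
    "surface_sqtot",
    "make_config",
    "make_variant",
]

#: Order of the four perfused compartments everywhere in the package.
COMPARTMENTS = ("brain", "fat_bone", "central", "muscle")

MMHG_PER_ATA = 760.0


class Species(str, Enum):
    LOGGERHEAD = "loggerhead"
    LEATHERBACK = "leatherback"
    GREEN = "green"


def _load_species_table() -> dict:
    with resources.files("divegas.data").joinpath("species.yaml").open() as fh:
        return yaml.safe_load(fh)


_SPECIES_TABLE = _load_species_table()


@dataclass(frozen=True)
class SpeciesParams:
    """Species-level physiology (lung size and blood/muscle O2 carriage)."""

    species: Species
    tlc_ml_per_kg: float          # mass-specific total lung capacity
    vd_fraction: float            # airway dead space as a fraction of TLC
    o2_store_lung: float          # reference O2 stores, ml/kg body mass
    o2_store_blood: float
    o2_store_muscle: float
    hb_g_per_ml: float            # hemoglobin, g per ml whole blood
    pcv_pct: float                # packed cell volume, %
    mb_g_per_kg: float            # myoglobin, g per kg muscle
    p50_mmhg: float               # Hb half-saturation PO2
    hill_h: float = 2.7

    @property
    def p50_ata(self) -> float:
        return self.p50_mmhg / MMHG_PER_ATA

    def __post_init__(self) -> None:
        for name in ("tlc_ml_per_kg", "hb_g_per_ml", "pcv_pct", "mb_g_per_kg",
                     "p50_mmhg", "hill_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.vd_fraction < 1.0:
            raise ValueError("vd_fraction must lie in (0, 1)")


def species_params(species: Species | str, body_mass: float) -> SpeciesParams:
    """Resolve the physiology table for ``species`` at ``body_mass`` kg.

    The loggerhead lung scales allometrically, TLC = 113.6 * M^0.923 ml
    (i.e. 113.6 * M^0.923 / M per kg); the other two species use
    constant mass-specific capacities.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    species = Species(species)
    try:
        row = _SPECIES_TABLE["species"][species.value]
    except KeyError:  # pragma: no cover - Species enum guards this
        raise ValueError(f"unknown species {species!r}") from None
    if "tlc_allometric" in row:
        allo = row["tlc_allometric"]
        tlc = allo["coefficient"] * body_mass ** allo["exponent"] / body_mass
    else:
        tlc = float(row["tlc_ml_per_kg"])
    return SpeciesParams(
        species=species,
        tlc_ml_per_kg=tlc,
        vd_fraction=float(_SPECIES_TABLE["dead_space_fraction_of_tlc"]),
        o2_store_lung=float(row["o2_store_lung"]),
        o2_store_blood=float(row["o2_store_blood"]),
        o2_store_muscle=float(row["o2_store_muscle"]),
        hb_g_per_ml=float(row["hb_g_per_ml"]),
        pcv_pct=float(row["pcv_pct"]),
        mb_g_per_kg=float(row["mb_g_per_kg"]),
        p50_mmhg=float(row["p50_mmhg"]),
        hill_h=float(_SPECIES_TABLE["hill_coefficient"]),
    )


@dataclass(frozen=True)
class BodyComposition:
    """Compartment sizes as fractions of body mass.

    Muscle is always the residual compartment so that the five fractions
    sum to exactly 1 (the emaciated table row as printed does not close;
    the residual rule restores it).
    """

    condition: str
    blood: float
    brain: float
    fat_bone: float
    central: float
    muscle: float
    arterial_fraction: float = 0.33   # arterial share of total blood volume

    @property
    def venous_fraction(self) -> float:
        return 1.0 - self.arterial_fraction

    def fractions(self) -> dict[str, float]:
        """Mass fractions of the four perfused compartments."""
        return {c: getattr(self, c) for c in COMPARTMENTS}

    def __post_init__(self) -> None:
        total = self.blood + self.brain + self.fat_bone + self.central + self.muscle
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        if not 0.0 < self.arterial_fraction < 1.0:
            raise ValueError("arterial_fraction must lie in (0, 1)")


# Non-muscle percentages per condition; muscle is the remainder.
_BODY_TABLE = {
    "control": {"blood": 7.0, "brain": 0.06, "fat_bone": 30.0, "central": 9.0},
    "obese": {"blood": 6.0, "brain": 0.054, "fat_bone": 40.0, "central": 8.0},
    "emaciated": {"blood": 8.0, "brain": 0.066, "fat_bone": 20.0, "central": 10.0},
}


def body_composition(condition: str = "control") -> BodyComposition:
    """Body-compartment fractions for a nutritional condition."""
    try:
        row = _BODY_TABLE[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {sorted(_BODY_TABLE)}"
        ) from None
    muscle = 100.0 - sum(row.values())
    return BodyComposition(
        condition=condition,
        blood=row["blood"] / 100.0,
        brain=row["brain"] / 100.0,
        fat_bone=row["fat_bone"] / 100.0,
        central=row["central"] / 100.0,
        muscle=muscle / 100.0,
    )


def _check_split(split: Mapping[str, float], name: str) -> dict[str, float]:
    if set(split) != set(COMPARTMENTS):
        raise ValueError(f"{name} must assign a flow fraction to each compartment")
    total = sum(split.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{name} sums to {total}, not 1")
    return dict(split)


@dataclass(frozen=True)
class CirculationPlan:
    """Cardiac output and its distribution at the surface and at depth.

    The control surface output is 7 ml min^-1 kg^-1 (the
    value the allometric relation yields at the 1.2 kg reference animal);
    while diving the total output falls to ``dive_fraction`` of the
    surface value and the distribution shifts almost entirely to the
    central circulation.
    """

    surface_sqtot: float = 7.0           # ml blood min^-1 kg^-1 body
    dive_fraction: float = 0.05          # diving Qtot as a fraction of surface
    surface_split: Mapping[str, float] = field(
        default_factory=lambda: {
            "central": 0.60, "muscle": 0.34, "brain": 0.04, "fat_bone": 0.02,
        })
    dive_split: Mapping[str, float] = field(
        default_factory=lambda: {
            "central": 0.928, "muscle": 0.050, "brain": 0.020, "fat_bone": 0.002,
        })

    def __post_init__(self) -> None:
        if self.surface_sqtot <= 0:
            raise ValueError("surface_sqtot must be positive")
        if not 0.0 < self.dive_fraction <= 1.0:
            raise ValueError("dive_fraction must lie in (0, 1]")
        object.__setattr__(self, "surface_split",
                           _check_split(self.surface_split, "surface_split"))
        object.__setattr__(self, "dive_split",
                           _check_split(self.dive_split, "dive_split"))

    @property
    def dive_sqtot(self) -> float:
        return self.surface_sqtot * self.dive_fraction


@dataclass(frozen=True)
class MetabolicPlan:
    """Whole-animal O2 consumption schedule.

    ``surface_mr`` is the exercising-scale rate used between dives;
    while submerged the rate drops to ``dive_mr_fraction`` of it
    (5% -> 0.21 ml O2 min^-1 kg^-1).  The rate is applied per kg of
    metabolizing compartment tissue; CO2 is produced at ``rq`` times the
    O2 actually consumed.
    """

    surface_mr: float = 4.23             # ml O2 min^-1 kg^-1 tissue
    dive_mr_fraction: float = 0.05
    rq: float = 1.0

    def __post_init__(self) -> None:
        # surface_mr = 0 is allowed (sealed, metabolism-free scenarios)
        if self.surface_mr < 0 or not 0.0 < self.dive_mr_fraction <= 1.0:
            raise ValueError("metabolic plan values out of range")

    @property
    def dive_mr(self) -> float:
        return self.surface_mr * self.dive_mr_fraction


@dataclass(frozen=True)
class GasConstants:
    """Boundary tensions, solubilities and carriage constants.

    The four surface tensions (N2/O2/CO2/H2O) are the breathing
    boundary condition and sum to 1.000 ATA.  Solubilities are
    Ostwald coefficients (ml gas ml^-1 ATA^-1); CO2 is carried with a
    single effective solubility rather than a full dissociation curve.
    """

    surface_pn2: float = 0.741
    surface_po2: float = 0.164
    surface_pco2: float = 0.033
    ph2o: float = 0.062
    sol_n2_blood: float = 0.0144   # also lean tissue
    sol_n2_fat: float = 0.067
    sol_o2: float = 0.0236         # physically dissolved O2, all phases
    sol_co2: float = 0.47          # effective, all phases
    hb_o2_capacity: float = 1.34   # ml O2 per g Hb
    mb_o2_capacity: float = 1.34   # ml O2 per g Mb
    mb_p50_mmhg: float = 2.75      # myoglobin half-saturation PO2

    @property
    def mb_p50_ata(self) -> float:
        return self.mb_p50_mmhg / MMHG_PER_ATA

    @property
    def surface_tension_sum(self) -> float:
        return self.surface_pn2 + self.surface_po2 + self.surface_pco2 + self.ph2o

    def n2_solubility(self, compartment: str) -> float:
        return self.sol_n2_fat if compartment == "fat_bone" else self.sol_n2_blood


@dataclass(frozen=True)
class LungShape:
    """Shape constants of the lung-compression / shunt realization.

    ``a, b, c`` are the cited human-alveolar compliance constants of the
    source compression model, retained for reference; the realization
    here treats the faveolar space as freely compliant (Boyle remainder)
    and puts the structural stiffness in the conducting airways:
    VD(P) = VD0 * (fmin + (1 - fmin) * (1 + (P-1)/|Kp|)^-n), with
    ``vd_min_fraction`` (fmin) the residual incompressible airway
    fraction.  The pulmonary shunt follows a derecruitment picture:
    compressed faveolar units empty completely (rather than all units
    shrinking uniformly), so the shunted fraction is the share of the
    pressure-scaled faveolar gas that the stiff airways have claimed,
    s = s0 + (1 - s0) * (1 - VfA/VfA_ref)^gamma with VfA_ref the
    unimpeded (Boyle-scaled) faveolar volume at the current pressure.
    ``vd_min_fraction`` and ``shunt_gamma`` are calibrated once against
    the published depth-of-collapse behavior (exchange largely open at
    <=30 m, almost none beyond 90 m, for a half-inflated lung).
    """

    a: float = 1.04
    b: float = 0.20
    c: float = 1.21
    kp: float = -6.44
    n: float = 0.74
    vd_min_fraction: float = 0.20
    shunt_gamma: float = 1.0
    shunt_s0: float = 0.0

    def __post_init__(self) -> None:
        if self.kp >= 0:
            raise ValueError("kp is a compliance (volume falls with pressure); must be negative")
        if not 0.0 < self.vd_min_fraction < 1.0:
            raise ValueError("vd_min_fraction must lie in (0, 1)")
        if not 0.0 <= self.shunt_s0 < 1.0:
            raise ValueError("shunt_s0 must lie in [0, 1)")


#: Model variants exercised in the experiments module.
VARIANTS = ("control", "obese", "emaciated",
            "surface_high", "surface_low", "dive_high", "dive_low")


@dataclass(frozen=True)
class TurtleConfig:
    """Complete parameterization of one simulated animal."""

    species: SpeciesParams
    body: BodyComposition
    circulation: CirculationPlan
    metabolism: MetabolicPlan
    gas: GasConstants
    lung_shape: LungShape
    body_mass: float                  # kg
    dlv_fraction: float = 1.0         # diving lung volume as a fraction of TLC
    dt: float = 1.0                   # integrator substep, s
    variant: str = "control"

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")
        if not 0.0 < self.dlv_fraction <= 1.0:
            raise ValueError("dlv_fraction must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    # -- convenience geometry -------------------------------------------------
    @property
    def tlc_total_ml(self) -> float:
        return self.species.tlc_ml_per_kg * self.body_mass

    def compartment_volumes_ml(self) -> dict[str, float]:
        """Compartment volumes in ml, assuming unit tissue density."""
        return {c: f * self.body_mass * 1000.0
                for c, f in self.body.fractions().items()}

    def blood_volume_ml(self) -> float:
        return self.body.blood * self.body_mass * 1000.0


def surface_sqtot(body_mass: float, reference_q: float = 8.4,
                  reference_mass: float = 1.2) -> float:
    """Allometric mass-specific cardiac output, ml blood min^-1 kg^-1.

    sQtot = (Qref / Mref) * (M / Mref)^-0.25: the measured reference
    output (8.4 ml min^-1 at 1.2 kg, i.e. 7 ml min^-1 kg^-1) scaled by
    the usual quarter-power of relative body mass.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    return (reference_q / reference_mass) * (body_mass / reference_mass) ** -0.25


def make_config(species: Species | str, body_mass: float, *,
                condition: str = "control",
                surface_sqtot_value: float | None = None,
                dive_fraction: float = 0.05,
                dlv_fraction: float = 1.0,
                gas: GasConstants | None = None,
                lung_shape: LungShape | None = None,
                metabolism: MetabolicPlan | None = None,
                dt: float = 1.0) -> TurtleConfig:
    """Build a control configuration for one animal.

    ``surface_sqtot_value`` defaults to the experiments' control value of
    7 ml min^-1 kg^-1 (use :func:`surface_sqtot` for the allometric value).
    """
    circulation = CirculationPlan(
        surface_sqtot=7.0 if surface_sqtot_value is None else surface_sqtot_value,
        dive_fraction=dive_fraction,
    )
    return TurtleConfig(
        species=species_params(species, body_mass),
        body=body_composition(condition),
        circulation=circulation,
        metabolism=metabolism or MetabolicPlan(),
        gas=gas or GasConstants(),
        lung_shape=lung_shape or LungShape(),
        body_mass=body_mass,
        dlv_fraction=dlv_fraction,
        dt=dt,
        variant="control" if condition == "control" else condition,
    )


def make_variant(base: TurtleConfig, variant: str) -> TurtleConfig:
    """Derive one experiment variant from a control configuration.

    Exactly one knob changes: the body condition (obese/emaciated), the
    surface cardiac output (10 or 2.5 ml min^-1 kg^-1), or the diving
    fraction of cardiac output (dive_low = 10%, dive_high = 3.3%; the
    low/high labels follow the published naming, which ranks variants by
    heart-rate direction, so ``dive_high`` is the *reduced-flow* variant).
    Compound variants are rejected: ``base`` must be a control config.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if base.variant != "control":
        raise ValueError(
            f"variants must derive from a control configuration, got {base.variant!r}")
    if variant == "control":
        return base
    if variant in ("obese", "emaciated"):
        return replace(base, body=body_composition(variant), variant=variant)
    if variant == "surface_high":
        circ = replace(base.circulation, surface_sqtot=10.0)
    elif variant == "surface_low":
        circ = replace(base.circulation, surface_sqtot=2.5)
    elif variant == "dive_low":
        circ = replace(base.circulation, dive_fraction=0.10)
    else:  # dive_high
        circ = replace(base.circulation, dive_fraction=0.033)
    return replace(base, circulation=circ, variant=variant)
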