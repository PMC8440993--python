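"""Lung compression, faveolar collapse and pulmonary shunt.

The reptilian lung is split into a gas-exchanging faveolar space and a
conducting-airway dead space (trachea + bronchi, 7% of TLC).  Under
hydrostatic pressure the total gas volume follows Boyle's law while the
airways, being stiffer, shrink more slowly toward a residual volume; the
faveolar space holds whatever gas the airways do not.  When the airway
volume exceeds the remaining gas volume the faveoli are empty
(VfA = 0): the lung has collapsed and gas exchange stops entirely.  The
pulmonary shunt - the fraction of cardiac output bypassing gas
exchange - grows smoothly from a baseline at full inflation to 1 at
collapse.

The dead-space and shunt shape constants are calibrated once against
the published collapse behavior for a half-inflated green-turtle lung
(exchange largely open at 30 m, almost none beyond 90 m, collapse just
past 90 m); see :class:`divegas.parameters.LungShape`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import LungShape, TurtleConfig

__all__ = [
    "LungGeometry",
    "ambient_pressure",
    "depth_for_pressure",
    "dead_space_volume",
    "compress",
    "shunt_fraction",
    "faveolar_reference",
    "collapse_pressure",
    "compression_table",
]

#: Metres of seawater per atmosphere of hydrostatic pressure.
M_PER_ATA = 10.0


def ambient_pressure(depth_m):
    """Ambient pressure in ATA at ``depth_m`` metres (1 ATA + 1 per 10 m)."""
    depth_m = np.asarray(depth_m, dtype=float)
    if np.any(depth_m < 0):
        raise ValueError("depth must be >= 0")
    return (1.0 + depth_m / M_PER_ATA) if depth_m.ndim else float(1.0 + depth_m / M_PER_ATA)


def depth_for_pressure(p_ata: float) -> float:
    """Inverse of :func:`ambient_pressure`."""
    if p_ata < 1.0:
        raise ValueError("ambient pressure is at least 1 ATA")
    return (p_ata - 1.0) * M_PER_ATA


@dataclass(frozen=True)
class LungGeometry:
    """Structural lung volumes (ml) for one animal plus shape constants."""

    tlc_total_ml: float
    vd0_ml: float                 # dead space at the surface
    dlv_fraction: float = 1.0     # diving lung volume as a fraction of TLC
    shape: LungShape = LungShape()

    def __post_init__(self) -> None:
        if not 0.0 < self.vd0_ml < self.tlc_total_ml:
            raise ValueError("dead space must be positive and smaller than TLC")
        if not 0.0 < self.dlv_fraction <= 1.0:
            raise ValueError("dlv_fraction must lie in (0, 1]")

    @property
    def vfa_max_ml(self) -> float:
        """Maximum faveolar volume: TLC minus surface dead space."""
        return self.tlc_total_ml - self.vd0_ml

    @classmethod
    def from_config(cls, config: TurtleConfig) -> "LungGeometry":
        tlc = config.tlc_total_ml
        return cls(
            tlc_total_ml=tlc,
            vd0_ml=config.species.vd_fraction * tlc,
            dlv_fraction=config.dlv_fraction,
            shape=config.lung_shape,
        )


def dead_space_volume(geometry: LungGeometry, p_amb):
    """Structural dead-space volume (ml) at ambient pressure ``p_amb``.

    VD(P) = VD0 * (fmin + (1 - fmin) * (1 + (P - 1)/|Kp|)^-n): a
    compliant decline toward a residual incompressible airway fraction.
    The decline is slower than Boyle at every pressure, so the airways
    never create gas volume.
    """
    p = np.asarray(p_amb, dtype=float)
    if np.any(p < 1.0):
        raise ValueError("ambient pressure must be >= 1 ATA")
    s = geometry.shape
    fmin = s.vd_min_fraction
    vd = geometry.vd0_ml * (fmin + (1.0 - fmin) * (1.0 + (p - 1.0) / (-s.kp)) ** -s.n)
    return vd if vd.ndim else float(vd)


def compress(geometry: LungGeometry, p_amb, total_gas_volume_ml=None):
    """Faveolar and dead-space volumes (ml) at pressure ``p_amb``.

    The total gas volume defaults to Boyle's law on the diving lung
    volume, DLV * TLC / P; the simulator passes the actual (exchange-
    depleted) gas volume instead.  The airways claim their structural
    volume first and the faveoli hold the remainder, clipped at zero.

    Returns ``(vfa_ml, vd_ml)``.
    """
    p = np.asarray(p_amb, dtype=float)
    if np.any(p < 1.0):
        raise ValueError("ambient pressure must be >= 1 ATA")
    if total_gas_volume_ml is None:
        v_tot = geometry.dlv_fraction * geometry.tlc_total_ml / p
    else:
        v_tot = np.asarray(total_gas_volume_ml, dtype=float)
    vd_struct = dead_space_volume(geometry, p)
    vd = np.minimum(vd_struct, v_tot)
    vfa = np.maximum(0.0, v_tot - vd)
    if vfa.ndim:
        return vfa, vd
    return float(vfa), float(vd)


def shunt_fraction(vfa_ml, vfa_reference_ml, shape: LungShape = LungShape()):
    """Pulmonary shunt as a function of faveolar derecruitment.

    ``vfa_reference_ml`` is the unimpeded faveolar volume the current
    pressure would allow if the gas kept its surface faveolar/airway
    split (Boyle-scaled; see :func:`faveolar_reference`); at the surface
    this equals the actual faveolar volume.  The shunt
    s = s0 + (1 - s0) * (1 - VfA/ref)^gamma is smooth, monotone
    non-increasing in VfA, equal to the baseline ``s0`` at the
    reference and exactly 1 at collapse (VfA = 0).
    """
    vfa = np.asarray(vfa_ml, dtype=float)
    if np.any(vfa < -1e-9) or np.any(vfa > np.asarray(vfa_reference_ml) * (1 + 1e-9)):
        raise ValueError("VfA must lie in [0, VfA_reference]")
    r = np.clip(vfa / vfa_reference_ml, 0.0, 1.0)
    s = shape.shunt_s0 + (1.0 - shape.shunt_s0) * (1.0 - r) ** shape.shunt_gamma
    return s if s.ndim else float(s)


def faveolar_reference(geometry: LungGeometry, total_gas_volume_ml):
    """Unimpeded faveolar volume for a given total gas volume.

    If faveoli and airways compressed in proportion (no airway
    stiffness), the faveoli would keep their surface share of the gas:
    ref = V_tot * VfA0 / (VfA0 + VD0) with VfA0 the faveolar volume at
    the start of the dive.  The shunt measures how far the actual VfA
    has fallen below this.
    """
    v0 = geometry.dlv_fraction * geometry.tlc_total_ml
    share0 = (v0 - geometry.vd0_ml) / v0
    ref = share0 * np.asarray(total_gas_volume_ml, dtype=float)
    return ref if ref.ndim else float(ref)


def collapse_pressure(geometry: LungGeometry, p_max: float = 200.0) -> float:
    """Smallest ambient pressure (ATA) at which the faveoli are empty.

    Found by bisection on VfA(P) = 0 for the closed (Boyle) lung; VfA is
    non-increasing over the physiological range, and a finite collapse
    pressure always exists because the airway volume levels off at its
    residual value while the gas volume keeps falling as 1/P.
    """
    lo, hi = 1.0, p_max
    vfa_hi, _ = compress(geometry, hi)
    if vfa_hi > 0:
        raise ValueError(f"no collapse below {p_max} ATA")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        vfa, _ = compress(geometry, mid)
        if vfa > 0.0:
            lo = mid
        else:
            hi = mid
    return hi


def compression_table(geometry: LungGeometry, depths_m) -> "np.ndarray":
    """Diagnostic (depth, VfA/VfA_max, shunt) rows for plotting.

    Returns an array of shape (n, 3); write it to CSV for compression-
    curve figures.
    """
    depths = np.asarray(depths_m, dtype=float)
    p = 1.0 + depths / M_PER_ATA
    v_tot = geometry.dlv_fraction * geometry.tlc_total_ml / p
    vfa, _ = compress(geometry, p)
    s = shunt_fraction(vfa, faveolar_reference(geometry, v_tot), geometry.shape)
    return np.column_stack([depths, np.asarray(vfa) / geometry.vfa_max_ml, s])
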