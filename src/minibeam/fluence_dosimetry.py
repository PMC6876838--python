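"""Particle-counting dosimetry: proton counts to dose via LET.

For a thin target in which the linear energy transfer is nearly constant,
the mean dose over an irradiated area A is the fluence times the mass
stopping power:

    D = N_total * LET / (rho * A)

with N_total the counted protons and appropriate unit conversions
(LET in keV/μm, area in mm², density in g/cm³, dose in Gy).  Counting at
MHz rates undercounts because of detector/electronics dead time; the
correction factor is obtained either from a stated loss fraction or from
the darkening ratio of two radiochromic films irradiated at low and high
count rate with the same nominal proton number.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "KEV_TO_JOULE",
    "IrradiationSetup",
    "DeadTimeRecord",
    "mean_dose_from_protons",
    "protons_for_dose",
    "deadtime_factor",
]

KEV_TO_JOULE = 1.602e-16  # J per keV
_UM_PER_CM = 1.0e4
_MM2_TO_CM2 = 1.0e-2
_G_TO_KG = 1.0e-3


@dataclass(frozen=True)
class IrradiationSetup:
    """Counted-proton irradiation of a uniform slab.

    ``protons_per_beam`` are the counted protons in each of ``n_beams``
    pencil beams; ``field_area_mm2`` the irradiated area over which the
    mean dose is defined; ``let_kev_um`` the (approximately constant)
    LET in the slab; ``density_g_cm3`` defaults to water/soft tissue.
    """

    protons_per_beam: float
    n_beams: int = 16
    field_area_mm2: float = 51.84
    let_kev_um: float = 2.7
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.protons_per_beam < 0:
            raise ValueError("protons_per_beam must be non-negative")
        if self.n_beams <= 0 or self.let_kev_um <= 0 or self.density_g_cm3 <= 0:
            raise ValueError("n_beams, LET and density must be positive")
        if self.field_area_mm2 <= 0:
            raise ZeroDivisionError("field area must be positive")


@dataclass(frozen=True)
class DeadTimeRecord:
    """Dead-time evidence: a loss fraction or a film darkening pair.

    ``darkening`` is (low-rate signal, high-rate signal) for films
    irradiated with the same nominal proton count; with a linear film
    response their ratio is exactly the count correction factor.
    """

    loss_fraction: float | None = None
    darkening: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (self.loss_fraction is None) == (self.darkening is None):
            raise ValueError("provide exactly one of loss_fraction or darkening")
        if self.loss_fraction is not None and not (0.0 <= self.loss_fraction < 1.0):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.darkening is not None:
            low, high = self.darkening
            if low <= 0 or high <= 0:
                raise ValueError("darkening signals must be positive")
            if high > low:
                raise ValueError(
                    "high-rate film darker than low-rate film: inconsistent dead-time input"
                )


def mean_dose_from_protons(setup: IrradiationSetup) -> float:
    """Mean dose (Gy) delivered by the counted protons.

    Uniform-slab fluence dosimetry: dose = fluence x LET / density, with
    LET converted from keV/μm to J/cm.  With the experimental values
    (16 beams of ~4.58e8 protons, LET 2.7 keV/μm, 7.2 x 7.2 mm²) this
    reproduces the nominal 60 Gy.
    """
    let_j_cm = setup.let_kev_um * _UM_PER_CM * KEV_TO_JOULE
    n_total = setup.protons_per_beam * setup.n_beams
    area_cm2 = setup.field_area_mm2 * _MM2_TO_CM2
    mass_per_area = setup.density_g_cm3 * _G_TO_KG  # kg/cm³ -> per cm depth
    return n_total * let_j_cm / (area_cm2 * mass_per_area)


def protons_for_dose(
    target_dose: float,
    n_beams: int = 16,
    field_area_mm2: float = 51.84,
    let_kev_um: float = 2.7,
    density_g_cm3: float = 1.0,
) -> float:
    """Protons per beam needed for a target mean dose (algebraic inverse)."""
    if target_dose < 0:
        raise ValueError("target_dose must be non-negative")
    let_j_cm = let_kev_um * _UM_PER_CM * KEV_TO_JOULE
    area_cm2 = field_area_mm2 * _MM2_TO_CM2
    mass_per_area = density_g_cm3 * _G_TO_KG
    return target_dose * area_cm2 * mass_per_area / (let_j_cm * n_beams)


def deadtime_factor(record: DeadTimeRecord | float) -> float:
    """Multiplicative count correction (>= 1) for detector dead time.

    From a loss fraction l: factor = 1 / (1 - l).  From a darkening pair
    (assumed linear film response): factor = low-rate / high-rate signal.
    """
    if not isinstance(record, DeadTimeRecord):
        record = DeadTimeRecord(loss_fraction=float(record))
    if record.loss_fraction is not None:
        return 1.0 / (1.0 - record.loss_fraction)
    low, high = record.darkening
    return low / high
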