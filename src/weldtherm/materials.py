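"""Material constants and temperature-dependent constitutive laws.

Tissue thermal and electrical conductivities follow affine laws in temperature
around a reference temperature; electrode (copper) properties are constant.
All temperatures are carried in degrees Celsius: the laws only ever use
temperature *differences*, so no Kelvin conversion is required anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import yaml

__all__ = [
    "DegeneratePropertyError",
    "UnknownRegionError",
    "MaterialProperties",
    "PerfusionParameters",
    "TISSUE",
    "ELECTRODE",
    "thermal_conductivity",
    "electrical_conductivity",
    "perfusion_source",
    "material_for_region",
    "materials_from_config",
]


class DegeneratePropertyError(ValueError):
    """A constitutive law evaluated to a non-physical (<= 0 or < 0) value."""


class UnknownRegionError(KeyError):
    """Requested material for a region label that has no material assigned."""


@dataclass(frozen=True)
class MaterialProperties:
    """Bulk material constants plus coefficients of the affine T-laws.

    Parameters
    ----------
    density : float
        Mass density ``rho`` (kg/m^3).
    heat_capacity : float
        Specific heat capacity at constant pressure ``c_p`` (J/kg/K).
    thermal_conductivity_baseline : float
        Thermal conductivity ``k0`` at the reference temperature (W/m/K).
    electrical_conductivity_baseline : float
        Electrical conductivity ``sigma0`` at the reference temperature (S/m).
    k_temp_coefficient : float
        Slope of ``k(T)`` (W/m/K per degree C). Ignored when
        ``temperature_dependent`` is False.
    sigma_temp_fraction : float
        Fractional slope of ``sigma(T)`` (1/degree C). Ignored when
        ``temperature_dependent`` is False.
    reference_temperature : float
        Reference temperature ``T0`` (degree C).
    temperature_dependent : bool
        Whether the affine laws apply (tissue) or the material is treated as
        constant (metal electrodes).
    """

    name: str
    density: float
    heat_capacity: float
    thermal_conductivity_baseline: float
    electrical_conductivity_baseline: float
    k_temp_coefficient: float = 0.0
    sigma_temp_fraction: float = 0.0
    reference_temperature: float = 25.0
    temperature_dependent: bool = False

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.heat_capacity <= 0:
            raise ValueError(f"heat_capacity must be > 0, got {self.heat_capacity}")
        if self.thermal_conductivity_baseline <= 0:
            raise ValueError(
                "thermal_conductivity_baseline must be > 0, got "
                f"{self.thermal_conductivity_baseline}"
            )
        if self.electrical_conductivity_baseline < 0:
            raise ValueError(
                "electrical_conductivity_baseline must be >= 0, got "
                f"{self.electrical_conductivity_baseline}"
            )

    @property
    def volumetric_heat_capacity(self) -> float:
        """``rho * c_p`` (J/m^3/K)."""
        return self.density * self.heat_capacity


#: Vessel-tissue defaults (affine conductivity laws referenced to 25 C).
TISSUE = MaterialProperties(
    name="tissue",
    density=1101.5,
    heat_capacity=3306.0,
    thermal_conductivity_baseline=0.462,
    electrical_conductivity_baseline=0.24567,
    k_temp_coefficient=0.0013,
    sigma_temp_fraction=0.02,
    reference_temperature=25.0,
    temperature_dependent=True,
)

#: Copper electrode defaults; properties treated as constant.
ELECTRODE = MaterialProperties(
    name="electrode",
    density=8960.0,
    heat_capacity=381.875,
    thermal_conductivity_baseline=401.0,
    electrical_conductivity_baseline=57_142_857.0,
    temperature_dependent=False,
)


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature must be finite")
    return T


def thermal_conductivity(props: MaterialProperties, T) -> Union[float, np.ndarray]:
    """Thermal conductivity ``k(T)`` in W/m/K.

    Affine in temperature for temperature-dependent materials,
    ``k0 + coeff * (T - T0)``; constant ``k0`` otherwise. Accepts scalars or
    arrays. Raises :class:`DegeneratePropertyError` if the computed value is
    not strictly positive (no silent clamping, so solver excursions are
    caught loudly).
    """
    T = _check_temperature(T)
    if props.temperature_dependent:
        k = props.thermal_conductivity_baseline + props.k_temp_coefficient * (
            T - props.reference_temperature
        )
    else:
        k = np.broadcast_to(
            np.float64(props.thermal_conductivity_baseline), T.shape
        ).copy()
    if np.any(k <= 0):
        raise DegeneratePropertyError(
            f"thermal conductivity of {props.name!r} became non-positive "
            f"(min {np.min(k):g} W/m/K)"
        )
    return k if k.ndim else float(k)


def electrical_conductivity(
    props: MaterialProperties,
    T,
    *,
    damage_above: float | None = None,
    damage_factor: float = 1e-4,
) -> Union[float, np.ndarray]:
    """Electrical conductivity ``sigma(T)`` in S/m.

    ``sigma0 * (1 + fraction * (T - T0))`` for temperature-dependent
    materials, constant ``sigma0`` otherwise. Negative computed values raise
    :class:`DegeneratePropertyError`.

    The optional ``damage_above`` switch multiplies sigma by
    ``damage_factor`` (default 1/10,000) wherever ``T >= damage_above``,
    emulating the abrupt conductivity collapse sometimes used to flag thermal
    damage. It is off by default.
    """
    T = _check_temperature(T)
    if props.temperature_dependent:
        sigma = props.electrical_conductivity_baseline * (
            1.0 + props.sigma_temp_fraction * (T - props.reference_temperature)
        )
    else:
        sigma = np.broadcast_to(
            np.float64(props.electrical_conductivity_baseline), T.shape
        ).copy()
    if np.any(sigma < 0):
        raise DegeneratePropertyError(
            f"electrical conductivity of {props.name!r} became negative "
            f"(min {np.min(sigma):g} S/m)"
        )
    if damage_above is not None:
        sigma = np.where(T >= damage_above, sigma * damage_factor, sigma)
    return sigma if sigma.ndim else float(sigma)


@dataclass(frozen=True)
class PerfusionParameters:
    """Blood-perfusion / metabolic source parameters (disabled by default).

    The source is ``rho_b * c_pb * omega_b * (T_b - T) + Q_met`` (W/m^3) when
    enabled and identically zero when disabled, matching the ex-vivo usage.
    """

    blood_density: float = 1050.0
    blood_heat_capacity: float = 3617.0
    perfusion_rate: float = 0.0
    arterial_temperature: float = 37.0
    metabolic_source: float = 0.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.perfusion_rate < 0:
            raise ValueError("perfusion_rate must be >= 0")
        if self.enabled and (self.blood_density <= 0 or self.blood_heat_capacity <= 0):
            raise ValueError("blood density and heat capacity must be > 0 when enabled")


def perfusion_source(params: PerfusionParameters, T) -> Union[float, np.ndarray]:
    """Volumetric perfusion + metabolic source (W/m^3); exactly 0 when disabled."""
    T = _check_temperature(T)
    if not params.enabled:
        out = np.zeros_like(T)
        return out if out.ndim else 0.0
    q = (
        params.blood_density
        * params.blood_heat_capacity
        * params.perfusion_rate
        * (params.arterial_temperature - T)
        + params.metabolic_source
    )
    return q if np.ndim(q) else float(q)


_DEFAULT_REGIONS: dict[str, MaterialProperties] = {
    "tissue": TISSUE,
    "upper_electrode": ELECTRODE,
    "lower_electrode": ELECTRODE,
}


def material_for_region(
    label: str, overrides: Mapping[str, MaterialProperties] | None = None
) -> MaterialProperties:
    """Material defaults for a solid region label.

    Valid labels are ``tissue``, ``upper_electrode`` and ``lower_electrode``.
    """
    table = dict(_DEFAULT_REGIONS)
    if overrides:
        table.update(overrides)
    try:
        return table[label]
    except KeyError:
        raise UnknownRegionError(
            f"no material for region {label!r}; expected one of {sorted(table)}"
        ) from None


def materials_from_config(
    source: Union[str, Path, Mapping]
) -> dict[str, MaterialProperties]:
    """Load a region -> material table, overriding bundled defaults.

    ``source`` is either a YAML file path or an already-parsed nested mapping
    of the form ``{region: {field: value, ...}, ...}``. Unspecified fields keep
    their defaults, so a config may override a single constant.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    table = dict(_DEFAULT_REGIONS)
    for region, fields in data.items():
        base = table.get(region)
        if base is None:
            base = TISSUE if "tissue" in region else ELECTRODE
        table[region] = replace(base, **dict(fields))
    return table
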