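"""Shared physics utilities for Er:YAG photoacoustic treatment bookkeeping.

Closed-form helpers used throughout the package: fiber-tip fluence, the
elastomer storage-modulus to Young's-modulus conversion, dual-pulse energy
accounting and the inter-pulse delay grid of the Auto-SWEEPS (ASW) modality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when a configuration value is physically inconsistent."""


@dataclass(frozen=True)
class LaserConfig:
    """Laser treatment settings.

    Defaults follow the treatment protocol used for the zero-gap pocket
    experiments: single 10/20/30 mJ pulses at 15 Hz through a 400 µm flat
    fiber, 10 s treatment time; the ASW dual-pulse modality sweeps the
    inter-pulse delay t_d from 200 to 650 µs in 10 µs steps.
    """

    modality: str = "USP"
    pulse_energy_mJ: float = 20.0
    repetition_rate_Hz: float = 15.0
    fiber_diameter_um: float = 400.0
    t_d_range_us: tuple[float, float] = (200.0, 650.0)
    t_d_step_us: float = 10.0
    treatment_time_s: float = 10.0

    def __post_init__(self) -> None:
        if self.modality not in ("USP", "ASW"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.pulse_energy_mJ <= 0:
            raise ConfigurationError("pulse energy must be positive")
        if self.fiber_diameter_um <= 0:
            raise ConfigurationError("fiber diameter must be positive")
        if not self.t_d_range_us[1] > self.t_d_range_us[0]:
            raise ConfigurationError("t_d range must be increasing")
        if self.t_d_step_us <= 0:
            raise ConfigurationError("t_d step must be positive")


@dataclass(frozen=True)
class MaterialConfig:
    """Soft-plate (gingiva-mimicking PDMS) material description.

    ``youngs_modulus_E_kPa`` is derived from the storage modulus via the
    elastomer approximation E ~ 3 G' when not given explicitly.
    """

    storage_modulus_G_prime_kPa: float
    roughness_Ra_um: float = 8.0
    youngs_modulus_E_kPa: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.storage_modulus_G_prime_kPa < 0:
            raise ConfigurationError("storage modulus must be non-negative")
        if self.roughness_Ra_um < 0:
            raise ConfigurationError("roughness Ra must be non-negative")
        if self.youngs_modulus_E_kPa is None:
            object.__setattr__(
                self,
                "youngs_modulus_E_kPa",
                youngs_from_storage(self.storage_modulus_G_prime_kPa),
            )


def fluence_J_cm2(energy_mJ: float, fiber_diameter_um: float) -> float:
    """Per-pulse fluence at the fiber tip in J/cm².

    Energy divided by the fiber cross-section; a 10 mJ pulse through a
    400 µm fiber gives ~8 J/cm², 30 mJ gives ~24 J/cm².
    """
    if energy_mJ <= 0 or fiber_diameter_um <= 0:
        raise ConfigurationError("energy and fiber diameter must be positive")
    radius_cm = fiber_diameter_um / 2.0 * 1e-4
    return (energy_mJ / 1000.0) / (math.pi * radius_cm**2)


def youngs_from_storage(g_prime_kPa: float) -> float:
    """Young's modulus (kPa) from storage modulus via E ~ 3 G' (elastomers)."""
    if g_prime_kPa < 0:
        raise ConfigurationError("storage modulus must be non-negative")
    return 3.0 * g_prime_kPa


def asw_pair_energy(per_pulse_mJ: float) -> float:
    """Total energy (mJ) delivered by one ASW dual-pulse pair."""
    if per_pulse_mJ <= 0:
        raise ConfigurationError("per-pulse energy must be positive")
    return 2.0 * per_pulse_mJ


def delay_grid(cfg: LaserConfig | None = None) -> list[float]:
    """Inclusive arithmetic grid of ASW inter-pulse delays in µs.

    Default grid is 200, 210, ..., 650 µs (46 points).
    """
    if cfg is None:
        cfg = LaserConfig(modality="ASW", t_d_range_us=(200.0, 650.0))
    lo, hi = cfg.t_d_range_us
    step = cfg.t_d_step_us
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    return [lo + i * step for i in range(n)]
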