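"""Accelerator and nozzle calibration model.

In a cyclotron-based pencil-beam-scanning (PBS) system operated in
transmission/FLASH mode, the beam current of an energy layer is set by the
minimum monitor unit (MU) of a spot in that layer: the machine runs the
nozzle at the current that delivers the minimum-MU spot in a fixed dwell
time (2 ms by default).  The chain

    min MU/spot  ->  MU rate  ->  proton flux  ->  nozzle current
                                          `->  spot peak dose rate (SPDR)

is anchored by a single calibration point: at the maximum-transmission
nozzle current (~640 nA for a 250 MeV transmission beam) the spot peak
dose rate in water near 4 cm depth is ~2600 Gy/s.  Together with the
MU definition (~5.17e6 protons per MU at 240 MeV) this fixes a dose-per-MU
constant ``k`` so that ``SPDR = k * MU_rate``; with the defaults
k ~ 3.365e-3 Gy/MU, giving ~168 Gy/s at 100 MU/spot and ~673 Gy/s at
400 MU/spot.

Units: seconds, Gy, Gy/s, mm and MU internally; amperes only at the
interface (nanoamperes in printed output).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

ELEMENTARY_CHARGE = 1.602176634e-19
"""Elementary charge in coulomb (2019 SI exact value)."""


class UndeliverableSpotError(ValueError):
    """A spot's MU is below the machine's minimum MU per spot."""


@dataclass(frozen=True)
class MachineModel:
    """Calibration constants linking MU, protons, current, dwell and SPDR.

    Parameters
    ----------
    protons_per_mu
        Protons contained in one monitor unit (default 5.17e6, the MU
        definition of a 240 MeV transmission beam).
    min_mu_per_spot
        Plan-level minimum MU of a spot in the energy layer; sets the
        layer beam current (typical FLASH settings: 100 or 400).
    dwell_time_min_mu
        Delivery time of a minimum-MU spot, in seconds (default 2 ms).
    scan_speed
        Magnet scanning speed between spots, in mm per ms (default 10).
    calibration_current
        Nozzle current of the calibration anchor, in ampere (default 640 nA).
    calibration_spdr
        Spot peak dose rate at the calibration current, in Gy/s
        (default 2600).
    """

    protons_per_mu: float = 5.17e6
    min_mu_per_spot: float = 100.0
    dwell_time_min_mu: float = 2e-3
    scan_speed: float = 10.0
    calibration_current: float = 640e-9
    calibration_spdr: float = 2600.0

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            value = getattr(self, name.name)
            if not (value > 0.0):
                raise ValueError(
                    f"MachineModel.{name.name} must be strictly positive, got {value!r}"
                )

    # ------------------------------------------------------------------
    # derived rates
    # ------------------------------------------------------------------
    @property
    def mu_rate(self) -> float:
        """Layer MU delivery rate in MU/s (min MU over the fixed dwell)."""
        return self.min_mu_per_spot / self.dwell_time_min_mu

    @property
    def calibration_mu_rate(self) -> float:
        """MU rate implied by the calibration current, in MU/s."""
        return self.calibration_current / ELEMENTARY_CHARGE / self.protons_per_mu

    @property
    def dose_per_mu(self) -> float:
        """Spot-peak dose per MU, ``k`` in Gy/MU, fixed by the anchor."""
        return self.calibration_spdr / self.calibration_mu_rate

    @property
    def spot_peak_dose_rate(self) -> float:
        """SPDR of the layer in Gy/s: ``k`` times the layer MU rate."""
        return self.dose_per_mu * self.mu_rate

    @property
    def nozzle_current(self) -> float:
        """Nozzle current of the layer in ampere."""
        return self.mu_rate * self.protons_per_mu * ELEMENTARY_CHARGE

    @property
    def scan_speed_mm_per_s(self) -> float:
        return self.scan_speed * 1e3

    # ------------------------------------------------------------------
    # inverse map and per-spot timing
    # ------------------------------------------------------------------
    def min_mu_from_current(self, current: float) -> float:
        """Minimum MU/spot that would set the layer to ``current`` ampere."""
        if not current > 0:
            raise ValueError("current must be strictly positive")
        return current / (self.protons_per_mu * ELEMENTARY_CHARGE) * self.dwell_time_min_mu

    def dwell_time(self, spot_mu: float) -> float:
        """Delivery time of a ``spot_mu`` spot in seconds.

        The beam current is fixed by the layer minimum MU, so dwell scales
        linearly with the spot weight; it equals ``dwell_time_min_mu`` at
        the minimum.  Spots below the minimum are undeliverable.
        """
        if spot_mu < self.min_mu_per_spot * (1.0 - 1e-12):
            raise UndeliverableSpotError(
                f"spot of {spot_mu} MU is below the minimum {self.min_mu_per_spot} MU/spot"
            )
        return spot_mu / self.mu_rate

    def with_min_mu(self, min_mu_per_spot: float) -> "MachineModel":
        """Copy of this model with a different minimum MU/spot."""
        return dataclasses.replace(self, min_mu_per_spot=min_mu_per_spot)
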