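"""Semi-quantification against a deuterated injection standard.

Amounts are estimated by single-point linear response: an analyte peak area
is scaled by the known injected amount of the standard divided by the
standard's area. A per-compound response factor is exposed for future
calibration but defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .profiles import Measurement, ValueKind

__all__ = ["InternalStandard", "semi_quantify", "detection_floor"]


@dataclass(frozen=True)
class InternalStandard:
    """Deuterated injection standard added at known concentration and volume.

    Defaults correspond to 0.5 mg/mL standard added at 3 uL per 100 uL of
    sample, i.e. 1.5 ug injected per aliquot.
    """

    concentration_mg_per_ml: float = 0.5
    volume_added_ul: float = 3.0
    measured_area: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_mg_per_ml <= 0:
            raise ValueError("standard concentration must be > 0")
        if self.volume_added_ul <= 0:
            raise ValueError("standard volume must be > 0")
        if self.measured_area < 0:
            raise ValueError("standard area must be >= 0")

    @property
    def amount_injected_ug(self) -> float:
        # mg/mL * uL == ug
        return self.concentration_mg_per_ml * self.volume_added_ul


def semi_quantify(area: float, standard: InternalStandard, *, response_factor: float = 1.0) -> float:
    """Amount (ug per aliquot) of an analyte from its peak area.

    ``amount = injected_standard_amount * (area / standard_area) / rf``,
    exactly linear in ``area``.
    """
    if standard.measured_area <= 0:
        raise ZeroDivisionError(
            "internal standard area is zero; cannot semi-quantify against it"
        )
    if area < 0:
        raise ValueError("peak area must be >= 0")
    if response_factor <= 0:
        raise ValueError("response factor must be > 0")
    return standard.amount_injected_ug * (area / standard.measured_area) / response_factor


def detection_floor(
    measurements: Iterable[Measurement], floor: float
) -> list[Measurement]:
    """Mark values strictly below ``floor`` as undetected ("n.d.").

    Values equal to the floor stay detected; ``floor=0`` is the identity.
    """
    if floor < 0:
        raise ValueError("detection floor must be >= 0")
    out: list[Measurement] = []
    for m in measurements:
        if m.detected and m.value is not None and m.value < floor:
            out.append(
                Measurement(
                    descriptor=m.descriptor,
                    value=None,
                    value_kind=m.value_kind,
                    detected=False,
                )
            )
        else:
            out.append(m)
    return out
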