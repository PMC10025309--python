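"""Branching indices of 3-hydroxy fatty acid compositions.

Let I, A, N be the summed relative abundances of iso, anteiso and normal
3-OH FAs in the C10-C18 range. The indices computed here are

* ``RIAN = -log10((I + A) / N)``
* ``RAN15 = [anteiso-C15] / [normal-C15]``
* ``RAN17 = [anteiso-C17] / [normal-C17]``

plus the plain class ratios I/A, I/N and A/N. Any ratio with an undetected
or zero denominator is undefined and reported as ``None`` (printed tables
show "n.d." in that case). Because every index is a ratio of abundances on
the same basis, the closure constant cancels: raw peak areas and normalized
profiles give identical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .profiles import (
    AggregateProfile,
    Basis,
    BasisError,
    Branching,
    ClassTotals,
    ExperimentSeries,
    FattyAcidDescriptor,
    SampleProfile,
    aggregate_replicates,
    class_totals,
)

__all__ = [
    "IndexSet",
    "INDEX_NAMES",
    "rian",
    "ran15",
    "ran17",
    "branching_ratios",
    "compute_indices",
    "index_table",
    "AI_C15",
    "N_C15",
    "AI_C17",
    "N_C17",
]

AI_C15 = FattyAcidDescriptor(15, Branching.ANTEISO, 0, True)
N_C15 = FattyAcidDescriptor(15, Branching.NORMAL, 0, True)
AI_C17 = FattyAcidDescriptor(17, Branching.ANTEISO, 0, True)
N_C17 = FattyAcidDescriptor(17, Branching.NORMAL, 0, True)

INDEX_NAMES = (
    "RIAN",
    "RAN15",
    "RAN17",
    "iso_over_anteiso",
    "iso_over_normal",
    "anteiso_over_normal",
)

#: Denominator abundance (%) below which a ratio is numerically unstable.
UNSTABLE_DENOMINATOR = 0.1

ProfileLike = SampleProfile | AggregateProfile | Mapping[FattyAcidDescriptor, float]


@dataclass(frozen=True)
class IndexSet:
    """All indices and class totals for one profile or aggregate."""

    rian: float | None
    ran15: float | None
    ran17: float | None
    iso_over_anteiso: float | None
    iso_over_normal: float | None
    anteiso_over_normal: float | None
    iso: float
    anteiso: float
    normal: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "RIAN": self.rian,
            "RAN15": self.ran15,
            "RAN17": self.ran17,
            "iso_over_anteiso": self.iso_over_anteiso,
            "iso_over_normal": self.iso_over_normal,
            "anteiso_over_normal": self.anteiso_over_normal,
        }


def _check_basis(profile: ProfileLike) -> None:
    if isinstance(profile, (SampleProfile, AggregateProfile)):
        if profile.basis is not Basis.TOTAL_3OH_FAS:
            raise BasisError(
                "indices require a profile on the total_3OH_FAs basis, got "
                f"{profile.basis.value}"
            )


def _abundances(profile: ProfileLike) -> Mapping[FattyAcidDescriptor, float]:
    if isinstance(profile, SampleProfile):
        return profile.detected
    if isinstance(profile, AggregateProfile):
        return profile.means
    return profile


def _safe_ratio(num: float | None, den: float | None) -> float | None:
    if num is None or den is None or den == 0:
        return None
    return num / den


def rian(profile: ProfileLike, *, totals: ClassTotals | None = None) -> float | None:
    """``-log10((I + A) / N)``; undefined when N or I+A is zero."""
    _check_basis(profile)
    t = totals if totals is not None else class_totals(_abundances(profile))
    if t.normal <= 0 or (t.iso + t.anteiso) <= 0:
        return None
    return -math.log10((t.iso + t.anteiso) / t.normal)


def ran15(profile: ProfileLike) -> float | None:
    """Anteiso-C15 over normal-C15 3-OH FA abundance ratio."""
    _check_basis(profile)
    a = _abundances(profile)
    return _safe_ratio(a.get(AI_C15), a.get(N_C15))


def ran17(profile: ProfileLike) -> float | None:
    """Anteiso-C17 over normal-C17 3-OH FA abundance ratio."""
    _check_basis(profile)
    a = _abundances(profile)
    return _safe_ratio(a.get(AI_C17), a.get(N_C17))


def branching_ratios(
    profile: ProfileLike, *, totals: ClassTotals | None = None
) -> tuple[float | None, float | None, float | None]:
    """(I/A, I/N, A/N) with the undefined-on-zero-denominator rule."""
    _check_basis(profile)
    t = totals if totals is not None else class_totals(_abundances(profile))
    return (
        _safe_ratio(t.iso, t.anteiso),
        _safe_ratio(t.iso, t.normal),
        _safe_ratio(t.anteiso, t.normal),
    )


def compute_indices(profile: ProfileLike) -> IndexSet:
    """Compute the full :class:`IndexSet` for one profile or aggregate.

    Ratios whose denominator abundance falls below 0.1% are still computed
    but flagged as numerically unstable.
    """
    _check_basis(profile)
    abund = _abundances(profile)
    t = class_totals(abund)
    i_a, i_n, a_n = branching_ratios(profile, totals=t)
    flags: set[str] = set()
    n15 = abund.get(N_C15)
    n17 = abund.get(N_C17)
    if n15 is not None and 0 < n15 < UNSTABLE_DENOMINATOR:
        flags.add("RAN15")
    if n17 is not None and 0 < n17 < UNSTABLE_DENOMINATOR:
        flags.add("RAN17")
    if 0 < t.normal < UNSTABLE_DENOMINATOR:
        flags.update({"RIAN", "iso_over_normal", "anteiso_over_normal"})
    return IndexSet(
        rian=rian(profile, totals=t),
        ran15=ran15(profile),
        ran17=ran17(profile),
        iso_over_anteiso=i_a,
        iso_over_normal=i_n,
        anteiso_over_normal=a_n,
        iso=t.iso,
        anteiso=t.anteiso,
        normal=t.normal,
        flags=frozenset(flags),
    )


def index_table(
    series: ExperimentSeries, mode: str = "per_replicate_then_aggregate"
) -> pd.DataFrame:
    """Per-level index summary for a replicated series.

    ``per_replicate_then_aggregate`` computes every index on each replicate
    and reports mean/sd/n over the replicates where it is defined (this
    reproduces printed "mean +/- sd" index rows). ``ratio_of_means``
    aggregates the composition first and computes indices from level-mean
    abundances; sd columns are then empty.

    Returns a tidy frame with columns ``level, index, mean, sd, n_defined``.
    """
    if mode not in ("per_replicate_then_aggregate", "ratio_of_means"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for level in series.levels:
        reps = series.at_level(level)
        if mode == "per_replicate_then_aggregate":
            per_rep = [compute_indices(p).as_dict() for p in reps]
            for name in INDEX_NAMES:
                vals = [d[name] for d in per_rep if d[name] is not None]
                mean = float(pd.Series(vals).mean()) if vals else float("nan")
                sd = (
                    float(pd.Series(vals).std(ddof=1))
                    if len(vals) > 1
                    else float("nan")
                )
                rows.append(
                    {
                        "level": level,
                        "index": name,
                        "mean": mean,
                        "sd": sd,
                        "n_defined": len(vals),
                    }
                )
        else:
            agg = aggregate_replicates(reps)
            idx = compute_indices(agg).as_dict()
            for name in INDEX_NAMES:
                val = idx[name]
                rows.append(
                    {
                        "level": level,
                        "index": name,
                        "mean": float("nan") if val is None else val,
                        "sd": float("nan"),
                        "n_defined": len(reps) if val is not None else 0,
                    }
                )
    return pd.DataFrame(rows)
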