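"""Fatty-acid identity, sample compositions and replicate aggregation.

The module models one GC-MS-derived measurement table: structured fatty-acid
descriptors (carbon number, branching class, unsaturation, 3-hydroxylation),
per-replicate compositions on a declared normalization basis, series of
replicated cultures along a temperature or pH gradient, and mean +/- sd
aggregates across replicates.

Compositions are *closed*: detected relative abundances sum to 100% of the
stated basis. Undetected compounds ("n.d." in printed tables) carry no value
and are distinct from true zeros.
"""

from __future__ import annotations

import enum
import math
import re
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Branching",
    "Basis",
    "ConditionVariable",
    "ValueKind",
    "FattyAcidDescriptor",
    "Measurement",
    "SampleProfile",
    "ExperimentSeries",
    "AggregateStat",
    "AggregateProfile",
    "ClassTotals",
    "FattyAcidParseError",
    "CarbonRangeError",
    "BasisError",
    "ClosureError",
    "DegenerateInputError",
    "parse_fa_name",
    "format_fa_name",
    "normalize",
    "class_totals",
    "aggregate_replicates",
    "INDEX_SCOPE_MIN_CARBON",
    "INDEX_SCOPE_MAX_CARBON",
    "in_index_scope",
]

INDEX_SCOPE_MIN_CARBON = 10
INDEX_SCOPE_MAX_CARBON = 18


class Branching(enum.Enum):
    """Methyl-branch position class of a fatty acid chain."""

    NORMAL = "normal"
    ISO = "iso"
    ANTEISO = "anteiso"


class Basis(enum.Enum):
    """Denominator set of a relative-abundance composition."""

    TOTAL_FAS = "total_FAs"
    TOTAL_3OH_FAS = "total_3OH_FAs"


class ConditionVariable(enum.Enum):
    TEMPERATURE_C = "temperature_C"
    PH = "pH"


class ValueKind(enum.Enum):
    PEAK_AREA = "peak_area"
    RELATIVE_ABUNDANCE = "relative_abundance"
    AMOUNT = "amount"


class FattyAcidParseError(ValueError):
    """A fatty-acid label could not be interpreted."""


class CarbonRangeError(ValueError):
    """Carbon number outside the supported C2-C40 range."""


class BasisError(ValueError):
    """Operation applied to a profile on an incompatible basis."""


class ClosureError(ValueError):
    """Detected relative abundances do not sum to 100 within tolerance."""


class DegenerateInputError(ValueError):
    """Empty or all-zero input where a positive total is required."""


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Structural identity of one fatty acid.

    Equality is structural: two descriptors with identical fields denote the
    same compound and collide as dict keys.
    """

    carbon_number: int
    branching: Branching = Branching.NORMAL
    n_unsaturations: int = 0
    hydroxylated_3: bool = False

    def __post_init__(self) -> None:
        if not (2 <= self.carbon_number <= 40):
            raise CarbonRangeError(
                f"carbon number {self.carbon_number} outside supported range 2-40"
            )
        if self.branching is Branching.ISO and self.carbon_number < 4:
            raise ValueError("iso branching requires >= 4 carbons")
        if self.branching is Branching.ANTEISO and self.carbon_number < 5:
            raise ValueError("anteiso branching requires >= 5 carbons")
        if self.n_unsaturations < 0:
            raise ValueError("n_unsaturations must be >= 0")
        if self.n_unsaturations >= self.carbon_number:
            raise ValueError("n_unsaturations must be < carbon_number")

    @property
    def label(self) -> str:
        """Canonical short label, e.g. ``3-OH ai-C15`` or ``n-C16:1``."""
        return format_fa_name(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_BRANCH_PREFIX = {
    Branching.NORMAL: "n",
    Branching.ISO: "i",
    Branching.ANTEISO: "ai",
}

_BRANCH_TOKENS = {
    "n": Branching.NORMAL,
    "normal": Branching.NORMAL,
    "i": Branching.ISO,
    "iso": Branching.ISO,
    "ai": Branching.ANTEISO,
    "a": Branching.ANTEISO,
    "anteiso": Branching.ANTEISO,
}

# Grammar covering the label dialects seen in practice:
#   "iso C_15", "anteiso 15:0", "16:1", "i-C15", "3-OH ai-C17", "n-C16:0"
_LABEL_RE = re.compile(
    r"""^
    (?P<oh>3\s*-?\s*oh)?            # optional 3-hydroxy marker
    [\s\-]*
    (?P<branch>anteiso|iso|normal|ai|i|n)?   # optional branching token
    [\s\-]*
    c?                              # optional carbon letter
    [\s_\-]*
    (?P<carbon>\d+)
    (?:\s*:\s*(?P<unsat>\d+))?      # optional :unsaturations
    $""",
    re.IGNORECASE | re.VERBOSE,
)


def parse_fa_name(label: str, *, hydroxylated_3: bool = False) -> FattyAcidDescriptor:
    """Parse a fatty-acid label into a :class:`FattyAcidDescriptor`.

    Parameters
    ----------
    label:
        Text label in any of the supported dialects (case-insensitive).
    hydroxylated_3:
        Default 3-OH flag applied when the label itself carries no
        ``3-OH`` marker, so bare ``iso C_15`` parses correctly in a
        3-hydroxy table context.
    """
    if not isinstance(label, str) or not label.strip():
        raise FattyAcidParseError("empty fatty-acid label")
    cleaned = label.strip().replace("_", " ").replace("−", "-")
    m = _LABEL_RE.match(cleaned)
    if m is None:
        raise FattyAcidParseError(f"cannot parse fatty-acid label {label!r}")
    carbon = int(m.group("carbon"))
    if not (2 <= carbon <= 40):
        raise CarbonRangeError(
            f"carbon number {carbon} in {label!r} outside supported range 2-40"
        )
    branch_token = m.group("branch")
    branching = (
        _BRANCH_TOKENS[branch_token.lower()] if branch_token else Branching.NORMAL
    )
    unsat = int(m.group("unsat")) if m.group("unsat") else 0
    is_oh = bool(m.group("oh")) or hydroxylated_3
    return FattyAcidDescriptor(
        carbon_number=carbon,
        branching=branching,
        n_unsaturations=unsat,
        hydroxylated_3=is_oh,
    )


def format_fa_name(descriptor: FattyAcidDescriptor) -> str:
    """Canonical label; ``parse_fa_name`` round-trips it exactly."""
    parts = []
    if descriptor.hydroxylated_3:
        parts.append("3-OH ")
    parts.append(_BRANCH_PREFIX[descriptor.branching])
    parts.append(f"-C{descriptor.carbon_number}")
    if descriptor.n_unsaturations:
        parts.append(f":{descriptor.n_unsaturations}")
    return "".join(parts)


@dataclass(frozen=True)
class Measurement:
    """One value for one compound; ``detected=False`` encodes "n.d."."""

    descriptor: FattyAcidDescriptor
    value: float | None
    value_kind: ValueKind = ValueKind.PEAK_AREA
    detected: bool = True

    def __post_init__(self) -> None:
        if self.detected:
            if self.value is None:
                raise ValueError("detected measurement requires a value")
            if self.value < 0:
                raise ValueError("measurement value must be non-negative")
            if (
                self.value_kind is ValueKind.RELATIVE_ABUNDANCE
                and not 0 <= self.value <= 100 + 1e-9
            ):
                raise ValueError("relative abundance must lie in [0, 100]")
        elif self.value is not None:
            raise ValueError('undetected ("n.d.") measurement must carry no value')


def _check_basis_compatible(descriptor: FattyAcidDescriptor, basis: Basis) -> None:
    if basis is Basis.TOTAL_3OH_FAS and not descriptor.hydroxylated_3:
        raise BasisError(
            f"{descriptor.label} is not 3-hydroxylated but basis is {basis.value}"
        )


@dataclass
class SampleProfile:
    """One replicate's composition on a stated normalization basis."""

    strain_id: str
    condition_variable: ConditionVariable
    condition_value: float
    replicate_id: str
    basis: Basis
    measurements: dict[FattyAcidDescriptor, Measurement] = field(default_factory=dict)
    fixed_condition: str = ""

    def __post_init__(self) -> None:
        for desc, meas in self.measurements.items():
            if desc != meas.descriptor:
                raise ValueError("measurement keyed under a different descriptor")
            _check_basis_compatible(desc, self.basis)

    @property
    def detected(self) -> dict[FattyAcidDescriptor, float]:
        """Mapping of detected descriptors to their values."""
        return {
            d: m.value
            for d, m in self.measurements.items()
            if m.detected and m.value is not None
        }

    def value_for(self, descriptor: FattyAcidDescriptor) -> float | None:
        m = self.measurements.get(descriptor)
        if m is None or not m.detected:
            return None
        return m.value

    def add(self, measurement: Measurement) -> None:
        if measurement.descriptor in self.measurements:
            raise ValueError(f"duplicate descriptor {measurement.descriptor.label}")
        _check_basis_compatible(measurement.descriptor, self.basis)
        self.measurements[measurement.descriptor] = measurement

    def validate_closure(self, tolerance: float = 0.5) -> float:
        """Check detected relative abundances sum to 100 +/- ``tolerance``.

        Returns the actual total. Raises :class:`ClosureError` on violation.
        """
        total = sum(self.detected.values())
        if abs(total - 100.0) > tolerance:
            raise ClosureError(
                f"detected abundances sum to {total:.4f}, expected 100 +/- {tolerance}"
            )
        return total


@dataclass
class ExperimentSeries:
    """One strain's replicated profiles across a varied condition."""

    strain_id: str
    condition_variable: ConditionVariable
    profiles: list[SampleProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("series requires at least one profile")
        for p in self.profiles:
            if p.strain_id != self.strain_id:
                raise ValueError("profiles mix strain ids")
            if p.condition_variable != self.condition_variable:
                raise ValueError("profiles mix condition variables")
        bases = {p.basis for p in self.profiles}
        if len(bases) > 1:
            raise BasisError("profiles mix normalization bases")
        if len(self.levels) < 2:
            raise ValueError("series requires >= 2 distinct condition levels")

    @property
    def basis(self) -> Basis:
        return self.profiles[0].basis

    @property
    def levels(self) -> list[float]:
        return sorted({p.condition_value for p in self.profiles})

    def at_level(self, level: float) -> list[SampleProfile]:
        return [p for p in self.profiles if p.condition_value == level]

    def descriptor_universe(self) -> list[FattyAcidDescriptor]:
        seen: dict[FattyAcidDescriptor, None] = {}
        for p in self.profiles:
            for d in p.measurements:
                seen.setdefault(d, None)
        return list(seen)


@dataclass(frozen=True)
class AggregateStat:
    mean: float
    sd: float | None  # None when only one detected replicate
    n_detected: int


@dataclass
class AggregateProfile:
    """Per-descriptor mean +/- sd across replicates at one condition level."""

    strain_id: str
    condition_variable: ConditionVariable
    condition_value: float
    basis: Basis
    n_replicates: int
    stats: dict[FattyAcidDescriptor, AggregateStat] = field(default_factory=dict)

    def mean_for(self, descriptor: FattyAcidDescriptor) -> float | None:
        stat = self.stats.get(descriptor)
        return None if stat is None else stat.mean

    @property
    def means(self) -> dict[FattyAcidDescriptor, float]:
        return {d: s.mean for d, s in self.stats.items()}


@dataclass(frozen=True)
class ClassTotals:
    """Summed abundance per branching class (the I, A, N of the indices)."""

    iso: float
    anteiso: float
    normal: float

    def __iter__(self):
        return iter((self.iso, self.anteiso, self.normal))


def normalize(
    measurements: Iterable[Measurement],
    basis: Basis,
    *,
    strain_id: str = "",
    condition_variable: ConditionVariable = ConditionVariable.TEMPERATURE_C,
    condition_value: float = float("nan"),
    replicate_id: str = "",
    fixed_condition: str = "",
) -> SampleProfile:
    """Close a set of peak areas to a 100% relative-abundance composition.

    Each detected area becomes ``100 * area / total`` where the total runs
    over the detected measurements compatible with ``basis``. Undetected
    entries are preserved as undetected.
    """
    measurements = list(measurements)
    for m in measurements:
        if m.value_kind is not ValueKind.PEAK_AREA:
            raise ValueError("normalize expects peak_area measurements")
        _check_basis_compatible(m.descriptor, basis)
    total = sum(m.value for m in measurements if m.detected)
    if not measurements or total <= 0:
        raise DegenerateInputError("no positive peak areas to normalize")
    profile = SampleProfile(
        strain_id=strain_id,
        condition_variable=condition_variable,
        condition_value=condition_value,
        replicate_id=replicate_id,
        basis=basis,
        fixed_condition=fixed_condition,
    )
    for m in measurements:
        if m.detected:
            profile.add(
                Measurement(
                    descriptor=m.descriptor,
                    value=100.0 * m.value / total,
                    value_kind=ValueKind.RELATIVE_ABUNDANCE,
                    detected=True,
                )
            )
        else:
            profile.add(
                Measurement(
                    descriptor=m.descriptor,
                    value=None,
                    value_kind=ValueKind.RELATIVE_ABUNDANCE,
                    detected=False,
                )
            )
    return profile


def in_index_scope(descriptor: FattyAcidDescriptor) -> bool:
    """True for 3-OH homologues in the C10-C18 index scope."""
    return (
        descriptor.hydroxylated_3
        and INDEX_SCOPE_MIN_CARBON
        <= descriptor.carbon_number
        <= INDEX_SCOPE_MAX_CARBON
    )


def class_totals(
    values: SampleProfile | AggregateProfile | Mapping[FattyAcidDescriptor, float],
    *,
    restrict_scope: bool = True,
) -> ClassTotals:
    """Sum detected abundances per branching class.

    Accepts a replicate profile, an aggregate (uses means), or a plain
    descriptor->value mapping. Undetected homologues contribute 0; by
    default the sum is restricted to 3-OH homologues in C10-C18.
    """
    if isinstance(values, SampleProfile):
        mapping = values.detected
    elif isinstance(values, AggregateProfile):
        mapping = values.means
    else:
        mapping = dict(values)
    sums = {Branching.ISO: 0.0, Branching.ANTEISO: 0.0, Branching.NORMAL: 0.0}
    for desc, value in mapping.items():
        if restrict_scope and not in_index_scope(desc):
            continue
        sums[desc.branching] += value
    return ClassTotals(
        iso=sums[Branching.ISO],
        anteiso=sums[Branching.ANTEISO],
        normal=sums[Branching.NORMAL],
    )


def aggregate_replicates(
    profiles: Sequence[SampleProfile],
    *,
    zero_impute_undetected: bool = False,
) -> AggregateProfile:
    """Collapse replicate profiles at one level into mean +/- sample sd.

    Undetected values are treated as missing (dropped per descriptor)
    unless ``zero_impute_undetected`` substitutes 0. Sample sd uses the
    n-1 denominator; with a single detected replicate sd is ``None``.
    """
    if not profiles:
        raise ValueError("aggregate_replicates requires >= 1 profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.basis != first.basis:
            raise BasisError("cannot aggregate profiles on mixed bases")
        if p.strain_id != first.strain_id:
            raise ValueError("cannot aggregate profiles from different strains")
        if not math.isclose(
            p.condition_value, first.condition_value, rel_tol=0, abs_tol=1e-12
        ):
            raise ValueError("cannot aggregate profiles at different levels")
    universe: dict[FattyAcidDescriptor, None] = {}
    for p in profiles:
        for d in p.measurements:
            universe.setdefault(d, None)
    stats: dict[FattyAcidDescriptor, AggregateStat] = {}
    for desc in universe:
        obs: list[float] = []
        for p in profiles:
            v = p.value_for(desc)
            if v is not None:
                obs.append(v)
            elif zero_impute_undetected:
                obs.append(0.0)
        if not obs:
            continue  # n.d. in every replicate
        mean = statistics.fmean(obs)
        sd = statistics.stdev(obs) if len(obs) > 1 else None
        stats[desc] = AggregateStat(mean=mean, sd=sd, n_detected=len(obs))
    return AggregateProfile(
        strain_id=first.strain_id,
        condition_variable=first.condition_variable,
        condition_value=first.condition_value,
        basis=first.basis,
        n_replicates=len(profiles),
        stats=stats,
    )
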