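"""Response-criteria rule sets and the patient-level classification engine.

Four rule sets are provided.  PERCIST 1.0 operates on SULpeak with the
classical thresholds: progression requires an increase of at least 30 %
*and* an absolute increase of at least 0.8 SUL units (or target-lesion size
growth of 30 %, or any new avid lesion); partial response requires a
decrease of at least 30 % and at least 0.8 SUL units.  mPERCIST and
PERCISTmax transfer the same thresholds to SUVpeak and SUVmax respectively
(the 0.8 absolute floor for partial response is specific to SUL units and
therefore only enforced for PERCIST 1.0).  EORTC operates on SUVmax with
±25 % thresholds and a strict >20 % longest-diameter rule for extent
progression.  New avid lesions mean progression under every rule set.

Precedence when rules conflict is PMD > CMR > PMR > SMD: a new lesion on a
shrinking target is still progression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from petresponse.types import Category, Dichotomy


@dataclass(frozen=True)
class CriteriaSpec:
    """Thresholds and metric of one response-criteria rule set.

    Attributes
    ----------
    name : str
        One of ``percist10``, ``mpercist``, ``percistmax``, ``eortc``.
    metric : str
        Uptake metric the rules read (``sulpeak``/``suvpeak``/``suvmax``).
    pmd_pct, pmr_pct : float
        Percent-change thresholds for progression / partial response
        (inclusive, "at least").
    pmd_abs_floor : float or None
        Minimal absolute uptake increase additionally required for
        uptake-based progression (0.8 for the PERCIST family).
    pmr_abs_floor : float or None
        Minimal absolute decrease additionally required for partial
        response (0.8, PERCIST 1.0 only).
    size_pmd_pct : float
        Size-progression threshold (target-lesion size for PERCIST,
        longest diameter for EORTC).
    size_strict : bool
        Whether the size threshold is strict (> rather than >=).
    """

    name: str
    metric: str
    pmd_pct: float
    pmr_pct: float
    pmd_abs_floor: float | None
    pmr_abs_floor: float | None
    size_pmd_pct: float
    size_strict: bool

    def __post_init__(self) -> None:
        if self.metric not in ("sulpeak", "suvpeak", "suvmax"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.pmd_pct <= 0 or self.pmr_pct <= 0 or self.size_pmd_pct <= 0:
            raise ValueError("thresholds must be > 0")


PERCIST10 = CriteriaSpec("percist10", "sulpeak", 30.0, 30.0, 0.8, 0.8, 30.0, False)
MPERCIST = CriteriaSpec("mpercist", "suvpeak", 30.0, 30.0, 0.8, None, 30.0, False)
PERCISTMAX = CriteriaSpec("percistmax", "suvmax", 30.0, 30.0, 0.8, None, 30.0, False)
EORTC = CriteriaSpec("eortc", "suvmax", 25.0, 25.0, None, None, 20.0, True)

CRITERIA: dict[str, CriteriaSpec] = {
    spec.name: spec for spec in (PERCIST10, MPERCIST, PERCISTMAX, EORTC)
}

PERCIST_FAMILY = ("percist10", "mpercist", "percistmax")


def percent_change(baseline_value: float, followup_value: float) -> float:
    """Percent change of a metric from baseline to follow-up.

    Raises ``ValueError`` for non-positive baselines: a percent change is
    undefined when there is no baseline uptake to change from.
    """
    if not baseline_value > 0:
        raise ValueError(f"baseline value must be > 0, got {baseline_value}")
    return 100.0 * (followup_value - baseline_value) / baseline_value


def _classify(
    spec: CriteriaSpec,
    baseline_value: float,
    followup_value: float,
    *,
    new_lesion: bool,
    size_change_pct: float | None,
    background_level: float | None,
    followup_lesion_values: Sequence[float] | None,
    all_resolved: bool | None,
) -> Category:
    change = percent_change(baseline_value, followup_value)
    abs_change = followup_value - baseline_value

    uptake_pmd = change >= spec.pmd_pct and (
        spec.pmd_abs_floor is None or abs_change >= spec.pmd_abs_floor
    )
    size_pmd = size_change_pct is not None and (
        size_change_pct > spec.size_pmd_pct
        if spec.size_strict
        else size_change_pct >= spec.size_pmd_pct
    )
    if uptake_pmd or size_pmd or new_lesion:
        return Category.PMD

    values = (
        tuple(followup_lesion_values)
        if followup_lesion_values is not None
        else (followup_value,)
    )
    below = background_level is not None and all(v <= background_level for v in values)
    if all_resolved is None:
        is_cmr = below
    else:
        is_cmr = all_resolved and (background_level is None or below)
    if is_cmr:
        return Category.CMR

    uptake_pmr = change <= -spec.pmr_pct and (
        spec.pmr_abs_floor is None or -abs_change >= spec.pmr_abs_floor
    )
    if uptake_pmr:
        return Category.PMR
    return Category.SMD


def classify_percist_family(
    spec: CriteriaSpec,
    baseline_value: float,
    followup_value: float,
    *,
    new_lesion: bool = False,
    target_size_change_pct: float | None = None,
    background_level: float | None = None,
    followup_lesion_values: Sequence[float] | None = None,
    all_resolved: bool | None = None,
) -> Category:
    """Classify one patient under a PERCIST-family rule set.

    ``baseline_value``/``followup_value`` are target values on the spec's
    own metric.  ``followup_lesion_values`` are all index lesions'
    follow-up values (for the complete-response check); ``all_resolved``
    is the reader-level call that every lesion is indistinguishable from
    background — when given, complete response additionally requires every
    lesion at or below ``background_level`` (liver reference).
    """
    if spec.name not in PERCIST_FAMILY:
        raise ValueError(f"{spec.name!r} is not a PERCIST-family rule set")
    return _classify(
        spec,
        baseline_value,
        followup_value,
        new_lesion=new_lesion,
        size_change_pct=target_size_change_pct,
        background_level=background_level,
        followup_lesion_values=followup_lesion_values,
        all_resolved=all_resolved,
    )


def classify_eortc(
    baseline_suvmax: float,
    followup_suvmax: float,
    *,
    new_lesion: bool = False,
    longest_diameter_change_pct: float | None = None,
    background_level: float | None = None,
    followup_lesion_values: Sequence[float] | None = None,
    all_resolved: bool | None = None,
) -> Category:
    """Classify one patient under the EORTC rules (SUVmax, ±25 %, >20 % diameter)."""
    return _classify(
        EORTC,
        baseline_suvmax,
        followup_suvmax,
        new_lesion=new_lesion,
        size_change_pct=longest_diameter_change_pct,
        background_level=background_level,
        followup_lesion_values=followup_lesion_values,
        all_resolved=all_resolved,
    )


def dichotomize(category: Category) -> Dichotomy:
    """Collapse the four response categories into disease control vs progression."""
    category = Category(category)
    return Dichotomy.PD if category is Category.PMD else Dichotomy.DC


def resolve_criteria(names: Iterable[str] | None) -> list[CriteriaSpec]:
    """Map criteria names to specs, defaulting to all four rule sets."""
    if names is None:
        return list(CRITERIA.values())
    specs = []
    for name in names:
        if name not in CRITERIA:
            raise ValueError(f"unknown criteria {name!r}; choose from {sorted(CRITERIA)}")
        specs.append(CRITERIA[name])
    return specs
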