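"""Variant-prioritization filter chain.

Classified calls are reduced to the reportable pathogenic / likely
pathogenic (P/LP) set that all downstream statistics consume. The chain is
an ordered, configurable rule list; the two built-in rules are panel
membership and ACMG class. Low-penetrance alleles (common alleles with a
reduced probability of causing disease, e.g. GJB2 c.109G>A) are *flagged*
rather than dropped, so downstream rates can be reported both with and
without them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .model import AcmgClass, EcsError, PanelEntry, VariantCall

#: Machine-readable drop reasons emitted by the built-in rules.
REASON_OFF_PANEL = "off-panel"
REASON_CLASS_EXCLUDED = "class-excluded"

# A rule maps a call to a drop reason, or None to keep it.
FilterRule = Callable[[VariantCall], Optional[str]]


@dataclass(frozen=True)
class FilterConfig:
    """Configuration of the prioritization chain.

    keep_classes defaults to {P, LP}: only pathogenic and likely pathogenic
    calls are reportable in a carrier-screening context.
    """

    keep_classes: frozenset[AcmgClass] = frozenset({AcmgClass.P, AcmgClass.LP})
    restrict_to_panel: bool = True
    extra_rules: tuple[FilterRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.keep_classes:
            raise EcsError("keep_classes must be non-empty")


@dataclass
class FilteredCallSet:
    """Partition of the input calls into retained and dropped (with reasons)."""

    retained: list[VariantCall] = field(default_factory=list)
    dropped: list[tuple[VariantCall, str]] = field(default_factory=list)
    low_penetrance_flags: dict[VariantCall, bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.retained) + len(self.dropped)

    def low_penetrance_calls(self) -> list[VariantCall]:
        return [c for c in self.retained if self.low_penetrance_flags.get(c, False)]


def flag_low_penetrance(call: VariantCall, panel: dict[str, PanelEntry]) -> bool:
    """True iff the call's allele is in its gene's low-penetrance registry."""
    entry = panel.get(call.gene)
    if entry is None:
        raise EcsError(f"gene {call.gene} is not on the panel")
    return call.allele_id in entry.low_penetrance_alleles


def apply_filters(
    calls: Iterable[VariantCall],
    panel: dict[str, PanelEntry],
    config: FilterConfig | None = None,
) -> FilteredCallSet:
    """Run the prioritization chain over ``calls``.

    Deterministic: input order is preserved in both partitions, and each
    dropped call carries exactly one reason — the first rule that rejected
    it (panel membership is checked before ACMG class, mirroring a
    prioritization funnel that first restricts to the designed target
    regions).
    """
    config = config or FilterConfig()
    result = FilteredCallSet()
    rules: list[FilterRule] = []
    if config.restrict_to_panel:
        rules.append(lambda c: None if c.gene in panel else REASON_OFF_PANEL)
    rules.append(
        lambda c: None if c.acmg_class in config.keep_classes else REASON_CLASS_EXCLUDED
    )
    rules.extend(config.extra_rules)

    for call in calls:
        reason = next((r for r in (rule(call) for rule in rules) if r is not None), None)
        if reason is None:
            result.retained.append(call)
            result.low_penetrance_flags[call] = (
                flag_low_penetrance(call, panel) if call.gene in panel else False
            )
        else:
            result.dropped.append((call, reason))
    return result
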