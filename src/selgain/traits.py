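"""Canonical trait registry for Egyptian cotton (Gossypium barbadense) breeding trials.

Eleven traits are tracked: seven yield traits recorded from the F2 generation
on, and four fiber traits recorded in the replicated F3/F4 trials only.
"""

from __future__ import annotations

# Canonical order used everywhere (matrices, reports, CSV columns).
CANONICAL_TRAITS: tuple[str, ...] = (
    "LY/P",  # lint cotton yield per plant (g)
    "B/P",   # bolls per plant (count)
    "BW",    # boll weight (g)
    "S/B",   # seeds per boll (count)
    "SI",    # seed index: 100-seed weight (g)
    "LP%",   # lint percentage (%)
    "LI",    # lint index: lint mass per 100 seeds (g)
    "UI%",   # fiber uniformity index (%)
    "FL",    # fiber length at 2.5% span length (mm)
    "PI",    # Pressley index: fiber bundle strength
    "MR",    # micronaire reading: fiber fineness (lower is desirable)
)

#: Traits recorded on unreplicated F2 plants (fiber traits are not measured in F2).
F2_TRAITS: tuple[str, ...] = CANONICAL_TRAITS[:7]

TRAIT_UNITS: dict[str, str] = {
    "LY/P": "g", "B/P": "count", "BW": "g", "S/B": "count", "SI": "g",
    "LP%": "%", "LI": "g", "UI%": "%", "FL": "mm", "PI": "index", "MR": "index",
}

#: +1 when larger values are favourable, -1 when smaller values are
#: favourable.  Only micronaire is improved downward.
TRAIT_DIRECTIONS: dict[str, int] = {t: 1 for t in CANONICAL_TRAITS}
TRAIT_DIRECTIONS["MR"] = -1

#: Traits constrained to the open interval (0, 100).
PERCENT_TRAITS: frozenset[str] = frozenset({"LP%", "UI%"})

#: Count-like traits constrained to be non-negative.
COUNT_TRAITS: frozenset[str] = frozenset({"B/P", "S/B"})


def canonical_subset(traits) -> tuple[str, ...]:
    """Return *traits* reordered into the canonical order.

    Raises ``ValueError`` for names outside the registry.
    """
    traits = set(traits)
    unknown = traits - set(CANONICAL_TRAITS)
    if unknown:
        raise ValueError(f"unknown trait name(s): {sorted(unknown)}")
    return tuple(t for t in CANONICAL_TRAITS if t in traits)
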