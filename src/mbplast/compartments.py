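"""Mushroom-body compartment identifiers.

Nine MB-lobe compartments are imaged in both dopaminergic neurons (DANs)
and Kenyon cells (KCs); a few extra regions are genotype-specific: the
ellipsoid body (EB) and fan-shaped body (FB) appear only in DAN
recordings, the insulin-producing cells (IPCs) only in KC recordings,
and the lobe junction in both.
"""

from __future__ import annotations

# Order is fixed; pattern vectors use exactly this component order.
SHARED_COMPARTMENTS: tuple[str, ...] = (
    "α1/α'1", "β2", "β'1", "β'2", "γ1", "γ2", "γ3", "γ4", "γ5",
)

JUNCTION = "junction"

EXTRA_BY_GENOTYPE: dict[str, tuple[str, ...]] = {
    "DAN": (JUNCTION, "EB", "FB"),
    "KC": (JUNCTION, "IPCs"),
}

GENOTYPES = ("DAN", "KC")


def compartments_for(genotype: str) -> tuple[str, ...]:
    """All ROI labels available for a genotype (shared + genotype-specific)."""
    if genotype not in EXTRA_BY_GENOTYPE:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    return SHARED_COMPARTMENTS + EXTRA_BY_GENOTYPE[genotype]


def is_shared(compartment: str) -> bool:
    return compartment in SHARED_COMPARTMENTS
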