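"""Small closed-form statistics for the flow-cytometry and flow-chamber
assays.

* specific median fluorescence intensity (sMFI): antigen staining MFI minus
  the matched isotype/negative-control MFI — a plain difference, reported
  as-is (a negative value means the stain fell below its control and is
  flagged, not clamped);
* transmigration percentage: transmigrated / (adherent + transmigrated)
  leukocytes, as a percentage;
* normalization of rolling/adhesion/transmigration counts to a reference
  endothelium (reference = 100 %).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "MfiPair",
    "FlowAssayCounts",
    "smfi",
    "transmigration_pct",
    "normalize_to_reference",
    "mean_transmigration_pct",
]


@dataclass(frozen=True)
class MfiPair:
    mfi_specific: float
    mfi_control: float

    def __post_init__(self) -> None:
        for v in (self.mfi_specific, self.mfi_control):
            if not (v == v and abs(v) != float("inf")):
                raise ValidationError("MFI values must be finite")
            if v < 0:
                raise ValidationError("MFI values must be non-negative")


@dataclass(frozen=True)
class FlowAssayCounts:
    condition: str
    rolling: int = 0
    adherent: int = 0
    transmigrated: int = 0

    def __post_init__(self) -> None:
        for name in ("rolling", "adherent", "transmigrated"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class SmfiResult:
    value: float
    below_control: bool


def smfi(pair: MfiPair) -> SmfiResult:
    """Specific MFI = specific staining MFI − negative-control MFI."""
    value = pair.mfi_specific - pair.mfi_control
    return SmfiResult(value=value, below_control=value < 0)


def transmigration_pct(counts: FlowAssayCounts) -> float:
    """Percentage of interacting (adherent + transmigrated) cells that
    transmigrated.  Undefined when no cells interacted."""
    interacting = counts.adherent + counts.transmigrated
    if interacting == 0:
        raise ValidationError(
            f"{counts.condition}: transmigration undefined (no interacting cells)"
        )
    return 100.0 * counts.transmigrated / interacting


def mean_transmigration_pct(rows: list[FlowAssayCounts]) -> float:
    """Mean of per-row transmigration percentages (per-field summary)."""
    if not rows:
        raise ValidationError("no rows")
    return sum(transmigration_pct(r) for r in rows) / len(rows)


def normalize_to_reference(
    counts: FlowAssayCounts, reference: FlowAssayCounts
) -> dict[str, float | None]:
    """Each count as a percentage of the reference endothelium
    (reference = 100 %).  A zero reference field leaves that field
    undefined (``None``); the others are still computed."""
    out: dict[str, float | None] = {}
    for name in ("rolling", "adherent", "transmigrated"):
        ref = getattr(reference, name)
        if ref == 0:
            out[name] = None
        else:
            out[name] = 100.0 * getattr(counts, name) / ref
    return out
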