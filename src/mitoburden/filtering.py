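"""Call-level quality filters for haploid mtDNA variant calls.

Two filters implement the study's quality policy:

* **genotype filter** — mtDNA is haploid, so a heterozygous-looking call is
  an unreliable signature of heteroplasmy or noise and is discarded; only
  hom-alt calls pass.
* **strand-balance filter** — a real variant should be supported by reads on
  both sequencing strands.  With ``f = min(alt_fwd, alt_rev) / (alt_fwd +
  alt_rev)``, a call fails when ``f`` is strictly below the threshold
  (default 10%); a call exactly at the threshold passes.  The denominator is
  alt-supporting reads only, so a reference-heavy site cannot mask the
  imbalance.

Filtering is per sample-call: a variant stays in the study as long as at
least one sample's call survives.  Passing calls are then aggregated into
study-wide variants keyed by (position, ref, alt) with per-variant carrier
counts ``n_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import ValidationError
from .io_formats import SampleCall, VariantKey

FILTER_REASONS = (
    "het_genotype",
    "strand_imbalance",
    "no_alt_support",
    "missing_genotype",
    "pass",
)


@dataclass(frozen=True)
class FilterDecision:
    call: SampleCall
    passed: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise ValidationError(f"unknown filter reason {self.reason!r}")
        if self.passed != (self.reason == "pass"):
            raise ValidationError("passed flag inconsistent with reason")


@dataclass
class AggregatedVariant:
    """A study-wide variant: distinct (position, ref, alt) with its carriers."""

    key: VariantKey
    carriers: Tuple[str, ...]
    annotations: Optional["AnnotationBundle"] = None  # noqa: F821 (filled later)

    def __post_init__(self) -> None:
        if len(self.carriers) == 0:
            raise ValidationError(f"variant {self.key} has no carriers")
        if len(set(self.carriers)) != len(self.carriers):
            raise ValidationError(f"variant {self.key} lists duplicate carriers")

    @property
    def carrier_count(self) -> int:
        return len(self.carriers)


def genotype_filter(
    calls: Iterable[SampleCall],
) -> Tuple[List[SampleCall], List[FilterDecision]]:
    """Keep hom-alt calls; log het and missing genotypes as failures.

    Hom-ref calls are not variant calls and are dropped without a log entry.
    """
    passing: List[SampleCall] = []
    log: List[FilterDecision] = []
    for call in calls:
        if call.genotype_class == "hom_alt":
            passing.append(call)
            log.append(FilterDecision(call, True, "pass"))
        elif call.genotype_class == "het":
            log.append(FilterDecision(call, False, "het_genotype"))
        elif call.genotype_class == "missing":
            log.append(FilterDecision(call, False, "missing_genotype"))
        # hom_ref: silently dropped
    return passing, log


def strand_balance_filter(
    calls: Iterable[SampleCall], min_fraction: float = 0.10
) -> Tuple[List[SampleCall], List[FilterDecision]]:
    """Discard calls whose weaker strand carries < ``min_fraction`` of the
    alt-supporting reads; zero alt support fails with its own reason."""
    if not 0.0 <= min_fraction <= 0.5:
        raise ValidationError(
            f"min_fraction must be in [0, 0.5], got {min_fraction}"
        )
    passing: List[SampleCall] = []
    log: List[FilterDecision] = []
    for call in calls:
        total = call.alt_fwd + call.alt_rev
        if total == 0:
            log.append(FilterDecision(call, False, "no_alt_support"))
            continue
        f = min(call.alt_fwd, call.alt_rev) / total
        if f < min_fraction:
            log.append(FilterDecision(call, False, "strand_imbalance"))
        else:
            passing.append(call)
            log.append(FilterDecision(call, True, "pass"))
    return passing, log


def aggregate(calls: Iterable[SampleCall]) -> List[AggregatedVariant]:
    """Collapse passing calls into study-wide variants with carrier counts.

    A sample contributing several passing calls for the same key counts once.
    Output is sorted by (position, ref, alt).
    """
    carriers: Dict[VariantKey, Dict[str, None]] = {}
    for call in calls:
        carriers.setdefault(call.key, {})[call.sample_id] = None
    return [
        AggregatedVariant(key=key, carriers=tuple(samples))
        for key, samples in sorted(carriers.items())
    ]


@dataclass(frozen=True)
class CoverageSummary:
    breadth: float
    mean_depth: float
    threshold: int


def coverage_breadth(depths: Sequence[int], threshold: int) -> CoverageSummary:
    """Fraction of positions with depth ≥ threshold, plus mean depth."""
    depths = list(depths)
    if len(depths) == 0:
        raise ValidationError("empty depth vector")
    if any(d < 0 for d in depths):
        raise ValidationError("depths must be non-negative")
    covered = sum(1 for d in depths if d >= threshold)
    return CoverageSummary(
        breadth=covered / len(depths),
        mean_depth=sum(depths) / len(depths),
        threshold=threshold,
    )


def decisions_to_rows(log: Iterable[FilterDecision]) -> List[dict]:
    """Render a decision log as rows for a TSV discard log."""
    return [
        {
            "sample": d.call.sample_id,
            "position": d.call.position,
            "ref": d.call.ref,
            "alt": d.call.alt,
            "reason": d.reason,
        }
        for d in log
        if not d.passed
    ]
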