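"""Per-gene variant-enrichment statistics.

Two rates summarise mitochondrial variability at the gene level.  For a gene
*x* of length *l_x* (bp) in which *N_x* distinct variants were observed:

* global variant enrichment rate  ``r_g = N_x / l_x × 1000``  (variants/Mb);
* weighted variant enrichment rate ``r_w = Σ_i n_i / l_x``, where *n_i* is
  the carrier count of the *i*-th variant of the gene.

``r_w`` is reported per bp by default, which is the scale of the published
per-gene table (e.g. 0.92 for a gene with carrier-sum 627 over 682 bp); a
``per_Mb`` switch multiplies by 1000 for the formula-as-stated scale.

tRNA genes are excluded by default: their very small lengths make the rates
unstable.  Genes with zero observed variants stay in the report with zeros
so the denominator of the means is explicit.

Normality of the per-gene ``r_g`` values is checked with the Shapiro–Wilk
test, which licenses placing individual genes on a fitted normal
distribution (``percentile_position`` with the default ``normal_model``
method); three rank-based percentile conventions are exposed alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import MitoGeneModel
from .errors import ValidationError
from .filtering import AggregatedVariant

PERCENTILE_METHODS = ("normal_model", "empirical_strict", "hazen", "weibull")
RW_SCALES = ("per_bp", "per_Mb")


def global_enrichment(n_variants: int, gene_length: int) -> float:
    """``r_g = N_x / l_x × 1000`` variants per Mb (unrounded)."""
    if gene_length <= 0:
        raise ValidationError(f"gene length must be > 0, got {gene_length}")
    if n_variants < 0:
        raise ValidationError("variant count must be non-negative")
    return n_variants / gene_length * 1000.0


def weighted_enrichment(
    carrier_counts: Sequence[int], gene_length: int, scale: str = "per_bp"
) -> float:
    """``r_w = Σ n_i / l_x`` (per bp), ×1000 under ``per_Mb``."""
    if gene_length <= 0:
        raise ValidationError(f"gene length must be > 0, got {gene_length}")
    if scale not in RW_SCALES:
        raise ValidationError(f"unknown r_w scale {scale!r}")
    if any(c < 1 for c in carrier_counts):
        raise ValidationError("carrier counts must be ≥ 1")
    rw = sum(carrier_counts) / gene_length
    return rw * 1000.0 if scale == "per_Mb" else rw


@dataclass(frozen=True)
class EnrichmentRow:
    symbol: str
    biotype: str
    length: int
    n_variants: int
    carrier_sum: int
    r_g: float
    r_w: float
    percentile: Optional[float] = None


@dataclass
class EnrichmentReport:
    rows: List[EnrichmentRow]
    mean_r_g: float
    mean_r_w: float
    shapiro_W: Optional[float]
    shapiro_p: Optional[float]
    excluded_biotypes: Tuple[str, ...]
    rw_scale: str

    def row(self, symbol: str) -> EnrichmentRow:
        for r in self.rows:
            if r.symbol == symbol:
                return r
        raise KeyError(symbol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "symbol": r.symbol,
                    "biotype": r.biotype,
                    "length": r.length,
                    "n_variants": r.n_variants,
                    "carrier_sum": r.carrier_sum,
                    "r_g": round(r.r_g, 1),
                    "r_w": round(r.r_w, 2),
                    "percentile": (
                        round(r.percentile, 1) if r.percentile is not None else None
                    ),
                }
                for r in self.rows
            ]
        )


def normality_test(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro–Wilk test; requires ≥3 non-identical values."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 3:
        raise ValidationError("Shapiro–Wilk needs at least 3 values")
    if np.ptp(values) == 0:
        raise ValidationError("Shapiro–Wilk undefined for constant input")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def percentile_position(
    value: float, values: Sequence[float], method: str = "normal_model"
) -> float:
    """Percentile (0–100) of ``value`` within ``values``.

    * ``normal_model``: 100·Φ((value − mean)/sd), sample sd (n−1);
    * ``empirical_strict``: 100·(# strictly below)/n;
    * ``hazen``: 100·(rank − 0.5)/n;
    * ``weibull``: 100·rank/(n + 1);

    where rank is the count of values ≤ value.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValidationError("percentile needs at least 2 values")
    if method not in PERCENTILE_METHODS:
        raise ValidationError(f"unknown percentile method {method!r}")
    n = vals.size
    if method == "normal_model":
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValidationError("normal-model percentile undefined for zero sd")
        return float(100.0 * stats.norm.cdf((value - vals.mean()) / sd))
    if method == "empirical_strict":
        return float(100.0 * np.sum(vals < value) / n)
    rank = int(np.sum(vals <= value))
    if method == "hazen":
        return float(100.0 * (rank - 0.5) / n)
    return float(100.0 * rank / (n + 1))  # weibull


def _build_report(
    records: Iterable[Tuple[str, str, int, int, Sequence[int]]],
    rw_scale: str,
    percentile_method: Optional[str],
    exclude_biotypes: Tuple[str, ...],
    rw_override: Optional[Mapping[str, float]] = None,
) -> EnrichmentReport:
    rows = []
    for symbol, biotype, length, n_var, counts in records:
        r_g = global_enrichment(n_var, length)
        if rw_override is not None and symbol in rw_override:
            r_w = rw_override[symbol]
        else:
            r_w = weighted_enrichment(counts, length, rw_scale) if counts else 0.0
        rows.append(
            EnrichmentRow(
                symbol=symbol,
                biotype=biotype,
                length=length,
                n_variants=n_var,
                carrier_sum=int(sum(counts)),
                r_g=r_g,
                r_w=r_w,
            )
        )
    if not rows:
        return EnrichmentReport([], 0.0, 0.0, None, None, exclude_biotypes, rw_scale)
    rgs = [r.r_g for r in rows]
    rws = [r.r_w for r in rows]
    try:
        W, p = normality_test(rgs)
    except ValidationError:
        W = p = None
    if percentile_method is not None and len(rows) >= 2:
        try:
            rows = [
                EnrichmentRow(
                    **{
                        **r.__dict__,
                        "percentile": percentile_position(r.r_g, rgs, percentile_method),
                    }
                )
                for r in rows
            ]
        except ValidationError:
            pass
    return EnrichmentReport(
        rows=rows,
        mean_r_g=float(np.mean(rgs)),
        mean_r_w=float(np.mean(rws)),
        shapiro_W=W,
        shapiro_p=p,
        excluded_biotypes=exclude_biotypes,
        rw_scale=rw_scale,
    )


def enrichment_table(
    variants: Iterable[AggregatedVariant],
    model: MitoGeneModel,
    exclude_biotypes: Iterable[str] = ("Mt_tRNA",),
    rw_scale: str = "per_bp",
    percentile_method: Optional[str] = "normal_model",
) -> EnrichmentReport:
    """Per-gene enrichment report from gene-annotated aggregated variants.

    A variant inside overlapping genes contributes once to each gene's tally.
    Variants must carry annotations whose gene symbols exist in the model.
    """
    exclude = tuple(exclude_biotypes)
    known = set(model.symbols)
    per_gene: Dict[str, List[AggregatedVariant]] = {s: [] for s in known}
    for v in variants:
        if v.annotations is None:
            raise ValidationError(f"variant {v.key} is not annotated")
        for symbol in v.annotations.genes:
            if symbol not in known:
                raise ValidationError(f"unknown gene symbol {symbol!r} in variant {v.key}")
            per_gene[symbol].append(v)
    records = []
    for gene in model:
        if gene.biotype in exclude:
            continue
        vs = per_gene[gene.symbol]
        records.append(
            (
                gene.symbol,
                gene.biotype,
                gene.printed_length,
                len(vs),
                [v.carrier_count for v in vs],
            )
        )
    return _build_report(records, rw_scale, percentile_method, exclude)


def report_from_counts(
    gene_table: pd.DataFrame,
    exclude_biotypes: Iterable[str] = ("Mt_tRNA",),
    percentile_method: Optional[str] = "normal_model",
) -> EnrichmentReport:
    """Enrichment report directly from a per-gene counts table.

    The table needs columns ``symbol``, ``biotype``, ``length`` and
    ``variant_count``; ``r_g`` is recomputed from them.  An optional
    ``rw_printed`` column supplies per-gene ``r_w`` values when the underlying
    carrier counts are not available (the published per-gene summary is of
    this form).
    """
    for col in ("symbol", "biotype", "length", "variant_count"):
        if col not in gene_table.columns:
            raise ValidationError(f"counts table lacks column {col!r}")
    exclude = tuple(exclude_biotypes)
    df = gene_table[~gene_table["biotype"].isin(exclude)]
    rw_override = None
    if "rw_printed" in df.columns:
        rw_override = {
            str(r["symbol"]): float(r["rw_printed"]) for _, r in df.iterrows()
        }
    records = [
        (str(r["symbol"]), str(r["biotype"]), int(r["length"]), int(r["variant_count"]), [])
        for _, r in df.iterrows()
    ]
    return _build_report(records, "per_bp", percentile_method, exclude, rw_override)


def rank_genes(report: EnrichmentReport) -> List[EnrichmentRow]:
    """Rows ordered by r_g descending; ties broken by symbol (A→Z)."""
    return sorted(report.rows, key=lambda r: (-r.r_g, r.symbol))
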