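"""Variant annotation: gene context, catalog status, conservation, codon and
amino-acid changes under the vertebrate mitochondrial genetic code, predictor
concordance, and homopolymer context.

Codon changes are rendered the way mitochondrial studies print them: both
codons lowercase except the altered base, e.g. ``aAc/aGc`` for an A→G change
at the second codon position.  Translation uses NCBI genetic code table 2
(vertebrate mitochondrial: ATA→M, TGA→W, AGA/AGG→stop).

For genes on the light strand (strand ``-``), heavy-strand alleles are
complemented into the coding frame before codon extraction, so a printed
heavy-strand T→C change in such a gene appears as an A→G coding change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from Bio.Data import CodonTable

from .core_model import GeneRecord, MitoGenome, MitoGeneModel
from .errors import ValidationError
from .filtering import AggregatedVariant
from .io_formats import VariantKey

VARIANT_TYPES = ("substitution", "insertion", "deletion", "complex")
REGION_CLASSES = ("coding_exon", "non_coding_exon", "intergenic")
EFFECTS = (
    "synonymous",
    "missense",
    "nonsense",
    "stop_loss",
    "non_coding",
    "intergenic",
    "frameshift_candidate",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# NCBI translation table 2 (vertebrate mitochondrial) via biopython.
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_CODON_TO_AA: Dict[str, str] = dict(_MITO_TABLE.forward_table)
for _stop in _MITO_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Returns a one-letter amino acid, or ``*`` for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= set("ACGT"):
        raise ValidationError(f"invalid codon {codon!r}")
    return _CODON_TO_AA[codon]


def classify_variant_type(ref: str, alt: str) -> str:
    """substitution / insertion / deletion / complex from the allele pair."""
    if not ref or not alt:
        raise ValidationError("alleles must be non-empty")
    if len(ref) == 1 and len(alt) == 1:
        return "substitution"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "complex"


def mitomap_status(key: VariantKey, catalog: Set[VariantKey]) -> str:
    """Known/Unknown membership in a MITOMAP-like catalog."""
    return "Known" if key in catalog else "Unknown"


def conservation_flag(position: int, conserved: Set[int]) -> bool:
    return position in conserved


@dataclass(frozen=True)
class CodonChange:
    codon_change: str  # e.g. "aAc/aGc"
    aa_change: str  # e.g. "N/S"
    effect: str  # synonymous / missense / nonsense / stop_loss


def _render_codon(codon: str, within: int) -> str:
    low = codon.lower()
    return low[:within] + codon[within].upper() + low[within + 1 :]


def codon_context(
    key: VariantKey,
    model: MitoGeneModel,
    gene: Optional[GeneRecord] = None,
) -> CodonChange:
    """Codon and amino-acid change of a substitution in a protein-coding gene.

    The reading frame is anchored at the gene's coordinate start (first codon
    begins at ``start`` for strand ``+``, at ``end`` reading backwards for
    strand ``-``).  Alleles in ``key`` are heavy-strand; they are complemented
    for light-strand genes.  Raises if the variant is not a single-base
    substitution inside a protein-coding gene with sequence available, or if
    the codon is truncated by the gene boundary.
    """
    genome = model.genome
    if genome.sequence is None:
        raise ValidationError("codon context requires a genome sequence")
    if classify_variant_type(key.ref, key.alt) != "substitution":
        raise ValidationError(f"{key}: codon context applies to substitutions only")
    if gene is None:
        coding = [
            g for g in model.locate(key.position) if g.biotype == "protein_coding"
        ]
        if not coding:
            raise ValidationError(f"{key}: not inside a protein-coding gene")
        gene = coding[0]
    if genome.base(key.position) != key.ref:
        raise ValidationError(
            f"{key}: reference allele {key.ref} does not match genome base "
            f"{genome.base(key.position)} at {key.position}"
        )

    L = genome.length
    span = gene.span_length(L)
    offset = gene.offset_of(key.position, L)  # heavy-strand offset in gene
    if gene.strand == "+":
        coding_offset = offset
    else:
        coding_offset = span - 1 - offset
    codon_idx, within = divmod(coding_offset, 3)
    if codon_idx * 3 + 3 > span:
        raise ValidationError(
            f"{key}: codon truncated by the boundary of {gene.symbol}"
        )

    ref_codon = []
    for j in range(3):
        if gene.strand == "+":
            pos = gene.position_at(codon_idx * 3 + j, L)
            ref_codon.append(genome.base(pos))
        else:
            pos = gene.position_at(span - 1 - (codon_idx * 3 + j), L)
            ref_codon.append(genome.base(pos).translate(_COMPLEMENT))
    ref_codon = "".join(ref_codon)

    alt_base = key.alt if gene.strand == "+" else key.alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == "*":
        effect = "stop_loss"
    else:
        effect = "missense"
    return CodonChange(
        codon_change=f"{_render_codon(ref_codon, within)}/{_render_codon(alt_codon, within)}",
        aa_change=f"{ref_aa}/{alt_aa}",
        effect=effect,
    )


def homopolymer_flag(
    position: int, genome: MitoGenome, min_run: int = 4
) -> bool:
    """True iff ``position`` lies within, or immediately adjacent to, a run of
    ≥ ``min_run`` identical bases (circular wrap respected)."""
    if genome.sequence is None:
        raise ValidationError("homopolymer detection requires a genome sequence")
    genome.check_position(position)
    seq, L = genome.sequence, genome.length

    def run_length_at(p: int) -> int:
        base = seq[p - 1]
        length = 1
        # extend left
        q = p
        while length < L:
            nxt = genome.wrap(q - 1) if genome.circular else q - 1
            if nxt < 1 or seq[nxt - 1] != base or nxt == p:
                break
            q = nxt
            length += 1
        # extend right
        r = p
        while length < L:
            nxt = genome.wrap(r + 1) if genome.circular else r + 1
            if nxt > L or seq[nxt - 1] != base or nxt == p:
                break
            r = nxt
            length += 1
        return length

    candidates = [position, position - 1, position + 1]
    for p in candidates:
        if genome.circular:
            p = genome.wrap(p)
        elif not 1 <= p <= L:
            continue
        if run_length_at(p) >= min_run:
            return True
    return False


@dataclass(frozen=True)
class AnnotationBundle:
    """Everything the pipeline knows about one aggregated variant."""

    genes: Tuple[str, ...]
    region_class: str
    variant_type: str
    mitomap_status: str
    rsid: Optional[str]
    conserved: bool
    codon_change: Optional[str]
    aa_change: Optional[str]
    effect: Optional[str]
    sift: str
    polyphen: str
    homopolymer: bool

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region class {self.region_class!r}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValidationError(f"unknown variant type {self.variant_type!r}")
        if self.effect is not None and self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")


def concordance_filter(
    variants: Iterable[AggregatedVariant],
) -> List[AggregatedVariant]:
    """Keep variants both predictors call damaging: SIFT ``deleterious`` AND
    PolyPhen ``probably_damaging``; NA in either excludes."""
    kept = []
    for v in variants:
        if v.annotations is None:
            continue
        if (
            v.annotations.sift == "deleterious"
            and v.annotations.polyphen == "probably_damaging"
        ):
            kept.append(v)
    return kept


def annotate(
    variants: Iterable[AggregatedVariant],
    model: MitoGeneModel,
    catalog: Optional[Set[VariantKey]] = None,
    conserved: Optional[Set[int]] = None,
    predictions: Optional[Mapping[VariantKey, Tuple[str, str]]] = None,
    rsids: Optional[Mapping[VariantKey, str]] = None,
    min_homopolymer_run: int = 4,
) -> List[AggregatedVariant]:
    """Fill every annotation field for each aggregated variant.

    Codon/amino-acid fields are computed only for substitutions inside
    protein-coding genes and only when the genome carries a sequence; in a
    region where coding genes overlap, the singular codon fields come from
    the first overlapping coding gene in model order, while ``genes`` lists
    all overlapping genes (per-gene tallies downstream count each).
    """
    catalog = catalog or set()
    conserved = conserved or set()
    predictions = predictions or {}
    rsids = rsids or {}
    has_seq = model.genome.sequence is not None

    out: List[AggregatedVariant] = []
    for v in variants:
        key = v.key
        genes = model.locate(key.position)
        vtype = classify_variant_type(key.ref, key.alt)
        coding = [g for g in genes if g.biotype == "protein_coding"]
        if coding:
            region = "coding_exon"
        elif genes:
            region = "non_coding_exon"
        else:
            region = "intergenic"

        codon_change = aa_change = None
        if region == "intergenic":
            effect: Optional[str] = "intergenic"
        elif region == "non_coding_exon":
            effect = "non_coding"
        elif vtype == "substitution":
            if has_seq:
                try:
                    cc = codon_context(key, model, gene=coding[0])
                    codon_change, aa_change, effect = (
                        cc.codon_change,
                        cc.aa_change,
                        cc.effect,
                    )
                except ValidationError:
                    effect = None  # truncated codon at a gene boundary
            else:
                effect = None  # coding change, consequence unknown without sequence
        else:
            effect = "frameshift_candidate"

        sift, polyphen = predictions.get(key, ("NA", "NA"))
        bundle = AnnotationBundle(
            genes=tuple(g.symbol for g in genes),
            region_class=region,
            variant_type=vtype,
            mitomap_status=mitomap_status(key, catalog),
            rsid=rsids.get(key),
            conserved=conservation_flag(key.position, conserved),
            codon_change=codon_change,
            aa_change=aa_change,
            effect=effect,
            sift=sift,
            polyphen=polyphen,
            homopolymer=(
                homopolymer_flag(key.position, model.genome, min_homopolymer_run)
                if has_seq
                else False
            ),
        )
        out.append(replace_annotations(v, bundle))
    return out


def replace_annotations(
    variant: AggregatedVariant, bundle: AnnotationBundle
) -> AggregatedVariant:
    return AggregatedVariant(
        key=variant.key, carriers=variant.carriers, annotations=bundle
    )


def variant_table_rows(variants: Iterable[AggregatedVariant]) -> List[dict]:
    """Render annotated variants as rows for io_formats.write_variant_table."""
    rows = []
    for v in variants:
        a = v.annotations
        rows.append(
            {
                "position": v.key.position,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "rsid": a.rsid if a else None,
                "mitomap": a.mitomap_status if a else None,
                "counts": v.carrier_count,
                "conserved": a.conserved if a else None,
                "gene": ";".join(a.genes) if a and a.genes else None,
                "codon_change": a.codon_change if a else None,
                "aa_change": a.aa_change if a else None,
                "effect": a.effect if a else None,
                "sift": a.sift if a else None,
                "polyphen": a.polyphen if a else None,
                "homopolymer": a.homopolymer if a else None,
            }
        )
    return rows
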