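"""Readers and writers for the formats the pipeline touches.

VCF dialect
-----------
Per-sample strand-split alternate-allele depths are carried in the FORMAT
fields ``SAF`` (forward) and ``SAR`` (reverse), one integer per ALT allele,
alongside the standard ``DP``.  Haploid genotypes are written as
single-allele GT (``1``); diploid-style input (``1/1``, ``0/1``, ``./.``)
is accepted on read.  Multi-allelic records are decomposed on read into one
:class:`SampleCall` per sample × ALT allele the sample's genotype touches;
samples whose genotype is hom-ref are not variant calls and yield nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple, Union

import pandas as pd
import pysam

from .errors import FormatError, ParseError, ValidationError

ALLELE_ALPHABET = set("ACGT")

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt", "missing")

SIFT_CATEGORIES = ("deleterious", "tolerated", "NA")
POLYPHEN_CATEGORIES = ("probably_damaging", "possibly_damaging", "benign", "NA")


class VariantKey(NamedTuple):
    """Identity of a variant: two calls describe the same variant iff
    position, ref and alt all match."""

    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class SampleCall:
    """One per-sample variant call with strand-split alt-read support."""

    sample_id: str
    position: int
    ref: str
    alt: str
    genotype_class: str
    alt_fwd: int
    alt_rev: int
    depth: int

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValidationError(f"unknown genotype class {self.genotype_class!r}")
        if min(self.alt_fwd, self.alt_rev, self.depth) < 0:
            raise ValidationError("read counts must be non-negative")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise ValidationError(
                f"{self.sample_id}@{self.position}: alt reads "
                f"{self.alt_fwd}+{self.alt_rev} exceed depth {self.depth}"
            )
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= ALLELE_ALPHABET:
                raise ValidationError(f"{name} allele {allele!r} invalid")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref!r}) at {self.position}")
        if self.position <= 0:
            raise ValidationError(f"position must be 1-based positive, got {self.position}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.position, self.ref, self.alt)


def _classify_gt(gt: Sequence[Optional[int]], allele_index: int) -> Optional[str]:
    """Map a pysam GT tuple to a genotype class for one ALT allele index
    (1-based within the record). None ⇒ the sample makes no call for this alt."""
    if len(gt) == 0 or all(a is None for a in gt):
        return "missing"
    called = [a for a in gt if a is not None]
    if allele_index not in called:
        return None  # hom-ref or a different alt: not a call for this allele
    if all(a == allele_index for a in called):
        return "hom_alt"
    return "het"


def _per_alt(value, n_alts: int, j: int, what: str, where: str) -> int:
    """Extract the j-th per-ALT integer from a FORMAT value (tuple or scalar)."""
    if value is None:
        raise FormatError(f"{where}: missing {what}")
    if isinstance(value, (tuple, list)):
        vals = [v for v in value]
        if len(vals) < n_alts or vals[j] is None:
            raise FormatError(f"{where}: {what} has no value for ALT #{j + 1}")
        return int(vals[j])
    return int(value)


def read_vcf(path: Union[str, Path]) -> List[SampleCall]:
    """Read a VCF into per-sample calls (see module docstring for dialect)."""
    path = str(path)
    calls: List[SampleCall] = []
    with pysam.VariantFile(path) as vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path}: FORMAT lacks GT")
        for rec in vcf:
            where = f"{path}:{rec.chrom}:{rec.pos}"
            alts = rec.alts or ()
            for sample_name, sample in rec.samples.items():
                if "GT" not in sample:
                    raise FormatError(f"{where}: sample {sample_name} lacks GT")
                gt = sample["GT"]
                for j, alt in enumerate(alts):
                    cls = _classify_gt(gt, j + 1)
                    if cls is None:
                        continue
                    if cls == "missing" and j > 0:
                        continue  # one missing call per sample, attached to ALT #1
                    try:
                        saf = _per_alt(sample.get("SAF"), len(alts), j, "SAF", where)
                        sar = _per_alt(sample.get("SAR"), len(alts), j, "SAR", where)
                    except FormatError:
                        if cls == "missing":
                            saf = sar = 0  # no-call: strand support may be absent
                        else:
                            raise FormatError(
                                f"{where}: strand-split alt depths (SAF/SAR) missing "
                                f"for sample {sample_name}"
                            )
                    dp = sample.get("DP")
                    depth = int(dp) if dp is not None else saf + sar
                    calls.append(
                        SampleCall(
                            sample_id=sample_name,
                            position=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            genotype_class=cls,
                            alt_fwd=saf,
                            alt_rev=sar,
                            depth=depth,
                        )
                    )
    return calls


def _vcf_header(samples: Sequence[str], contig: str, contig_length: int) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={contig_length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=SAF,Number=A,Type=Integer,'
        'Description="Alt-supporting reads on the forward strand">'
    )
    header.add_line(
        '##FORMAT=<ID=SAR,Number=A,Type=Integer,'
        'Description="Alt-supporting reads on the reverse strand">'
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    calls: Iterable[SampleCall],
    path: Union[str, Path],
    contig: str = "MT",
    contig_length: Optional[int] = None,
) -> None:
    """Write calls as an uncompressed biallelic VCF (one record per variant key).

    Samples without a call at a record are emitted as haploid hom-ref (``0``);
    ``read_vcf(write_vcf(x))`` reproduces ``x`` field-for-field.
    """
    calls = list(calls)
    samples = sorted({c.sample_id for c in calls})
    max_pos = max((c.position + len(c.ref) - 1 for c in calls), default=1)
    if contig_length is None:
        contig_length = max(max_pos, 1)
    header = _vcf_header(samples, contig, contig_length)

    by_key: Dict[VariantKey, Dict[str, SampleCall]] = {}
    for c in calls:
        by_key.setdefault(c.key, {})[c.sample_id] = c

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(by_key):
            rec = out.new_record(
                contig=contig, start=key.position - 1, alleles=(key.ref, key.alt)
            )
            rec.stop = key.position - 1 + len(key.ref)
            for s in samples:
                call = by_key[key].get(s)
                fmt = rec.samples[s]
                if call is None:
                    fmt["GT"] = (0,)
                    continue
                fmt["GT"] = {
                    "hom_alt": (1,),
                    "het": (0, 1),
                    "missing": (None,),
                    "hom_ref": (0,),
                }[call.genotype_class]
                fmt["DP"] = call.depth
                fmt["SAF"] = (call.alt_fwd,)
                fmt["SAR"] = (call.alt_rev,)
            out.write(rec)


def read_catalog(path: Union[str, Path]) -> Set[VariantKey]:
    """Read a known-variant catalog (TSV: position, ref, alt) into a key set."""
    df = _read_tsv(path, ("position", "ref", "alt"))
    keys = set()
    for i, row in df.iterrows():
        try:
            keys.add(VariantKey(int(row["position"]), str(row["ref"]), str(row["alt"])))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {i + 2}: malformed row ({exc})") from exc
    return keys


def read_conserved_positions(path: Union[str, Path]) -> Set[int]:
    """Read a conserved-positions file.

    Accepts either one 1-based position per line, or 3-column BED
    (0-based half-open, converted to 1-based inclusive on read).
    """
    path = Path(path)
    positions: Set[int] = set()
    bed = None
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if bed is None:
            bed = len(fields) >= 3
        if bed:
            if len(fields) < 3:
                raise ParseError(f"{path}, line {line_no}: expected 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}, line {line_no}: non-integer BED bounds") from exc
            positions.update(range(start + 1, end + 1))
        else:
            try:
                positions.add(int(fields[0]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}, line {line_no}: non-integer position {fields[0]!r}"
                ) from exc
    return positions


def read_predictions(
    path: Union[str, Path]
) -> Dict[VariantKey, Tuple[str, str]]:
    """Read externally computed SIFT/PolyPhen categories per variant.

    Absent variants default to ("NA", "NA") at lookup time (use ``.get`` with
    that default); unknown category tokens are rejected.
    """
    df = _read_tsv(path, ("position", "ref", "alt", "sift", "polyphen"))
    preds: Dict[VariantKey, Tuple[str, str]] = {}
    for i, row in df.iterrows():
        sift = str(row["sift"])
        poly = str(row["polyphen"])
        if sift not in SIFT_CATEGORIES:
            raise ValidationError(
                f"{path}, line {i + 2}: unknown SIFT category {sift!r}"
            )
        if poly not in POLYPHEN_CATEGORIES:
            raise ValidationError(
                f"{path}, line {i + 2}: unknown PolyPhen category {poly!r}"
            )
        preds[VariantKey(int(row["position"]), str(row["ref"]), str(row["alt"]))] = (
            sift,
            poly,
        )
    return preds


#: Canonical column order of the annotated-variant table (mirrors the study's
#: printed variant tables; "-" renders empty fields).
VARIANT_TABLE_COLUMNS = (
    "position",
    "ref",
    "alt",
    "rsid",
    "mitomap",
    "counts",
    "conserved",
    "gene",
    "codon_change",
    "aa_change",
    "effect",
    "sift",
    "polyphen",
    "homopolymer",
)


def write_variant_table(rows: Iterable[Mapping], path: Union[str, Path]) -> None:
    """Write annotated variants as a deterministic TSV (one row per variant).

    ``rows`` are mappings with (a subset of) :data:`VARIANT_TABLE_COLUMNS`;
    missing or None values render as "-".
    """
    records = []
    for row in rows:
        rec = {}
        for col in VARIANT_TABLE_COLUMNS:
            val = row.get(col)
            if val is None or val == "":
                val = "-"
            elif isinstance(val, bool):
                val = "Yes" if val else "No"
            rec[col] = val
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=list(VARIANT_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read an annotated-variant table written by :func:`write_variant_table`."""
    df = _read_tsv(path, ("position", "ref", "alt"))
    df["position"] = df["position"].astype(int)
    if "counts" in df.columns:
        df["counts"] = df["counts"].replace("-", "0").astype(int)
    return df


def _read_tsv(path: Union[str, Path], required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df
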