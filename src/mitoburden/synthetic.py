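"""Synthetic data with the statistical structure of targeted haploid mtDNA
sequencing, plus ground-truth labels for filter-recovery testing.

The generator emulates the data-generating conditions of a targeted
mitochondrial resequencing study of a human population sample:

* a circular genome with overlapping genes, a light-strand gene, rRNA- and
  tRNA-like features, and homopolymer runs;
* a haploid population carrying common variants (haplogroup-like allele
  frequencies), rare variants (1–3 carriers) and reference-minor sites
  (the reference carries the minor allele, population alt frequency ≥95%);
* per-call read support: Poisson total depth, binomial(0.5) strand split
  for true calls;
* three artifact classes injected as extra false calls — heterozygous-looking
  heteroplasmy artifacts, strand-biased calls with all alt reads on one
  strand, and indel calls placed inside homopolymer runs (these get balanced
  strand support: on real semiconductor-sequencing data such indels survive
  read-support filters and must be caught by sequence context).

Every operation is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .core_model import GeneRecord, MitoGenome, MitoGeneModel
from .errors import ValidationError
from .io_formats import SampleCall, VariantKey, write_vcf

TRUTH_LABELS = (
    "true_variant",
    "het_artifact",
    "strand_artifact",
    "homopolymer_artifact",
)

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 436 haploid genomes, ~1200 distinct variants
    (200 common + 1000 rare + 2 reference-minor sites), mean depth 198×."""

    genome_length: int = 16569
    n_genes: int = 10
    n_samples: int = 436
    n_common_variants: int = 200
    common_af_range: Tuple[float, float] = (0.05, 0.5)
    n_rare_variants: int = 1000
    rare_max_carriers: int = 3
    n_ref_minor_sites: int = 2
    ref_minor_af: float = 0.95
    het_artifact_rate: float = 0.05
    strand_artifact_rate: float = 0.05
    homopolymer_indel_rate: float = 0.01
    mean_depth: float = 198.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "het_artifact_rate",
            "strand_artifact_rate",
            "homopolymer_indel_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {rate}")
        if self.genome_length < 2000:
            raise ValidationError("genome_length must be ≥ 2000")
        if not 0.0 <= self.ref_minor_af <= 1.0:
            raise ValidationError("ref_minor_af must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    key: VariantKey
    label: str

    def __post_init__(self) -> None:
        if self.label not in TRUTH_LABELS:
            raise ValidationError(f"unknown truth label {self.label!r}")


@dataclass
class PopulationTruth:
    """True variant keys with their carrier sets (sample ids)."""

    carriers: Dict[VariantKey, Tuple[str, ...]]

    @property
    def keys(self) -> List[VariantKey]:
        return sorted(self.carriers)

    def carrier_count(self, key: VariantKey) -> int:
        return len(self.carriers[key])


def _sample_ids(n: int) -> List[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


def make_toy_genome(config: SimConfig) -> Tuple[MitoGenome, MitoGeneModel]:
    """Deterministic toy circular genome + gene model.

    Guarantees: ≥1 light-strand gene, ≥1 overlapping protein-coding pair,
    ≥1 rRNA-like and ≥1 tRNA-like gene, ≥3 homopolymer runs of length ≥4.
    All protein-coding spans are multiples of 3 (clean reading frames).
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    seq = list(rng.choice(list(BASES), size=L))

    # break accidental runs ≥4, then plant controlled homopolymer runs
    for i in range(3, L):
        if seq[i] == seq[i - 1] == seq[i - 2] == seq[i - 3]:
            seq[i] = BASES[(BASES.index(seq[i]) + 1) % 4]

    genes: List[GeneRecord] = []
    cursor = max(151, L // 100)  # leave a control-region-like gap at the origin

    def place(symbol: str, biotype: str, length: int, strand: str = "+") -> GeneRecord:
        nonlocal cursor
        start = cursor
        end = start + length - 1
        if end > L - 60:
            raise ValidationError("gene layout does not fit the genome length")
        rec = GeneRecord(symbol, biotype, start, end, strand, length)
        genes.append(rec)
        cursor = end + 1 + int(rng.integers(20, 60))
        return rec

    unit = max(60, (L - cursor - 60) // max(config.n_genes, 6) - 80)
    unit -= unit % 3
    place("RNR-A", "Mt_rRNA", max(unit, 300))
    place("TRN-A", "Mt_tRNA", 69)
    n_pc = max(config.n_genes - 3, 3)
    for i in range(n_pc - 2):
        strand = "-" if i == 1 else "+"  # at least one light-strand gene
        place(f"PC{i + 1:02d}", "protein_coding", unit, strand)
    # overlapping pair: second gene starts inside the first
    first = place(f"PC{n_pc - 1:02d}", "protein_coding", unit)
    ov_start = first.end - 44  # 45 bp overlap, multiple of 3
    ov_len = unit
    if ov_start + ov_len - 1 > L - 60:
        ov_len = (L - 60 - ov_start + 1) // 3 * 3
    genes.append(
        GeneRecord(f"PC{n_pc:02d}", "protein_coding", ov_start, ov_start + ov_len - 1, "+", ov_len)
    )

    # plant ≥3 homopolymer runs of length 4-6 in intergenic/tail space
    run_starts = [L - 50, L - 35, L - 20]
    for k, rs in enumerate(run_starts):
        base = BASES[k % 4]
        run = 4 + int(rng.integers(0, 3))
        for j in range(run):
            seq[rs - 1 + j] = base
        # keep neighbours distinct so the run length is exact
        seq[rs - 2] = BASES[(BASES.index(base) + 1) % 4]
        seq[rs - 1 + run] = BASES[(BASES.index(base) + 2) % 4]

    genome = MitoGenome(
        name=f"toy-mt-{config.seed}", length=L, circular=True, sequence="".join(seq)
    )
    return genome, MitoGeneModel(genome=genome, genes=genes)


def homopolymer_runs(genome: MitoGenome, min_run: int = 4) -> List[Tuple[int, int]]:
    """(start, end) 1-based inclusive intervals of runs ≥ min_run (linear scan;
    a run spanning the origin is reported in two parts)."""
    seq = genome.sequence
    if seq is None:
        raise ValidationError("genome has no sequence")
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j + 1 < len(seq) and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i + 1, j + 1))
        i = j + 1
    return runs


def simulate_population(
    config: SimConfig,
    genome: MitoGenome,
    gene_densities: Optional[Mapping[str, float]] = None,
    model: Optional[MitoGeneModel] = None,
) -> PopulationTruth:
    """Draw a haploid population of true variants.

    Default placement is uniform over the genome.  ``gene_densities`` maps
    gene symbols to per-base variant densities and overrides the uniform
    counts for those genes (variants placed inside the gene, Poisson counts,
    all rare); it requires ``model``.
    """
    rng = np.random.default_rng(config.seed + 1)
    samples = _sample_ids(config.n_samples)
    L = genome.length
    carriers: Dict[VariantKey, Tuple[str, ...]] = {}
    used_positions: Set[int] = set()

    def draw_positions(n: int, pool: Optional[Sequence[int]] = None) -> List[int]:
        candidates = [p for p in (pool if pool is not None else range(1, L + 1))
                      if p not in used_positions]
        if n > len(candidates):
            raise ValidationError(
                f"cannot place {n} variants in {len(candidates)} free positions"
            )
        chosen = rng.choice(len(candidates), size=n, replace=False)
        positions = [candidates[i] for i in chosen]
        used_positions.update(positions)
        return positions

    def alt_for(pos: int) -> Tuple[str, str]:
        ref = genome.base(pos) if genome.sequence else str(rng.choice(list(BASES)))
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return ref, alt

    def add_variant(pos: int, n_carriers: int) -> None:
        ref, alt = alt_for(pos)
        n_carriers = min(max(n_carriers, 1), config.n_samples)
        chosen = rng.choice(config.n_samples, size=n_carriers, replace=False)
        carriers[VariantKey(pos, ref, alt)] = tuple(sorted(samples[i] for i in chosen))

    if gene_densities:
        if model is None:
            raise ValidationError("gene_densities requires the gene model")
        for symbol, density in gene_densities.items():
            gene = model[symbol]
            span = gene.span_length(L)
            n = int(rng.poisson(density * span))
            pool = [gene.position_at(k, L) for k in range(span)]
            for pos in draw_positions(n, pool):
                add_variant(pos, int(rng.integers(1, config.rare_max_carriers + 1)))

    for _ in range(config.n_common_variants):
        (pos,) = draw_positions(1)
        f = rng.uniform(*config.common_af_range)
        add_variant(pos, int(rng.binomial(config.n_samples, f)))
    for _ in range(config.n_rare_variants):
        (pos,) = draw_positions(1)
        add_variant(pos, int(rng.integers(1, config.rare_max_carriers + 1)))
    floor = int(np.ceil(config.ref_minor_af * config.n_samples))
    for _ in range(config.n_ref_minor_sites):
        (pos,) = draw_positions(1)
        f = rng.uniform(config.ref_minor_af, 1.0)
        # the stated alt frequency is a floor, not just a sampling mean
        add_variant(pos, max(int(rng.binomial(config.n_samples, f)), floor))
    return PopulationTruth(carriers=carriers)


def simulate_calls(
    truth: PopulationTruth, config: SimConfig, genome: MitoGenome
) -> Tuple[List[SampleCall], List[TruthRecord]]:
    """Render the population as per-sample calls and inject labelled artifacts.

    True calls: hom-alt genotype, Poisson(mean_depth) alt reads split
    binomial(0.5) across strands.  Artifact counts are binomial draws with
    the per-call configured rates, placed at positions carrying no true
    variant.
    """
    rng = np.random.default_rng(config.seed + 2)
    samples = _sample_ids(config.n_samples)
    calls: List[SampleCall] = []
    labels: List[TruthRecord] = []

    def depths() -> Tuple[int, int, int]:
        total = max(int(rng.poisson(config.mean_depth)), 1)
        fwd = int(rng.binomial(total, 0.5))
        return fwd, total - fwd, total

    for key in truth.keys:
        for sample in truth.carriers[key]:
            fwd, rev, total = depths()
            calls.append(
                SampleCall(sample, key.position, key.ref, key.alt, "hom_alt", fwd, rev, total)
            )
            labels.append(TruthRecord(sample, key, "true_variant"))

    n_true = len(calls)
    taken = {k.position for k in truth.keys}
    free = np.array([p for p in range(1, genome.length + 1) if p not in taken])
    rng.shuffle(free)
    free_iter = iter(free.tolist())

    def artifact_site() -> Tuple[int, str, str]:
        pos = next(free_iter)
        ref = genome.base(pos)
        if ref == "N":
            ref = "A"
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return pos, ref, alt

    for _ in range(int(rng.binomial(n_true, config.het_artifact_rate))):
        pos, ref, alt = artifact_site()
        sample = samples[int(rng.integers(config.n_samples))]
        fwd, rev, total = depths()
        calls.append(SampleCall(sample, pos, ref, alt, "het", fwd, rev, total))
        labels.append(TruthRecord(sample, VariantKey(pos, ref, alt), "het_artifact"))

    for _ in range(int(rng.binomial(n_true, config.strand_artifact_rate))):
        pos, ref, alt = artifact_site()
        sample = samples[int(rng.integers(config.n_samples))]
        _, _, total = depths()
        one_strand = bool(rng.integers(2))
        fwd, rev = (total, 0) if one_strand else (0, total)
        calls.append(SampleCall(sample, pos, ref, alt, "hom_alt", fwd, rev, total))
        labels.append(TruthRecord(sample, VariantKey(pos, ref, alt), "strand_artifact"))

    runs = homopolymer_runs(genome) if genome.sequence else []
    run_positions = [p for s, e in runs for p in range(s, e + 1) if p not in taken]
    rng.shuffle(run_positions)
    run_iter = iter(run_positions)
    for _ in range(int(rng.binomial(n_true, config.homopolymer_indel_rate))):
        try:
            pos = next(run_iter)
        except StopIteration:
            break
        base = genome.base(pos)
        ref, alt = (base, base * 2) if rng.integers(2) else (base * 2, base)
        if ref == base * 2 and pos == genome.length:
            continue  # two-base ref would run off the linear sequence end
        sample = samples[int(rng.integers(config.n_samples))]
        fwd, rev, total = depths()
        calls.append(SampleCall(sample, pos, ref, alt, "hom_alt", fwd, rev, total))
        labels.append(
            TruthRecord(sample, VariantKey(pos, ref, alt), "homopolymer_artifact")
        )

    order = sorted(range(len(calls)), key=lambda i: (calls[i].key, calls[i].sample_id))
    return [calls[i] for i in order], [labels[i] for i in order]


def write_truth_table(labels: Sequence[TruthRecord], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "sample": t.sample_id,
                "position": t.key.position,
                "ref": t.key.ref,
                "alt": t.key.alt,
                "label": t.label,
            }
            for t in labels
        ]
    ).to_csv(path, sep="\t", index=False)


def write_genome_fasta(genome: MitoGenome, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        seq = genome.sequence or ""
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_gene_table(model: MitoGeneModel, path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "symbol": g.symbol,
                "biotype": g.biotype,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "length": g.printed_length,
            }
            for g in model
        ]
    ).to_csv(path, sep="\t", index=False)


def simulate_bundle(config: SimConfig, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Full simulation to disk: ref.fa, genes.tsv, calls.vcf, truth.tsv.

    Byte-identical across reruns with the same config (including seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, model = make_toy_genome(config)
    truth = simulate_population(config, genome)
    calls, labels = simulate_calls(truth, config, genome)
    paths = {
        "ref": out / "ref.fa",
        "genes": out / "genes.tsv",
        "vcf": out / "calls.vcf",
        "truth": out / "truth.tsv",
    }
    write_genome_fasta(genome, paths["ref"])
    write_gene_table(model, paths["genes"])
    write_vcf(calls, paths["vcf"], contig=genome.name, contig_length=genome.length)
    write_truth_table(labels, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# Printed-table fixture bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaperFixture:
    """The published printed-table bundle: per-gene summary (15 genes), the
    24 concordant-damaging variants, the 35 catalog-unknown variants, plus a
    catalog of exactly the Known keys, predictions and rsid maps."""

    gene_table: pd.DataFrame
    concordant: pd.DataFrame  # 24 rows
    unknown: pd.DataFrame  # 35 rows
    catalog: Set[VariantKey]
    predictions: Dict[VariantKey, Tuple[str, str]]
    rsids: Dict[str, str]  # "pos:ref:alt" -> rsid


def _data_path(name: str):
    return resources.files("mitoburden.data") / name


def load_gene_summary_table() -> pd.DataFrame:
    """The bundled per-gene summary with printed lengths, counts and rates."""
    with resources.as_file(_data_path("gene_model.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return df


def make_paper_fixture(out_dir: Optional[Union[str, Path]] = None) -> PaperFixture:
    """Assemble the printed-table fixtures; optionally write them to a
    directory (genes.tsv, concordant.tsv, unknown.tsv, catalog.tsv,
    predictions.tsv, conserved.txt)."""
    genes = load_gene_summary_table()
    with resources.as_file(_data_path("concordant_variants.tsv")) as p:
        concordant = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    with resources.as_file(_data_path("unknown_variants.tsv")) as p:
        unknown = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    if len(concordant) != 24 or len(unknown) != 35 or len(genes) != 15:
        raise ValidationError("bundled fixture tables have unexpected row counts")

    def key_of(row) -> VariantKey:
        return VariantKey(int(row["position"]), str(row["ref"]), str(row["alt"]))

    catalog = {
        key_of(r) for _, r in concordant.iterrows() if r["mitomap"] == "Known"
    }
    predictions: Dict[VariantKey, Tuple[str, str]] = {}
    for _, r in unknown.iterrows():
        if r["sift"] != "-" and r["polyphen"] != "-":
            predictions[key_of(r)] = (str(r["sift"]), str(r["polyphen"]))
    for _, r in concordant.iterrows():
        predictions[key_of(r)] = ("deleterious", "probably_damaging")
    rsids = {
        f"{r['position']}:{r['ref']}:{r['alt']}": str(r["rsid"])
        for _, r in concordant.iterrows()
        if r["rsid"] != "."
    }
    fixture = PaperFixture(
        gene_table=genes,
        concordant=concordant,
        unknown=unknown,
        catalog=catalog,
        predictions=predictions,
        rsids=rsids,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        concordant.to_csv(out / "concordant.tsv", sep="\t", index=False)
        unknown.to_csv(out / "unknown.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(catalog), columns=["position", "ref", "alt"]
        ).to_csv(out / "catalog.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"position": k.position, "ref": k.ref, "alt": k.alt, "sift": s, "polyphen": p}
                for k, (s, p) in sorted(predictions.items())
            ]
        ).to_csv(out / "predictions.tsv", sep="\t", index=False)
        conserved = sorted(
            int(r["position"])
            for df in (concordant, unknown)
            for _, r in df.iterrows()
            if r["conserved"] == "Yes"
        )
        (out / "conserved.txt").write_text("".join(f"{p}\n" for p in conserved))
    return fixture


def fixture_variant_keys(fixture: PaperFixture) -> Set[VariantKey]:
    """Deduplicated union of the two printed variant lists (57 keys)."""
    keys: Set[VariantKey] = set()
    for df in (fixture.concordant, fixture.unknown):
        for _, r in df.iterrows():
            keys.add(VariantKey(int(r["position"]), str(r["ref"]), str(r["alt"])))
    return keys
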