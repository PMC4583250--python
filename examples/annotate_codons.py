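"""Codon-level annotation under the vertebrate mitochondrial genetic code.

Builds a 120 bp toy circular genome with one gene on each strand and
annotates substitutions in both, showing the printed-style codon rendering
(altered base uppercase) and the mitochondrial-specific translations.
"""

from mitoburden.annotation import codon_context, translate_codon
from mitoburden.core_model import GeneRecord, MitoGenome, MitoGeneModel
from mitoburden.io_formats import VariantKey

seq = list("ACGT" * 30)
seq[9:12] = "CTA"    # + strand gene starts with codon CTA (Leu)
seq[76:79] = "CAT"   # heavy-strand CAT reads ATG (Met) on the light strand
genome = MitoGenome(name="toy", length=120, circular=True, sequence="".join(seq))
model = MitoGeneModel(
    genome=genome,
    genes=[
        GeneRecord("HEAVY", "protein_coding", 10, 39, "+", 30),
        GeneRecord("LIGHT", "protein_coding", 50, 79, "-", 30),
    ],
)

for key in (VariantKey(10, "C", "A"), VariantKey(79, "T", "C")):
    gene = model.locate(key.position)[0]
    cc = codon_context(key, model)
    print(f"{gene.symbol} (strand {gene.strand}): {key.ref}>{key.alt} at {key.position}"
          f" -> {cc.codon_change}  {cc.aa_change}  ({cc.effect})")

print("\nmitochondrial-specific codons:")
for codon in ("ATA", "TGA", "AGA"):
    print(f"  {codon} -> {translate_codon(codon)}")

# The + strand change Cta/Ata is L->M because ATA codes methionine in the
# vertebrate mitochondrial code (not isoleucine as in the standard code);
# the light-strand heavy T>C reads as a coding A>G, Atg/Gtg, M->V.
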