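"""Haploid genotype and strand-balance filtering of per-sample calls.

Builds a handful of calls by hand — a clean haploid call, a heterozygous-
looking heteroplasmy artifact, a strand-biased false call, and a boundary
case — and shows which survive and why.
"""

from mitoburden.filtering import aggregate, genotype_filter, strand_balance_filter
from mitoburden.io_formats import SampleCall

calls = [
    SampleCall("S1", 15218, "A", "G", "hom_alt", 101, 97, 205),   # clean
    SampleCall("S2", 15218, "A", "G", "hom_alt", 95, 103, 210),   # clean
    SampleCall("S3", 15218, "A", "G", "het", 40, 45, 180),        # heteroplasmy-like
    SampleCall("S4", 8563, "A", "G", "hom_alt", 120, 3, 130),     # strand-biased
    SampleCall("S5", 8563, "A", "G", "hom_alt", 45, 5, 55),       # exactly 10%: passes
]

gt_pass, gt_log = genotype_filter(calls)
sb_pass, sb_log = strand_balance_filter(gt_pass, min_fraction=0.10)

print("discards:")
for d in gt_log + sb_log:
    if not d.passed:
        print(f"  {d.call.sample_id} @ {d.call.position}: {d.reason}")

print("\nsurviving variants with carrier counts:")
for v in aggregate(sb_pass):
    print(f"  {v.key.position} {v.key.ref}>{v.key.alt}  n_i = {v.carrier_count}")

# S3 falls to the haploid-genotype rule, S4 to strand imbalance (3/123 < 10%);
# S5 sits exactly on the 10% boundary and passes. Carrier counts n_i feed the
# weighted enrichment rate downstream.
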