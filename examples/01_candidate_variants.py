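"""Build candidate variants from a toy haplotype catalogue.

Three short haplotypes are aligned against a reference; the differences
become candidate variants, summarised as the carrier matrix V and the
coverage matrix Cov, and serialised to a multi-sample VCF.
"""

import tempfile
from pathlib import Path

from haploquant import HaplotypeSeq, build_catalog, read_candidates, write_candidates

reference = "ACGTACGTACGTACGTACGTACGTACGT"
haplotypes = [
    HaplotypeSeq("A*01:01", "ACGTACTTACGTACGTACGTACGTACGT"),  # SNV G>T at pos 7
    HaplotypeSeq("A*01:02", "ACGTACTTACGTACATACGTACGTACGT"),  # + SNV G>A at pos 15
    HaplotypeSeq("A*02:01", "ACGTACGTACGTACGTACGTAGGTACGT"),  # SNV C>G at pos 22
]

matrix = build_catalog(haplotypes, reference, chrom="toy")

print("variants:", [v.id for v in matrix.variants])
print("V (haplotype carries variant):")
for name, row in zip(matrix.haplotype_names, matrix.V):
    print(f"  {name}: {row.tolist()}")

with tempfile.TemporaryDirectory() as d:
    path = str(Path(d) / "candidates.vcf")
    write_candidates(matrix, path)
    back = read_candidates(path)
    print("VCF round-trip identical:", back.variants == matrix.variants)

# Each row of V is one haplotype's variant fingerprint; the posterior
# model only ever sees these fingerprints, not the sequences themselves.
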