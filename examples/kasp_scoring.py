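"""Score a KASP genotype matrix for polymorphism and superior alleles.

Generates a 23-marker x 15-cultivar call matrix in which 20 markers differ
from the donor genotype in at least one cultivar, then scores polymorphism
and superior-allele presence.
"""

from panhap import synthetic
from panhap.kasp import KaspMatrix, score_markers

frame = synthetic.generate_kasp_matrix(
    n_markers=23, n_polymorphic=20, donor="ICC4958", seed=6)
matrix = KaspMatrix.from_frame(frame, donor="ICC4958")

report = score_markers(matrix)
print("markers        :", len(frame))
print("polymorphic    :", report.n_polymorphic)
print("uninformative  :", int(report.uninformative.sum()))

carriers = report.presence.drop(columns=[matrix.donor]).sum(axis=1)
print("superior-allele carriers per marker (first 5):")
print(carriers.head())
print()
print("A cultivar carries the superior allele only when homozygous for the")
print("allele linked to the superior haplotype; H calls never count.")
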