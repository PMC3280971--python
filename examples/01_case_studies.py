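"""The two packaged case studies: congruence inversion between paralogs and orthologs.

Scores the transcribed experimental GO annotation snapshots for the MAP4K
kinases (biological process) and the nuclear receptors (molecular function).
In both families the within-species paralog pair scores a higher jaccard
annotation congruence than the cross-species ortholog pair — not because the
orthologs diverged in function, but because the two species' annotation
corpora capture complementary, incomplete slices of the same biology.
"""

from gocongruence import run_case_studies

table = run_case_studies("jaccard")
print(table.to_string(index=False))
print()
print(
    "Each 'paralog_exceeds_ortholog' row is 1.0 when the within-species\n"
    "paralog pair out-scores the ortholog pair; the score column holds the\n"
    "jaccard overlap of the ontology-closed annotation sets (|A∩B|/|A∪B|)."
)
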