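"""Count Simple Shared Motifs (SSMs) for one gene pair.

Builds two small genes whose conserved promoter motifs overlap near-exactly,
enumerates the (8,1)SSMs — maximal sets of length-8 extended sequences,
pairwise within Hamming distance 1, drawing material from both genes — and
prints the counts behind the SSMC ratio.
"""

from ssmotif import AtomicMotif, GeneMotifSet, SSMType, enumerate_ssms, ssm_count_result

g1 = GeneMotifSet("geneA", (AtomicMotif("m1", "AAAAAAAA"),))
g2 = GeneMotifSet("geneB", (AtomicMotif("m1", "AAAAAAAC"), AtomicMotif("m2", "AAAAAACC")))

t = SSMType(8, 1)
ssms = enumerate_ssms(g1, g2, t)
result = ssm_count_result(g1, g2, t)

print(f"type {t}: {len(ssms)} SSM(s)")
for ssm in ssms:
    print("  nodes (canonical keys):", ", ".join(ssm.canonical_keys))
print(f"ssm_count={result.ssm_count}  potential_count={result.potential_count}  ssmc={result.ssmc}")
print()
print("The single SSM pairs geneA's A-run with geneB's near-identical window;")
print("the clique {AAAAAAAC, AAAAAACC} is discarded because it uses geneB only.")
print("SSMC divides the SSM count by the product of the genes' window counts,")
print("correcting for how much motif material each gene carries.")
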