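"""Empirical nulls and CEXlist recovery of a planted co-regulated module.

Simulates a 60-gene motif database in which five genes share an exact
planted 10-mer, builds empirical SSMC nulls over the (10,d) types from
random gene pairs, and prints the CEXlist of one module member — the
genes whose cp-value (minimum empirical p-value across types) falls
below the threshold.
"""

from ssmotif import (
    PlantedModule,
    SSMEngine,
    SSMType,
    SyntheticConfig,
    build_cexlist,
    build_nulls,
    default_gene_ids,
    generate_db,
)

module = tuple(default_gene_ids(60)[:5])
cfg = SyntheticConfig(
    n_genes=60,
    seed=12345,
    planted_modules=(PlantedModule(module, "GATTACGCAT"),),
)
db, truth = generate_db(cfg)

grid = tuple(SSMType(10, d) for d in range(4))
engine = SSMEngine(db, grid)
nulls = build_nulls(db, grid, n_pairs=1000, seed=12346, engine=engine)

query = module[0]
cex = build_cexlist(query, db, grid, nulls, t=0.05, engine=engine)

print(f"planted module: {', '.join(module)}")
print(f"CEXlist({query}, t=0.05): {len(cex.members)} gene(s)")
for rank, m in enumerate(cex.members, 1):
    tag = "  <- module co-member" if m.gene_id in module else ""
    print(f"  {rank}. {m.gene_id}  cp={m.cp_value:.4f}  best type {m.best_type}{tag}")
print()
print("Module co-members head the list: sharing the planted 10-mer gives the")
print("pair an SSMC far above the random-pair null, hence a tiny cp-value.")
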