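"""Ligand multiplicity, alpha-sharing and beta-subunit evolutionary paths.

Loads the packaged ligand -> receptor pairing table, counts ligands and
distinct alpha partners per beta subunit, builds the shared-alpha graph and
infers an evolutionary-path hypothesis rooted at the hemidesmosomal beta-4.
"""

from itbkit import (
    alpha_partner_count,
    infer_evolutionary_paths,
    ligand_count_per_beta,
    load_pairing_table,
    shared_alpha_graph,
)

table = load_pairing_table()
ligands = ligand_count_per_beta(table)
alphas = alpha_partner_count(table)

print("beta  ligand_rows  alpha_partners")
for beta in sorted(ligands):
    print(f"  b{beta}       {ligands[beta]:>2}            {alphas[beta]:>2}")
# beta-1 is the promiscuity hub (12 ligand rows); beta-4 pairs only with
# alpha-6 inside the sole hemidesmosomal receptor.

graph = shared_alpha_graph(table)
print("\nshared-alpha edges (beta pair: shared alphas):")
for pair in sorted(graph.edges, key=sorted):
    a, b = sorted(pair)
    print(f"  b{a}-b{b}: {sorted(graph.shared[pair])}")

hypothesis = infer_evolutionary_paths(graph, root_beta="4", fallback_grouping=[{"2", "7"}])
print("\npredicted paths from the ancestral beta-4:")
for parent, child, via in hypothesis.edges:
    how = f"shared alpha-{via}" if via != "unshared" else "immune-lineage fallback"
    print(f"  b{parent} -> b{child}  ({how})")
print("flagged non-canonical receptor names:", table.noncanonical_receptors())
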