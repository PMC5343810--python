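"""Biomarker-of-interest selections on a miRNA-GRN.

Shows the containment of the three subnetwork selections (between-BIs
only <= touching a BI <= two-hop neighbourhood) and the degree filter.
"""
from mirgrn import (GeneratorConfig, enrich_network, filter_by_degree,
                    gen_gene_network, gen_hub_coupled_targets,
                    select_direct_any, select_direct_indirect,
                    select_direct_only, summarize)

cfg = GeneratorConfig(seed=2, n_genes=150, n_mirnas=15, alpha=1.0)
net = gen_gene_network(cfg)
grn = enrich_network(net, gen_hub_coupled_targets(net, cfg))

bis = {"G0000", "G0001", "miR-1"}   # two genes and a miRNA of interest
for name, sub in [
    ("only (edges between BIs)", select_direct_only(grn, bis)),
    ("any (edges touching a BI)", select_direct_any(grn, bis)),
    ("indirect (two-hop induced)", select_direct_indirect(grn, bis)),
]:
    s = summarize(sub)
    print(f"{name}: {s.n_nodes} nodes, {s.n_edges} edges")

hubs = filter_by_degree(grn, bis, cutoff=10)
print(f"BIs with more than 10 direct neighbours: {sorted(hubs)}")
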