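"""Meta-hub frequency analysis on the packaged 52-study literature table.

Counts, for every gene reported as a hepatocellular-carcinoma hub gene by
any of 52 published studies, how many studies list it; genes at frequency
>= 3 are the significant meta-hub genes.  Intersecting them with the eight
published central hub genes and the six hub-module genes yields the key
candidate genes.
"""

from keygenes import (
    key_candidate_genes,
    load_packaged_meta_table,
    meta_gene_frequencies,
    significant_meta_hub,
)

table = load_packaged_meta_table()
freqs = meta_gene_frequencies(table)
print(f"studies: {freqs.m}, distinct meta-hub genes: {len(freqs.genes)}")

top = freqs.to_frame().head(10)
print("\nmost frequently reported hub genes:")
print(top.to_string(index=False))

for strict, label in [(False, ">= 3"), (True, "> 3")]:
    sig = significant_meta_hub(freqs, 3, strict=strict)
    print(f"significant meta-hub genes (frequency {label}): {len(sig)}")

central_hubs = {"NUSAP1", "TOP2A", "CDC20", "PRC1", "UBE2C", "ASPM", "PNPLA7", "MT1E"}
module_genes = {"TOP2A", "CDC20", "ASPM", "PRC1", "UBE2C", "NUSAP1"}
key = key_candidate_genes(central_hubs, module_genes, significant_meta_hub(freqs, 3))
print(f"\nkey candidate genes: {sorted(key)}")
# PNPLA7 and MT1E never occur in the literature table, so the meta-hub
# route trims the eight central hubs down to the six-gene consensus.
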