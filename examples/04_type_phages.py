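"""Type a phage collection by six-protein barcodes.

Simulates a 193-phage panel whose marker proteins (Int, LM, Rep, TerS,
TMP, Doc) fall into planted families, clusters each category at >90%
global identity, and censuses the resulting barcode patterns.
"""

import crisprtrace as ct

params = ct.typing_panel_params(n_phages=193, n_patterns=27, seed=1)
proteins = ct.simulate_proteomes(params)
assignments = {cat: ct.cluster_category(seqs) for cat, seqs in proteins.items()}

for cat, classes in assignments.items():
    sizes = [len(c.member_phage_ids) for c in classes]
    print(f"{cat}: {len(classes)} class(es), sizes {sizes}")

barcodes = [ct.assign_barcode(pid, assignments) for pid in params.phage_ids]
census = ct.pattern_census(barcodes)
print(f"\n{census.n_patterns} distinct patterns among {len(barcodes)} phages")
example = next(iter(census.patterns))
print(f"example pattern {example}: represented by {census.representatives[example]}")

# One representative per pattern dereplicates the collection: a panel of
# ~27 phages captures the combinatorial diversity of all 193.
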