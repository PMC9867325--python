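"""Match spacers against an MGE database and infer the PAM.

Plants protospacers with 0-4 substitutions (plus one 5-substitution decoy
that must stay below the 85% identity threshold) in a 34-genome panel,
then reports every hit, the per-target distribution and the upstream PAM.
"""

import crisprtrace as ct

params = ct.interaction_panel_params(seed=7)
host, truth = ct.simulate_host(params)
targets, _, db_truth = ct.simulate_phage_db(params, truth.spacers)

arrays = [ct.orient_array(a) for a in ct.find_crispr_arrays(host)]
spacers = [sp for a in arrays for sp in a.spacers]
hits = ct.match_spacers(spacers, targets)

print(f"{len(spacers)} spacers vs {len(targets)} targets -> {len(hits)} hits")
for h in hits[:5]:
    print(f"  {h.spacer_ref} -> {h.target_id}:{h.target_start}-{h.target_end} "
          f"({h.strand}) identity {h.identity:.3f}, {h.n_mismatch} mismatch(es)")

dist = ct.hit_distribution(hits, targets)
print(f"targets with >=1 protospacer: {dist.fraction_with_hit:.1%}")

pam = ct.infer_pam(hits, side="upstream", k=3)
print(f"upstream PAM: 5'-{pam.motif}-3' (support: {pam.support} hits)")

# The hit fraction counts how widely the spacer repertoire samples the
# phage panel; the PAM is the motif conserved immediately 5' of the
# protospacers, a requirement for interference.
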