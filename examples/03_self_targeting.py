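"""Find self-targeting spacers (STS) and the prophage attachment core.

The simulated lysogen carries a prophage whose body contains exact copies
of five array spacers — a potential autoimmunity conflict.  The att core
duplicated at the prophage boundaries marks the integration site.
"""

import crisprtrace as ct

params = ct.interaction_panel_params(seed=3)
host, truth = ct.simulate_host(params)
arrays = [ct.orient_array(a) for a in ct.find_crispr_arrays(host)]

sts = ct.find_self_targets(arrays, host)
print(f"self-targeting spacers: {len(sts)}")
for r in sts:
    print(f"  {r.spacer_ref} hits {r.hit.target_start}-{r.hit.target_end} "
          f"identity {r.hit.identity:.2f} in {', '.join(r.overlapping_features) or 'no feature'}")

att = ct.locate_att_core(host, truth.prophage)
print(f"att core: 5'-{att.sequence}-3' ({att.length} bp), "
      f"copies at {att.left_copy} and {att.right_copy}")

pam = ct.infer_pam([r.hit for r in sts], side="upstream", k=3)
print(f"PAM upstream of the STS: 5'-{pam.motif}-3'")

# Every STS lies inside the prophage (none in the flanking chromosome),
# and the duplicated core is the exact repeat bounding the integration.
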