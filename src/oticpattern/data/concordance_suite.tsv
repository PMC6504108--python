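# Concordance suite: staged qualitative observations of otic anteroposterior
# patterning, one assertion per row, evaluated on simulated profiles with the
# default detection threshold (20% of saturation).  Columns are tab-separated.
# stage_hpf is the assay stage; argument is the predicate's numeric bound;
# ref_scenario is the comparison run for reference-relative predicates.
id	scenario	species	stage_hpf	predicate	argument	ref_scenario	anchor
wt-pax5-single-domain	wild_type	pax5	36	domain_count_eq	1		wild-type pax5 occupies a single anterior otic domain
wt-pax5-anterior-bias	wild_type	pax5	36	anterior_gt_posterior	0		wild-type pax5 is anterior: posterior cells receive too little extrinsic Fgf
wt-hmx3a-anterior-bias	wild_type	hmx3a	22.5	anterior_gt_posterior	0		wild-type hmx3a is expressed anteriorly, not posteriorly, at vesicle stages
wt-fgfi-single-pole	wild_type	fgf_i	36	domain_count_eq	1		wild-type intrinsic fgf expression marks the anterior pole only
wt-fgfi-restricted	wild_type	fgf_i	36	extent_le	35		wild-type intrinsic fgf stays within the anterior pole region
hs14-hmx3a-rapid-expansion	fgf3_hs_14	hmx3a	16	extent_ge	95		two hours after fgf3 heat shock, hmx3a covers the entire anteroposterior extent
hs14-hmx3a-persists	fgf3_hs_14	hmx3a	36	extent_ge	95		hmx3a expression remains expanded across the whole axis at 36 hpf (autoregulation)
hs14-pax5-two-domains-25.5	fgf3_hs_14	pax5	25.5	domain_count_eq	2		pax5 has already resolved into two discrete pole domains by 25.5 hpf
hs14-pax5-two-domains-36	fgf3_hs_14	pax5	36	domain_count_eq	2		two discrete pax5 domains at the anterior and posterior poles persist at 36 hpf
hs14-fgfi-both-poles	fgf3_hs_14	fgf_i	36	domain_count_eq	2		ectopic endogenous fgf appears at the posterior pole, not across the middle
hs14-fgfi-not-central	fgf3_hs_14	fgf_i	36	extent_le	45		intrinsic fgf is confined to the competent poles even under uniform Fgf
hs18-hmx3a-broad	fgf3_hs_18	hmx3a	22.5	extent_ge	95		late (18 hpf) heat shock still expands hmx3a across the whole axis by 22.5 hpf
hs18-pax5-broad	fgf3_hs_18	pax5	22.5	extent_ge	95		late (18 hpf) heat shock still expands pax5 across the whole axis by 22.5 hpf
cyc-hmx3a-graded	cyclopamine_14_22.5	hmx3a	22.5	graded_decreasing	0		under Hh inhibition hmx3a is graded across the ear, higher anteriorly, at 22.5 hpf
cyc-hmx3a-expanded	cyclopamine_14_22.5	hmx3a	22.5	extent_ge_ref	1.05	wild_type	hmx3a extent under Hh inhibition exceeds the wild-type extent at 22.5 hpf
cyc-pax5-unchanged-22.5	cyclopamine_14_22.5	pax5	22.5	domain_count_eq	1		pax5 shows no posterior expansion at 22.5 hpf under Hh inhibition
cyc-pax5-duplicate-36	cyclopamine_14_22.5	pax5	36	domain_count_eq	2		a new discrete posterior pax5 domain has appeared by 36 hpf after wash-out
cyc-pax5-posterior-weaker	cyclopamine_14_22.5	pax5	36	anterior_gt_posterior	0		the duplicate posterior pax5 domain is weaker than the anterior one
cyc-fgfi-unchanged-22.5	cyclopamine_14_22.5	fgf_i	22.5	domain_count_eq	1		intrinsic fgf expression is unchanged at 22.5 hpf under Hh inhibition
cyc-fgfi-duplicate-36	cyclopamine_14_22.5	fgf_i	36	domain_count_eq	2		duplicate intrinsic fgf expression appears at the posterior pole by 36 hpf
smo-hmx3a-expanded	smo_mutant	hmx3a	22.5	extent_ge_ref	1.05	wild_type	constitutive Hh loss expands hmx3a posteriorly by 22.5 hpf, like the drug
smo-hmx3a-full-extent	smo_mutant	hmx3a	22.5	extent_ge	95		constitutive Hh loss de-represses hmx3a across the full axis by 22.5 hpf
lof-pax5-reduced	hmx3a_lof	pax5	24	level_ratio_le	0.25	wild_type	anterior pax5 is drastically reduced without functional Hmx3a protein
lof-fgfi-reduced	hmx3a_lof	fgf_i	24	level_ratio_le	0.25	wild_type	anterior intrinsic fgf is drastically reduced without functional Hmx3a protein
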