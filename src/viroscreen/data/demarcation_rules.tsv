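taxon_scope	marker	threshold	relation	source_note
narnavirus	RdRp_aa	50	below_means_new_species	genus Narnavirus: 50% RdRp amino-acid identity accepted as the species demarcation threshold (ICTV)
mitovirus	RdRp_aa	40	below_means_new_species	genus Mitovirus: 40% amino-acid identity as the threshold to discriminate among species (ICTV)
totivirus	RdRp_aa	50	below_means_new_species	family Totiviridae: host specificity and amino-acid identity values below 50% demarcate species (ICTV)
totivirus	CP_aa	50	below_means_new_species	family Totiviridae: host specificity and amino-acid identity values below 50% demarcate species (ICTV)
partitivirus	CP_aa	80	below_means_new_species	family Partitiviridae: 80% CP amino-acid identity species threshold (ICTV)
partitivirus	RdRp_aa	90	below_means_new_species	family Partitiviridae: 90% RdRp amino-acid identity species threshold (ICTV)
partitivirus	RdRp_aa	24	below_means_new_genus	family Partitiviridae: pairwise RdRp amino-acid identity <24% for viruses from different genera (ICTV)
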