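group	n_individuals	excluded
afr	37545	false
amr	30019	false
asj	14804	false
eas	22448	false
fin	32026	false
mid	3031	false
nfe	590031	false
sas	45546	false
remaining	31256	false
ami	456	true
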