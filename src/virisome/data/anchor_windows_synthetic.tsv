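anchor_name	label	start	end
PolA_anchor	pos762	762	762
PolA_anchor	partial	675	799
PolA_anchor	full_domain	547	926
PolA_anchor	concat	784	926
NrdA_anchor	rnr_region	437	625
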