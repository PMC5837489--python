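variant_a	variant_b	d_prime	r_squared	exceeds_threshold
rs11591147	rs505151	NA	NA	false
rs11591147	rs11206510	NA	NA	true
rs11591147	rs2479409	NA	NA	true
rs11591147	rs562556	NA	NA	true
rs11591147	rs11583680	NA	NA	true
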