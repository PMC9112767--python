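chrM	16023	16383	HV1
chrM	56	372	HV2
chrM	437	574	HV3
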