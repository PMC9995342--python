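>EPO_HUMAN_mature erythropoietin, mature chain (165 aa, des-Arg166), numbering gives N-glycosites Asn24/Asn38/Asn83
APPRLICDSRVLERYLLEAKEAENITTGCAEHCSLNENITVPDTKVNFYAWKRMEVGQQA
VEVWQGLALLSEAVLRGQALLVNSSQPWEPLQLHVDKAVSGLRSLTTLLRALGAQKEAIS
PPDAASAAPLRTITADTFRKLFRVYSNFLRGKLKLYTGEACRTGD
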