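source,temperature_c,development_days
eckenrode,7.2,62.6
eckenrode,10.0,39.9
eckenrode,12.8,27.1
eckenrode,15.6,17.0
eckenrode,18.3,15.0
eckenrode,21.1,11.0
eckenrode,23.9,8.0
eckenrode,26.7,7.0
ishikawa,10.0,50.9
ishikawa,15.8,22.0
ishikawa,21.2,14.0
ishikawa,25.0,11.5
park,10.0,38.3
park,15.0,18.7
park,20.0,11.6
park,25.0,8.6
park,30.0,6.4
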