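stage,degree_days
egg,53.6
instar1,79.3
instar2,73.6
instar3,159.2
pupa,217.0
preoviposition,68.2
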