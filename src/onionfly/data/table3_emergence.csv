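year,percentile,observed_julian,predicted_julian
1986,10,256.0,267.0
1986,15,260.0,268.0
1986,25,263.5,270.0
1986,50,266.5,273.5
1986,75,269.5,278.5
1986,90,275.0,282.0
1986,95,279.0,284.0
1987,10,261.0,265.0
1987,15,261.5,266.5
1987,25,263.5,268.5
1987,50,267.5,274.5
1987,75,269.5,279.0
1987,90,279.0,282.0
1987,95,284.0,284.0
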