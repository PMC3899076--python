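predicted,water,forest,cropland,other
water,434735,25,18090,0
forest,91,392800,2383,29036
cropland,10434,9837,102247,1001
other,278,55826,6935,57982
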