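excipient,concentration,tm_c,e_values
trehalose,5% w/v,80.4,-13.8;-12.3
sucrose,5% w/v,80.16,-16.9;-13.9
mannitol,4% w/v,80.06,-11.9;-10.7;-7.8
sorbitol,4% w/v,80.3,-9.4;-8.9;-8.5
tween20,0.4% w/v,80.5,-14.4;-15.6
tween80,0.4% w/v,80.1,-18.9
glycine,2% w/v,81.6,-27.3;-25.3
arginine,2% w/v,71.6,-22.7
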