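type_name,top_mm,bottom_mm,soma_mm,relative_density,cell_class
L2py,0.10,0.55,0.25,0.11,excitatory
L3py,0.10,0.80,0.50,0.17,excitatory
L4sp,0.30,1.05,0.90,0.09,excitatory
L4ss,0.60,1.10,0.90,0.15,excitatory
L5st,0.10,1.35,1.20,0.11,excitatory
L5tt,0.05,1.50,1.25,0.10,excitatory
L6cc,0.60,1.90,1.65,0.14,excitatory
L6ct,0.40,1.95,1.70,0.13,excitatory
BC,0.75,1.05,0.90,0.12,inhibitory
MC,0.90,1.30,1.25,0.06,inhibitory
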