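# Element mass table for CHNOPS small-molecule work.
# nominal: integer mass of the most abundant isotope (unit-resolution MRM arithmetic).
# monoisotopic: exact mass of the most abundant isotope in Da (CODATA/AME2020 values).
# heavy_abundance: natural abundance of the +1 heavy isotope (13C, 15N) where it
# matters for isotopologue correction; 0 where it is negligible for this workflow.
element,nominal,monoisotopic,heavy_abundance
C,12,12.0,0.0107
H,1,1.00782503207,0.000115
N,14,14.0030740048,0.00364
O,16,15.9949146196,0.0
P,31,30.97376163,0.0
S,32,31.97207100,0.0
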