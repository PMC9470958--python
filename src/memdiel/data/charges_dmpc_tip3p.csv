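# CHARMM36-like simplified partial charges; group-wise neutral by construction.
residue,atom,charge_e,mass_u
DMPC,N,-0.6,14.007
DMPC,C13,-0.35,12.011
DMPC,H13A,0.25,1.008
DMPC,H13B,0.25,1.008
DMPC,H13C,0.25,1.008
DMPC,C14,-0.35,12.011
DMPC,H14A,0.25,1.008
DMPC,H14B,0.25,1.008
DMPC,H14C,0.25,1.008
DMPC,C15,-0.35,12.011
DMPC,H15A,0.25,1.008
DMPC,H15B,0.25,1.008
DMPC,H15C,0.25,1.008
DMPC,C12,-0.1,12.011
DMPC,H12A,0.25,1.008
DMPC,H12B,0.25,1.008
DMPC,C11,-0.08,12.011
DMPC,H11A,0.09,1.008
DMPC,H11B,0.09,1.008
DMPC,P,1.5,30.974
DMPC,O13,-0.78,15.999
DMPC,O14,-0.78,15.999
DMPC,O11,-0.57,15.999
DMPC,O12,-0.57,15.999
DMPC,C1,-0.08,12.011
DMPC,HA,0.09,1.008
DMPC,HB,0.09,1.008
DMPC,C2,-0.09,12.011
DMPC,HS,0.09,1.008
DMPC,C3,-0.08,12.011
DMPC,HX,0.09,1.008
DMPC,HY,0.09,1.008
DMPC,O21,-0.49,15.999
DMPC,C21,0.79,12.011
DMPC,O22,-0.63,15.999
DMPC,C22,0.1,12.011
DMPC,H2R,0.09,1.008
DMPC,H2S,0.09,1.008
DMPC,C23,-0.18,12.011
DMPC,H3R,0.09,1.008
DMPC,H3S,0.09,1.008
DMPC,C24,-0.18,12.011
DMPC,H4R,0.09,1.008
DMPC,H4S,0.09,1.008
DMPC,C25,-0.18,12.011
DMPC,H5R,0.09,1.008
DMPC,H5S,0.09,1.008
DMPC,C26,-0.18,12.011
DMPC,H6R,0.09,1.008
DMPC,H6S,0.09,1.008
DMPC,C27,-0.18,12.011
DMPC,H7R,0.09,1.008
DMPC,H7S,0.09,1.008
DMPC,C28,-0.18,12.011
DMPC,H8R,0.09,1.008
DMPC,H8S,0.09,1.008
DMPC,C29,-0.18,12.011
DMPC,H9R,0.09,1.008
DMPC,H9S,0.09,1.008
DMPC,C210,-0.18,12.011
DMPC,H10R,0.09,1.008
DMPC,H10S,0.09,1.008
DMPC,C211,-0.18,12.011
DMPC,H11R,0.09,1.008
DMPC,H11S,0.09,1.008
DMPC,C212,-0.18,12.011
DMPC,H12R,0.09,1.008
DMPC,H12S,0.09,1.008
DMPC,C213,-0.18,12.011
DMPC,H13R,0.09,1.008
DMPC,H13S,0.09,1.008
DMPC,C214,-0.27,12.011
DMPC,H14R,0.09,1.008
DMPC,H14S,0.09,1.008
DMPC,H14T,0.09,1.008
DMPC,O31,-0.49,15.999
DMPC,C31,0.79,12.011
DMPC,O32,-0.63,15.999
DMPC,C32,0.1,12.011
DMPC,H2X,0.09,1.008
DMPC,H2Y,0.09,1.008
DMPC,C33,-0.18,12.011
DMPC,H3X,0.09,1.008
DMPC,H3Y,0.09,1.008
DMPC,C34,-0.18,12.011
DMPC,H4X,0.09,1.008
DMPC,H4Y,0.09,1.008
DMPC,C35,-0.18,12.011
DMPC,H5X,0.09,1.008
DMPC,H5Y,0.09,1.008
DMPC,C36,-0.18,12.011
DMPC,H6X,0.09,1.008
DMPC,H6Y,0.09,1.008
DMPC,C37,-0.18,12.011
DMPC,H7X,0.09,1.008
DMPC,H7Y,0.09,1.008
DMPC,C38,-0.18,12.011
DMPC,H8X,0.09,1.008
DMPC,H8Y,0.09,1.008
DMPC,C39,-0.18,12.011
DMPC,H9X,0.09,1.008
DMPC,H9Y,0.09,1.008
DMPC,C310,-0.18,12.011
DMPC,H10X,0.09,1.008
DMPC,H10Y,0.09,1.008
DMPC,C311,-0.18,12.011
DMPC,H11X,0.09,1.008
DMPC,H11Y,0.09,1.008
DMPC,C312,-0.18,12.011
DMPC,H12X,0.09,1.008
DMPC,H12Y,0.09,1.008
DMPC,C313,-0.18,12.011
DMPC,H13X,0.09,1.008
DMPC,H13Y,0.09,1.008
DMPC,C314,-0.27,12.011
DMPC,H14X,0.09,1.008
DMPC,H14Y,0.09,1.008
DMPC,H14Z,0.09,1.008
SOL,OW,-0.834,15.999
SOL,HW1,0.417,1.008
SOL,HW2,0.417,1.008
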