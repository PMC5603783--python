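mode,joint,min_deg,max_deg,abduction_deg,source
bipedal,hip,-40,10,0,"approximate; digitised from published gorilla bipedal walking graphs (single-plane video); chimpanzee abduction 14-30 deg used as proxy"
quadrupedal,hip,-27,40,0,"approximate; digitised from published gorilla knuckle-walking graphs"
climbing,hip,-10,50,50,"vertical climbing kinematics; maximum flexion coincides with maximum abduction, maximum extension with minimal abduction"
bipedal,knee,9,53,0,"approximate; digitised from published gorilla bipedal walking graphs"
quadrupedal,knee,17,65,0,"approximate; digitised from published gorilla knuckle-walking graphs"
climbing,knee,40,140,0,"vertical climbing uses strongly flexed knee postures"
bipedal,ankle,30,62,0,"approximate; maximum extension about 30 deg just before push-off"
quadrupedal,ankle,18,55,0,"approximate; digitised from published gorilla knuckle-walking graphs"
climbing,ankle,,119,10,"only the maximum dorsiflexion (119 deg) is reported; interval open at the extended end; ankle abducted up to 10 deg"
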