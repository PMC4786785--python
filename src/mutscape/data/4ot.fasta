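>4OT_Pputida_mt2 4-oxalocrotonate tautomerase, mature monomer (62 aa)
PIAQIHILEGRSDEQKETLIREVSEAISRSLDAPLTSVRVIITEMAKGHFGIAGELASKV
RR
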