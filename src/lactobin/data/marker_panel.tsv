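marker	subunit
S1p	SSU
S2p	SSU
S3p	SSU
S4p	SSU
S5p	SSU
S6p	SSU
S7p	SSU
S8p	SSU
S9p	SSU
S10p	SSU
S11p	SSU
S12p	SSU
S13p	SSU
S14p	SSU
S15p	SSU
S16p	SSU
S17p	SSU
S18p	SSU
S19p	SSU
S20p	SSU
S21p	SSU
L1p	LSU
L2p	LSU
L3p	LSU
L4p	LSU
L5p	LSU
L6p	LSU
L7/L12p	LSU
L9p	LSU
L10p	LSU
L11p	LSU
L13p	LSU
L14p	LSU
L15p	LSU
L16p	LSU
L17p	LSU
L18p	LSU
L19p	LSU
L20p	LSU
L21p	LSU
L22p	LSU
L23p	LSU
L24p	LSU
L25p	LSU
L27p	LSU
L28p	LSU
L29p	LSU
L30p	LSU
L31p	LSU
L32p	LSU
L33p	LSU
L34p	LSU
L35p	LSU
L36p	LSU
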