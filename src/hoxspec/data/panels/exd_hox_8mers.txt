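# Exd-Hox dimer binding 8-mers (TGAy-nnAy composites; SELEX-Seq fingerprint
# panel members named in the comparative analysis).
TGATTTAT	red
TGATTTAC	magenta
TGATTGAT	dark_green
TGATTAAT	dark_blue
TGATAAAT	light_blue
TGATGGAT	yellow
TGACAAAT	orange
TGACTAAT	purple
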