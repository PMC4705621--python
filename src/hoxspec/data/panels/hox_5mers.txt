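# Core Hox monomer binding 5-mers (SELEX-Seq fingerprint panel members
# named in the comparative analysis; labels are the conventional colours).
# Extend or replace with the full published panel as needed.
TTTAT	red
TTAAT	dark_blue
TTGAT	dark_green
TGGAT	yellow
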