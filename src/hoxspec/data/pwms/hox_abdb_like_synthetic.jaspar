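# Synthetic Hox-like count matrix with a TTTAT (TTAT-core) consensus,
# constructed for testing and demonstration; not a database motif.
>hox_abdb_like_synthetic
A  [  5  5  5 85  5 15 45 20 ]
C  [  5  5  5  5  5 15 15 45 ]
G  [  5  5  5  5  5 55 20 15 ]
T  [ 85 85 85  5 85 15 20 20 ]
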