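# Synthetic Hox-like count matrix with a TTAAT (TAAT-core) consensus,
# constructed for testing and demonstration; not a database motif.
>hox_ubx_like_synthetic
A  [  5  5 85 85  5 10 20 40 ]
C  [  5  5  5  5  5 10 10 20 ]
G  [  5  5  5  5  5 60 50 20 ]
T  [ 85 85  5  5 85 20 20 20 ]
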