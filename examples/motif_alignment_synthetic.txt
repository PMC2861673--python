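# Synthetic example alignment of NBD functional motifs.
# The consensus row mimics a homodimeric bacterial exporter; the
# degenerate rows are constructed illustrations of the substitution
# pattern seen in degenerate eukaryotic nucleotide-binding sites
# (Q-loop D, x-loop R, Walker-B E and signature positions replaced).

# motif: Q_loop
consensus     VSQD
deg_NBD1      VSQN
cons_NBD2     VSQD

# motif: x_loop
consensus     GERG
deg_NBD1      GERG
cons_NBD2     GEQG

# motif: walker_B
consensus     ILLLDE
deg_NBD1      ILLLDD
cons_NBD2     ILLLDE

# motif: signature
consensus     LSGGQ
deg_NBD1      LSGGQ
cons_NBD2     LSVGE

# motif: switch
consensus     SVH
deg_NBD1      SVQ
cons_NBD2     SVH
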