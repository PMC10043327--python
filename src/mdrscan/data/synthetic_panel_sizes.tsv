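# SYNTHETIC stand-in for the per-network post-QC SNP panel sizes of the
# five Wnt interactome panels (the originals are not publicly deposited).
# Reconstructed as the unique five-part integer solution consistent with
# the published totals of 173,425 two-way and 26,125,277 three-way models
# (exhaustive search over all panel-size vectors); total 1,009 SNPs.
# network	n_snps
Wnt5a	526
Wnt11	213
Wnt2	118
Wnt1	89
Wnt5b	63
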