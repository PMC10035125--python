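"""Encode a handful of transcripts into the four feature families.

Builds three short synthetic transcripts, encodes each feature block and
prints the block widths plus a few named components. The widths (1360, 1370,
64, 2368, 768, 48, 144; 6122 in total) are fixed by the alphabet and the
property tables, not by the input sequences.
"""
import subloc as sl

tables = sl.default_tables()
cfg = sl.PseKNCConfig()

seqs = [
    sl.NucleotideSequence("t1", "ATAGCATCAGGATTACCAGTT"),
    sl.NucleotideSequence("t2", "GCGCGCGGCCATGCGCAGTACGT"),
    sl.NucleotideSequence("t3", "AATTTATTAAATATTTCCATAGCA"),
]

fm = sl.build_feature_matrix(seqs, sl.CANONICAL_GROUPS, cfg, tables)
print(f"feature matrix: {fm.data.shape[0]} sequences x "
      f"{fm.data.shape[1]} features")
for group in sl.CANONICAL_GROUPS:
    n = len(fm.schema.columns_in_groups([group]))
    print(f"  {group:>16}: {n} columns")

# a few individual components of the first transcript
for name in ("kmer.k2.AT", "eiip.ATA", "zc48.y.AT", "pseknc.lambda.1"):
    print(f"  {name:>18} = {fm.data.loc['t1', name]:.4f}")
print("kmer.k2.AT is the AT dinucleotide count divided by sequence length;")
print("eiip.ATA weights the ATA frequency by its summed electron-ion")
print("interaction pseudopotential; zc48.y.AT contrasts amino vs keto")
print("bases following the AT prefix.")
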