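"""Map stability/conservation/chromatin/TF signals onto eG4 regions.

Builds a toy genome (eG4 regions with planted pG4 motifs, strand-specific
MM% track, phyloP track, chromatin-state segmentation, ATAC fragments, TF
peaks), runs the full mapping, and prints the per-region metric table.
"""

import g4causal as g

fx = g.make_genome_fixture(seed=11)
print(f"toy genome: {len(fx.regions)} candidate regions "
      f"({int(fx.regions.is_decoy.sum())} pG4-free decoys), "
      f"{len(fx.pg4s)} pG4 loci")

table = g.build_region_table(fx)
cols = ["region_id", "stability", "eg4_signal", "atac", "phylop",
        "chrom_state", "tf_recruitment"]
print(table[cols].to_string(index=False))
# stability = max same-strand MM% in a 150 bp window on the pG4 nearest
# the region midpoint (percent, higher = more thermostable in K+);
# atac = depth-normalised fragment coverage (1.0 = genome average);
# tf_recruitment = total TF peak hits in the region.  Decoy regions are
# absent: the pG4-containment filter removed them.
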