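"""Generate a miniature peptide atlas with planted ground truth.

Builds a 10-chromosome genome with spliced gene models, draws 2000
nonredundant peptides from the three-frame translations (91% planted
in-frame), and simulates 13-tissue label-free abundances for peptides
and their source proteins.
"""

import numpy as np

from pepatlas import synthetic as syn

atlas = syn.generate_atlas(syn.default_config(seed=1))

lengths = atlas.peptides["sequence"].str.len()
in_frame = np.mean([atlas.truth.frame_class[p] == "in_frame"
                    for p in atlas.peptides.index])

print(f"genome: {len(atlas.genome)} chromosomes x "
      f"{len(next(iter(atlas.genome.values()))):,} bp")
print(f"gene models: {len(atlas.models)}")
print(f"peptides: {len(atlas.peptides)} "
      f"({100 * in_frame:.2f}% planted in-frame, "
      f"{100 * (lengths < 23).mean():.1f}% shorter than 23 aa)")
print(f"abundance matrix: {atlas.abundance.shape[0]} peptides x "
      f"{atlas.abundance.shape[1]} tissues; "
      f"protein matrix: {atlas.protein_abundance.shape[0]} genes")

# The truth object records what was planted for every peptide, so any
# downstream result can be scored against it.
pid = atlas.peptides.index[0]
print(f"example truth for {pid}: frame={atlas.truth.frame_class[pid]}, "
      f"gene={atlas.truth.source_gene[pid]}, "
      f"category={atlas.truth.specificity[pid]}")
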