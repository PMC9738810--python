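# Curated default contaminant-genus list (kitome / reagent contamination).
# Compiled from the published negative-control and extraction-kit
# contamination literature; an approximation intended as an editable
# starting point, not a normative reference.  Status semantics:
#   flagged      genus includes species potentially associated with humans;
#                keep but inspect
#   blacklisted  known reagent/environmental contaminant; remove
genus	status
Ralstonia	blacklisted
Bradyrhizobium	blacklisted
Burkholderia	blacklisted
Sphingomonas	blacklisted
Methylobacterium	blacklisted
Delftia	blacklisted
Comamonas	blacklisted
Herbaspirillum	blacklisted
Cupriavidus	blacklisted
Pelomonas	blacklisted
Janthinobacterium	blacklisted
Acidovorax	blacklisted
Caulobacter	blacklisted
Mesorhizobium	blacklisted
Phyllobacterium	blacklisted
Stenotrophomonas	blacklisted
Variovorax	blacklisted
Aquabacterium	blacklisted
Paracoccus	blacklisted
Novosphingobium	blacklisted
Deinococcus	blacklisted
Afipia	blacklisted
Brevundimonas	blacklisted
Chryseobacterium	blacklisted
Curvibacter	blacklisted
Duganella	blacklisted
Hydrogenophaga	blacklisted
Leifsonia	blacklisted
Massilia	blacklisted
Pedobacter	blacklisted
Polaromonas	blacklisted
Rhodoferax	blacklisted
Undibacterium	blacklisted
Escherichia	flagged
Streptococcus	flagged
Staphylococcus	flagged
Corynebacterium	flagged
Cutibacterium	flagged
Propionibacterium	flagged
Neisseria	flagged
Haemophilus	flagged
Bacteroides	flagged
Prevotella	flagged
Lactobacillus	flagged
Enterococcus	flagged
Fusobacterium	flagged
Veillonella	flagged
Acinetobacter	flagged
Pseudomonas	flagged
Micrococcus	flagged
Rothia	flagged
Enterobacter	flagged
Klebsiella	flagged
Serratia	flagged
Bacillus	flagged
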