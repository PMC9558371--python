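# Per-state relative stabilities (kJ/mol) of KIT kinase point mutants, as
# published for the folding cycle: state is the folded conformation the ddG
# refers to; ddG < 0 means the mutant is less stable than WT in that state.
# source column:
#   printed              value printed in the results/discussion text
#   reconstructed        = minus the WT-referenced activation baseline
#                          (19.8 +/- 0.5) stated alongside the 26.3 total
#   printed_alternate    same quantity printed twice with a different SE;
#                          kept so the discrepancy stays visible
#   synthetic_figure_standin  value shown only graphically; the number here
#                          is a synthetic stand-in (correct sign, plausible
#                          magnitude), NOT a published figure
mutation	state	ddg_kJ_per_mol	se_kJ_per_mol	source
D816V	inactive	-19.8	0.5	reconstructed
D816V	active	6.5	1.3	printed
V620A	inactive	-13.7	0.2	printed
V620A	active	-12.1	0.3	printed
G812V	inactive	-1.6	0.5	printed
G812V	inactive	-1.6	0.4	printed_alternate
G812V	active	-12.0	0.7	printed
V559A	inactive	-7.0	1.0	synthetic_figure_standin
V560D	inactive	-9.0	1.0	synthetic_figure_standin
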