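# Unified Watson-Crick nearest-neighbor parameters for DNA duplex stacks,
# 1 M NaCl reference state.
# Source: SantaLucia, J. (1998) "A unified view of polymer, dumbbell, and
# oligonucleotide DNA nearest-neighbor thermodynamics", PNAS 95:1460-1465.
# Stacks are keyed by the top-strand dinucleotide read 5'->3'; the bottom
# strand is its antiparallel Watson-Crick complement.  The 10 unique stacks
# are listed; the other 6 dinucleotides follow by reverse-complement symmetry.
# dH in kcal/mol, dS in cal/(mol*K).
#
# format: version 1
stack_AA_dH -7.9
stack_AA_dS -22.2
stack_AT_dH -7.2
stack_AT_dS -20.4
stack_TA_dH -7.2
stack_TA_dS -21.3
stack_CA_dH -8.5
stack_CA_dS -22.7
stack_GT_dH -8.4
stack_GT_dS -22.4
stack_CT_dH -7.8
stack_CT_dS -21.0
stack_GA_dH -8.2
stack_GA_dS -22.2
stack_CG_dH -10.6
stack_CG_dS -27.2
stack_GC_dH -9.8
stack_GC_dS -24.4
stack_GG_dH -8.0
stack_GG_dS -19.9
# Duplex initiation (one term per duplex; average over terminal base pairs).
init_dH 0.2
init_dS -5.7
# Coarse penalties for imperfect duplexes (kcal/mol, temperature independent):
# a fixed destabilization per internal mismatched position and an affine
# penalty for an internal unpaired stretch (loop) between helical segments.
mismatch_penalty_dG 1.0
loop_open_dG 3.0
loop_extend_dG 0.5
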