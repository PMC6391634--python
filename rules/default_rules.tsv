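# Retrosynthetic cut rules (RECAP-style stand-in; fully configurable).
# Format: rule_id<TAB>SMARTS. The bond to cut lies between the atoms
# mapped :1 and :2; only exocyclic single bonds between heavy atoms are
# ever cut, whatever the pattern matches.
amide	[C:1](=O)-[N:2]
ester	[C:1](=O)-[O;D2:2]
sulfonamide	[S:1](=O)(=O)-[N:2]
amine	[N;X3;!$(N~[!#6]);!$(N-C=[O,S,N]):1]-[C;!$(C=*):2]
ether	[O;D2;!$(O-C=O):1]-[C,c:2]
aromatic_cc	[c:1]-[c:2]
aromatic_n_aliphatic_c	[n:1]-[C:2]
olefin_adjacent	[C;$(C=C):1]-[C;X4:2]
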