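# Ionizable-group pKa values, Lehninger-style free-amino-acid set (Nelson & Cox,
# Lehninger Principles of Biochemistry, 4th ed., Table 3-1; termini averaged over
# the 20 amino acids). version 1.
# group: "nterm"/"cterm" or the one-letter residue code of the ionizable side chain.
# kind: basic groups are positively charged when protonated, acidic groups
# negatively charged when deprotonated.
group,kind,pka
nterm,basic,9.69
cterm,acidic,2.34
D,acidic,3.65
E,acidic,4.25
C,acidic,8.30
Y,acidic,10.07
H,basic,6.00
K,basic,10.53
R,basic,12.48
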