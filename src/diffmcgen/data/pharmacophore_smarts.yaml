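# Pharmacophore feature family definitions, v1.
# Feature position = centroid of the matched atoms (3D) / first matched atom (2D).
donor:
  - "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0]),n&H1&+0]"
acceptor:
  - "[$([O,S;H0;v2]),$([O,S;-]),$([N;v3;!$(N-*=[O,N,P,S])]),n&H0&+0]"
  - "[$([O;H1;v2;!$(*-*=[O,N,P,S])])]"
aromatic:
  - "a1aaaaa1"
  - "a1aaaa1"
hydrophobic:
  - "[CX4;!$(C[#7,#8,#9,#15,#16])]"
positive:
  - "[+1,+2,$([NX3;H2,H1;!$(NC=O);!$(N~[!#6])])]"
negative:
  - "[-1,-2,$([CX3](=O)[OX2H1])]"
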