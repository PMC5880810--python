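# Synthetic TIP reference annotation.
# Coordinates are 1-based and inclusive throughout.  The reference
# sequence is a synthetic six-helix scaffold carrying the published
# TIP signature residues of the FaTIP(a) group at annotated positions.

[reference]
id = TIP_ref_synthetic
class = TIP
sequence = STNNTDSKGTTNLVLFFIFFFLLFVVFLLVLLVIILNPGKPGNKSKNNKGVVLLIVFLIH
    IFIFIILIIFLVFVPQQGNQDSGGHVNPAVTFPGLQTKSIIFLIFLVVLVIILIVALVAF
    FILNSVSDSNGSGKPQGKSILLILIFILLVLVLVLLVLILLLLQKKKIKKKKQDQVLFVI
    LIFLIIVLIIIFFFPLVGASMNPARAFGDDTSSAGADFHVFYFLIPVLIWFFVFVIIFLL
    VILLVFSTNNDS

[npa]
loopB_window = 82 10
loopE_window = 198 11

[arr]
H2 = 60
H5 = 185
LE1 = 199
LE2 = 205

[froger]
P1 = 211
P2 = 214
P3 = 216
P4 = 222
P5 = 230

[sites]
loopB_phospho = 97
loopD_L = 168

[sdp]
h2o2 = 116 119 123 126 182 219 222 224 226
urea = 85 88 92 95 158 195 198 200 202
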