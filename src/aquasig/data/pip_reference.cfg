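# Synthetic PIP reference annotation.
# Coordinates are 1-based and inclusive throughout.  The reference
# sequence is a synthetic six-helix scaffold carrying the published
# PIP signature residues of the FaPIP1;1 group at annotated positions;
# substitute a real translation (e.g. of accession KY453768) by
# replacing [reference] sequence, keeping the coordinates aligned.

[reference]
id = PIP_ref_synthetic
class = PIP
sequence = TPKTSENQQTTPDDSTGPKSDDTKGNQGDPKQPLLLLVLLVVILLIILIFFFLVVLLPND
    NSDQQPGDSTDNSQDPGKDNSNSILLVILILILIIVIFLVFVAFVLLTGGISGGHINPAV
    TFGGFGSSPPSFIVFVILIVILTFFALVGLIFVFFFDSTDTNKQDQQGKENQTGNKTILL
    LVILFEFVVLLLLIVIFFIVFKKHNQNLKKDLFIIHFLIIISILLLLVLATLPIIGTGIN
    PARSLGDKITDTPKGKWIDHWFFVVLPLWIVFIFIFLLIVILIFIQSTG

[npa]
# start length; windows anchored at NPA-5 (loop B) and NPA-4 (loop E)
loopB_window = 112 10
loopE_window = 236 11

[arr]
H2 = 98
H5 = 216
LE1 = 237
LE2 = 243

[froger]
P1 = 170
P2 = 222
P3 = 230
P4 = 263
P5 = 269

[sites]
loopB_Ser = 112
cterm_Ser = 287
loopD_His = 204
loopD_L = 208
methylation_K = 3
methylation_E = 6

[permeability]
TM2 = 103
loopE = 249

[sdp]
boron = 108 111 115 118 186 226 229 231 233
co2 = 136 139 143 146 214 254 257 259 261
h2o2 = 146 149 153 156 220 260 263 265 267
urea = 115 118 122 125 193 233 236 238 240
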