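# Specificity-determining positions (SDPs), Hove-derived transcription.
# residues = <coordinate>:<residue>[/<alternative>] ...; coordinates are
# 1-based on the class reference (see *_reference.cfg).  Boric acid and
# CO2 lists exist only for PIPs; the TIP ammonia SDP entry is omitted
# (not defined), as the published residue listing excludes the TIPs
# considered here.

[meta]
source = hove
kind = sdp

[PIP boron]
residues = 108:T 111:I 115:H 118:P 186:E 226:L 229:L 231:T 233:P

[PIP co2]
residues = 136:V 139:I 143:S 146:A 214:I 254:D 257:W 259:D 261:W

[PIP h2o2]
residues = 146:A 149:G 153:V 156:F 220:I 260:H/Q 263:F 265:V 267:P

[PIP urea]
residues = 115:H 118:P 122:F 125:F 193:L 233:P 236:G 238:G 240:N

[TIP h2o2]
residues = 116:A/S 119:A 123:L 126:V 182:I 219:H 222:Y 224:V 226:P

[TIP urea]
residues = 85:H 88:P 92:F 95:A/L 158:L 195:P 198:G 200:S 202:N
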