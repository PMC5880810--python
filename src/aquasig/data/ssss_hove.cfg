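# Substrate-specific signature sequences, Hove-derived transcription.
# Sections are "<class> <substrate>".  Strings give the expected
# residues over the loop-B window (10), loop-E window (11), Ar/R filter
# (H2 H5 LE1 LE2) and Froger P1-P5; X marks a position the source does
# not constrain.  A missing (class, substrate) section means the source
# defines no signature for that combination ("not defined").
# Silicon is intentionally absent: silicic-acid transport is a NIP
# feature and no PIP/TIP signature exists.

[meta]
source = hove
kind = ssss

[PIP h2o2]
loopB = SGGHINPAVT
loopE = GTGINPARSXG
arr = FHTR
froger = QSAFW

[PIP urea]
loopB = SGGHINPAVT
loopE = GTGINPARSXG
arr = FHTR
froger = QSAFW

[PIP boron]
loopB = SGGHINPAVT
loopE = GTGINPARSLG
arr = FHTR
froger = QSAFW

[PIP co2]
loopB = SGGHINPAVT
loopE = GTGINPARSLG
arr = FHTR
froger = QSAFW

[TIP h2o2]
loopB = SGGHXNPAVT
loopE = GXSMNPARXFG
arr = HIXR
froger = TXAYW

[TIP urea]
loopB = SGGHXNPAVT
loopE = GXSMNPARXFG
arr = HIXR
froger = TXAYW

[TIP ammonia]
loopB = SGGHLNPAVT
loopE = GGSMNPARSFG
arr = HIGR
froger = TSAYW
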