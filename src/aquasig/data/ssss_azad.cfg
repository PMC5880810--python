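# Substrate-specific signature sequences, Azad-derived transcription.
# This source provides no boron signature for PIPs or TIPs and no urea
# signature for PIPs, and its TIP signatures are stricter than the
# Hove-derived ones (they match only the FaTIP(b)-type residues).
# Format as in ssss_hove.cfg.

[meta]
source = azad
kind = ssss

[PIP h2o2]
loopB = SGGHINPAVT
loopE = GTGINPARSXG
arr = FHTR
froger = QSAFW

[PIP co2]
loopB = SGGHINPAVT
loopE = GTGINPARSLG
arr = FHTR
froger = QSAFW

[TIP h2o2]
loopB = SGGHLNPAVT
loopE = GGSMNPARSFG
arr = HIGR
froger = TSAYW

[TIP urea]
loopB = SGGHLNPAVT
loopE = GGSMNPARSFG
arr = HIGR
froger = TSAYW

[TIP ammonia]
loopB = SGGHLNPAVT
loopE = GGSMNPARSFG
arr = HIGR
froger = TSAYW
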