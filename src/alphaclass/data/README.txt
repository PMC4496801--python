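Synthetic consensus-model data set (stand-in; see docs/methods.md).
Generated by scripts/build_consensus_data.py; do not edit by hand.
Format of classes/*.synthetic_counts.txt: header '>LABEL TYPE LENGTH',
then one line per position: pos countA countC countG countT.
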