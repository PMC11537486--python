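# Legacy / literature tRNA gene names mapped to gtRNAdb mm10 identifiers.
# Editable: one alias per line, tab-separated.  Unknown aliases are errors,
# never silent drops.
n-TRtct5	tRNA-Arg-TCT-4-1
n-TFgaa7	tRNA-Phe-GAA-1-1
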