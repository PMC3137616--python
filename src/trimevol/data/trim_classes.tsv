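# Canonical TRIM structural classes keyed by C-terminal domain content
# (domains downstream of the RING/B-box/coiled-coil module).
# columns: trim_class <TAB> comma-separated C-terminal domain set
I	COS,FN3,B30.2
II	COS
III	COS,FN3
IV	B30.2
V
VI	PHD,BROMO
VII	FILAMIN,NHL
VIII	MATH
IX	ARF
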