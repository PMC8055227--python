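# hdxdiff attribute file (chain A)
attribute: hdx
match mode: 1-to-1
recipient: residues
	:1.A	deprotected
	:2.A	deprotected
	:3.A	deprotected
	:4.A	none
	:5.A	protected
	:6.A	protected
	:8.A	mixed
	:9.A	protected
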