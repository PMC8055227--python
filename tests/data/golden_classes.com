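# hdxdiff coloring commands (Chimera)
defattr hdx.defattr
color 0.8431,0.0980,0.1098 :1-3.A
color 0.4824,0.1961,0.5804 :8.A
color 0.8784,0.8784,0.8784 :4.A
color 0.1725,0.4824,0.7137 :5-6,9.A
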