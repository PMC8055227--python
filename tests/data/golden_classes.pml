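# hdxdiff structure coloring (PyMOL)
# chain A, numbering offset +0
set_color hdx_deprotected, [0.8431, 0.0980, 0.1098]
color hdx_deprotected, chain A and resi 1-3
set_color hdx_mixed, [0.4824, 0.1961, 0.5804]
color hdx_mixed, chain A and resi 8
set_color hdx_none, [0.8784, 0.8784, 0.8784]
color hdx_none, chain A and resi 4
set_color hdx_protected, [0.1725, 0.4824, 0.7137]
color hdx_protected, chain A and resi 5-6
color hdx_protected, chain A and resi 9
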