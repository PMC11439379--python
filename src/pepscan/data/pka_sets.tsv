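# pKa sets  v1  columns: set_name  group  pKa
# group is a one-letter ionizable residue code or n_terminus / c_terminus
calibrated	n_terminus	7.7
calibrated	c_terminus	3.55
calibrated	D	4.05
calibrated	E	4.45
calibrated	C	9.0
calibrated	Y	10.0
calibrated	H	6.5
calibrated	K	10.0
calibrated	R	12.5
emboss	n_terminus	8.6
emboss	c_terminus	3.6
emboss	D	3.9
emboss	E	4.1
emboss	C	8.5
emboss	Y	10.1
emboss	H	6.5
emboss	K	10.8
emboss	R	12.5
lehninger	n_terminus	9.69
lehninger	c_terminus	2.34
lehninger	D	3.65
lehninger	E	4.25
lehninger	C	8.33
lehninger	Y	10.07
lehninger	H	6.0
lehninger	K	10.53
lehninger	R	12.48
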