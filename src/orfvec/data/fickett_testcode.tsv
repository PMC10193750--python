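# Fickett TESTCODE lookup constants.
# Source publication: Fickett J.W. (1982) "Recognition of protein coding
# regions in DNA sequences", Nucleic Acids Research 10(17):5303-5318.
# version: 1
# kind: rows are lookup categories; 'position' rows are indexed by the
#   position-parameter thresholds and 'content' rows by the content-parameter
#   thresholds (first threshold whose value the parameter reaches, scanning
#   left to right); 'weight' rows give the per-base combination weights.
kind	base	values
position_threshold	*	1.9	1.8	1.7	1.6	1.5	1.4	1.3	1.2	1.1	0.0
position_prob	A	0.51	0.55	0.57	0.52	0.48	0.58	0.57	0.54	0.50	0.36
position_prob	C	0.29	0.44	0.55	0.49	0.52	0.60	0.60	0.56	0.51	0.38
position_prob	G	0.62	0.67	0.74	0.65	0.61	0.62	0.66	0.58	0.52	0.41
position_prob	T	0.51	0.60	0.69	0.64	0.62	0.67	0.58	0.48	0.39	0.24
position_weight	A	0.26
position_weight	C	0.18
position_weight	G	0.31
position_weight	T	0.33
content_threshold	*	0.33	0.31	0.29	0.27	0.25	0.23	0.21	0.19	0.17	0.00
content_prob	A	0.40	0.55	0.58	0.58	0.52	0.48	0.45	0.45	0.38	0.19
content_prob	C	0.50	0.63	0.59	0.50	0.41	0.30	0.33	0.29	0.23	0.21
content_prob	G	0.21	0.40	0.58	0.61	0.64	0.64	0.63	0.40	0.27	0.17
content_prob	T	0.30	0.49	0.56	0.53	0.48	0.48	0.34	0.20	0.09	0.09
content_weight	A	0.11
content_weight	C	0.12
content_weight	G	0.15
content_weight	T	0.14
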