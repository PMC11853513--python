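# Structured-UMI design library.
# design_name	pattern_string
# `reference` is the conventional fully randomized 12-mer (diversity 4^12 =
# 16,777,216).  `a_structured` interleaves fixed adenines among twelve
# randomized positions ("NNNN A NNNN A NNNN" style), keeping full 12-N
# diversity while suppressing cross-hybridization.  Entries suffixed
# `_exemplar` are synthetic representatives of diversity classes (ten-N,
# eleven-N, ten-N-plus-one-twofold, all-twofold), not transcriptions of any
# published oligo.
design_name	pattern_string
reference	NNNNNNNNNNNN
a_structured	NNNNANNNNANNNN
ten_n_exemplar	NNNNNNNNNN
eleven_n_exemplar	NNNNNNNNNNN
ten_n_plus_s_exemplar	NNNNNNNNNNS
twofold_14mer_exemplar	SWSWSWSWSWSWSW
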