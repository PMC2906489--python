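# pattern_id	keyword	directional	template
# Template tokens: A / B protein slots, "..." unbounded gap, (x|y) alternation,
# bare words match their inflection set (keyword forms) or themselves (literals).
INT-1	interact	no	A interact with B
INT-2	interact	no	interaction of A (with|and) B
INT-3	interact	no	interaction between A and B
INT-4	interact	no	interaction among A and B
INT-5	interact	no	A - B interact
INT-6	interact	no	A and B interact
ASC-1	associate	no	A associate with B
ASC-2	associate	no	association between A and B
ASC-3	associate	no	association of A (with|and) B
ASC-4	associate	no	A and B associated with each other
BND-1	bind	no	binding of A to B
BND-2	bind	no	A and B bind
BND-3	bind	no	binding between A and B
BND-4	bind	no	A bind B
CPX-1	complex	no	A (-|/) B complex
CPX-2	complex	no	A and B complex
CPX-3	complex	no	complex A and B
CPX-4	complex	no	A complex with B
CPX-5	complex	no	complex ... (contains|contain|contained|containing) A and B
CPX-6	complex	no	A complex B
ACT-1	activate	yes	A activate B
REG-1	regulate	yes	A regulate B
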