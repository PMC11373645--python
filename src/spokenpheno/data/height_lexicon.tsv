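phrase	bin
no growth	0
did not grow	0
nothing grew	0
no emergence	0
dead plants	0
very short plants	1
extremely short	1
tiny plants	1
stunted plants	1
barely grew	1
short plants	2
short	2
small plants	2
short row	2
short to medium height	3
below average height	3
somewhat short plants	3
on the shorter side	3
medium height plants	4
medium height	4
average height	4
intermediate height	4
medium-tall plants	5
medium tall	5
moderately tall plants	5
fairly tall plants	5
tall	6
tall plants	6
tall height	6
tall row	6
very tall plants	7
very tall	7
extremely tall	7
super tall	7
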