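text	role	subset
help	stem	A
soft	stem	A
last	stem	A
ship	stem	A
stop	stem	A
hold	stem	A
park	stem	B
jump	stem	B
town	stem	B
bird	stem	B
farm	stem	B
milk	stem	B
josk	nonstem	A
terp	nonstem	A
firn	nonstem	A
bron	nonstem	A
trum	nonstem	A
burk	nonstem	A
molp	nonstem	B
lort	nonstem	B
bemp	nonstem	B
jelt	nonstem	B
culp	nonstem	B
tand	nonstem	B
ity	suffix	A
ive	suffix	A
ory	suffix	A
ure	suffix	A
ous	suffix	A
ise	suffix	A
ful	suffix	B
ist	suffix	B
ite	suffix	B
ish	suffix	B
ese	suffix	B
ess	suffix	B
ert	nonsuffix	A
une	nonsuffix	A
ute	nonsuffix	A
int	nonsuffix	A
ald	nonsuffix	A
ere	nonsuffix	A
sal	nonsuffix	B
arn	nonsuffix	B
ene	nonsuffix	B
ult	nonsuffix	B
oke	nonsuffix	B
ust	nonsuffix	B
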