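eee
mmm
hmm
aaa
eeem
uuu
eh
ah
uh
oh
aha
mhm
no
ja
ne
pač
torej
tako
potem
čakaj
mislim
recimo
okej
evo
pol
ziher
itak
ojej
uf
ono
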