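voda
zrak
ogenj
zemlja
dan
noč
jutro
večer
človek
otrok
ženska
moški
roka
noga
glava
oko
uho
nos
usta
srce
delo
igra
pesem
beseda
stvar
čas
leto
dan
pot
svet
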