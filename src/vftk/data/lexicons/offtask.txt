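miza
stol
okno
vrata
reka
gora
cesta
hiša
avto
knjiga
svinčnik
telefon
računalnik
sonce
dež
sneg
veter
morje
drevo
roža
trava
kamen
most
mesto
vas
šola
bolnica
trgovina
kruh
mleko
sir
jabolko
hruška
krompir
čevelj
srajca
ura
ključ
denar
pismo
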