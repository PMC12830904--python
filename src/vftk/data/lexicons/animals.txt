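lev
tiger
medved
volk
lisica
zajec
srna
jelen
slon
žirafa
kača
krava
konj
prašič
ovca
koza
pes
mačka
miš
podgana
veverica
jež
netopir
kit
delfin
riba
orel
sokol
vrana
golob
vrabec
sova
štorklja
labod
raca
gos
kokoš
petelin
puran
pav
papiga
kanarček
žolna
kukavica
lastovka
škorec
sinica
ščinkavec
čaplja
galeb
pingvin
noj
emu
kenguru
koala
panda
gorila
šimpanz
opica
pavijan
lemur
lenivec
pasavec
krokodil
aligator
želva
kuščar
legvan
gekon
žaba
krastača
pupek
močerad
polž
školjka
hobotnica
ligenj
rak
jastog
kozica
meduza
som
krap
ščuka
postrv
losos
tuna
sardela
slanik
jegulja
kobilica
čriček
murn
metulj
vešča
čebela
osa
sršen
čmrlj
mravlja
termit
hrošč
pikapolonica
komar
muha
obad
pajek
škorpijon
klop
bolha
gosenica
deževnik
pijavka
hijena
šakal
kojot
dingo
puma
jaguar
gepard
leopard
ris
panter
bizon
bivol
antilopa
gazela
zebra
nosorog
tapir
lama
alpaka
kamela
dromedar
osel
mula
poni
žrebec
kobila
tele
jagnje
hrček
činčila
dihur
kuna
podlasica
hermelin
vidra
bober
svizec
polh
krt
rovka
gams
kozorog
muflon
merjasec
lane
košuta
los
sob
morž
tjulenj
orka
beluga
narval
oroslan
velblod
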