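lev
led
lek
les
lep
lem
len
lesa
leto
lice
list
lipa
luna
lok
lom
lov
lot
las
lak
lan
laž
luč
luža
lug
lup
lupa
lupina
lonec
lopata
ladja
lestev
letalo
lakota
lastnost
lahkota
lepota
lenoba
lega
leča
leder
lutka
lojtra
lokal
lokacija
logika
lubje
lovec
ledenik
ledvica
legenda
lekarna
lektor
lepilo
lesketanje
lesnina
letnica
letos
letev
liman
limona
linija
lira
lisa
liter
litje
ljubezen
ljudstvo
lobanja
logar
lojalnost
lokostrelec
lomilec
lopar
losion
loščilo
lotos
lovorika
lucerna
luknja
lukenj
lunapark
lupljenje
luska
luksuz
lulček
lekcija
lament
lasulja
lastovičnik
latnik
lazur
lebdenje
ledina
legija
lemež
lepenka
lesk
lesketati
letak
letalstvo
letina
levji
lezenje
ležaj
ležišče
libela
liberalec
licenca
ličilo
likalnik
likovnik
limanica
limuzina
lingvist
lirika
lisjak
listje
listina
litografija
liturgija
livada
ljubček
ljubica
ljudomrznik
lobist
ločitev
ločnica
lodrica
logaritem
logopedija
lojtrnik
lokomotiva
lončar
lopa
lord
lornjon
lososovina
lota
loterija
lotenje
lovišče
lovstvo
loža
lubadar
lucidnost
lučaj
luknjač
lump
lunin
lupinar
luskina
lustracija
luteranec
ljubeznivec
lepoglasje
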