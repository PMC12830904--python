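oroslan
velblod
ljubeznivec
lepoglasje
potemtakem
vendarle
zategadelj
naposled
kajpak
docela
bržkone
malodane
skorajda
nemara
čislan
blagor
milostljiv
vsekakor
skratka
spoštovanje
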