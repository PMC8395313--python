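>LasioIII amidated | Lasioglossin LL-III, hymenopteran venom
VNWKKILGKIIKVVK
>Macro1 amidated | Macropin 1, hymenopteran venom
GFGMALKLLKKVL
>TempoLa amidated | Temporin-La, anuran skin
LLRHVVKILEKYL
>FK-16 amidated | cathelicidin fragment of LL-37
FKRIVQRIKDFLRNLV
>LL-37 amidated | human cathelicidin
LLGDFFRKSKEKIGKEFKRIVQRIKDFLRNLVPRTES
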