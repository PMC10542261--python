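compound_id,technique,matrix,citation
eg-aromadendrine,GC-FID,essential oil,CR25
eg-aromadendrine,GC-MS,essential oil,CR101
eg-terpineol,GC-FID,essential oil,CR25
eg-terpineol,GC-MS,essential oil,CR101
eg-globulol,GC-FID,essential oil,CR25
eg-globulol,GC-MS,essential oil,CR101
eg-cineol,GC-FID,essential oil,CR25
eg-cineol,GC-MS,essential oil,CR101
av-aloin-a,HPLC-DAD/MS,whole leaf,CR102
av-aloin-b,HPLC-DAD/MS,whole leaf,CR102
av-aloe-emodin,HPLC-DAD/MS,whole leaf,CR102
av-acemannan,size-exclusion chromatography,gel,CR103
av-acemannan,UV-Vis spectrophotometry,gel,CR104
ac-lupeol,HPLC-DAD,stem bark,CR105
ac-lupenone,HPLC-DAD,stem bark (Albizia inundata),CR107
ac-betulinic-acid,HPLC-DAD,stem bark (Albizia lebbeck),CR108
ac-catechin,HPLC-DAD,stem bark (Albizia lebbeck),CR109
mi-mangiferin,HPLC-UV,leaves,CR110
mi-catechin,HPLC-UV,stem bark,CR111
mi-epicatechin,HPLC,stem bark,CR112
mi-epicatechin,HPLC,stem bark,CR113
mi-gallic-acid,HPLC-UV,stem bark,CR111
mi-quercetin,HPLC-UV,leaves,CR111
ai-azadirachtin,HPLC-UV,oil and leaf,CR114
ai-nimbin,HPLC-UV,oil,CR115
ai-nimbolide,HPLC-UV,leaf,CR116
zo-12-gingerol,HPLC-MS,rhizome,CR117
zo-10-gingerol,HPLC-MS,rhizome,CR117
zo-8-gingerol,HPLC-MS,rhizome,CR117
zo-6-gingerol,HPLC-MS,rhizome,CR117
zo-6-shogaol,HPLC-MS,rhizome,CR117
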