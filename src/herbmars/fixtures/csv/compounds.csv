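compound_id,name,plant,documented_constituent,conc_raw_text,conc_determined,conc_low,conc_high,conc_unit,conc_basis,toxic,recorded_a,recorded_b,recorded_c,recorded_d,recorded_e,recorded_f,recorded_total
eg-aromadendrine,aromadendrine,Eucalyptus globulus,true,10–30% of essential oil,true,10.0,30.0,percent_w_w,essential oil,false,1,2,1,1,1,1,7
eg-terpineol,α-terpineol,Eucalyptus globulus,true,0.50% of essential oil,true,0.5,0.5,percent_w_w,essential oil,false,1,3,1,1,1,1,8
eg-globulol,globulol,Eucalyptus globulus,true,10–11% of essential oil,true,10.0,11.0,percent_w_w,essential oil,false,1,1,1,1,1,1,6
eg-cineol,"1,8-cineol",Eucalyptus globulus,true,97.32% of essential oil,true,97.32,97.32,percent_w_w,essential oil,false,1,3,1,1,1,1,8
av-aloin-a,aloin A,Aloe vera,true,0.1–0.6% of leaf,true,0.1,0.6,percent_w_w,leaf,true,1,3,1,1,1,1,8
av-aloin-b,aloin B,Aloe vera,true,10–30% of latex,true,10.0,30.0,percent_w_w,latex,true,1,3,1,1,1,1,8
av-aloe-emodin,aloe emodin,Aloe vera,true,0.09–0.29 mg/g of whole leaf,true,0.09,0.29,mg_per_g,whole leaf,true,1,2,1,1,1,1,7
av-acemannan,acemannan,Aloe vera,true,109-135ppm of gel,true,109.0,135.0,ppm,gel,false,1,3,1,1,1,1,8
av-m6p,mannose 6-phosphate,Aloe vera,true,ND,false,,,,,false,1,1,0,0,1,0,3
ac-lupeol,lupeol,Albizia coriaria,true,1–6 mg/g of stembark,true,1.0,6.0,mg_per_g,stembark,false,1,3,1,1,1,1,8
ac-lupenone,lupenone,Albizia coriaria,true,19–200 ppm of stem bark,true,19.0,200.0,ppm,stem bark,false,1,1,1,1,1,1,6
ac-betulinic-acid,betulinic acid,Albizia coriaria,true,1.2–10 mg/g of stem bark,true,1.2,10.0,mg_per_g,stem bark,false,1,3,1,1,1,1,8
ac-catechin,catechin,Albizia coriaria,true,0.2–12 mg/g of stem bark,true,0.2,12.0,mg_per_g,stem bark,false,1,3,1,1,1,1,8
mi-mangiferin,mangiferin,Mangifera indica,true,5–20 mg/g of leaves,true,5.0,20.0,mg_per_g,leaves,false,1,3,1,1,1,1,8
mi-catechin,catechin,Mangifera indica,true,71.4 mg/g of stem bark,true,71.4,71.4,mg_per_g,stem bark,false,1,3,1,1,1,1,8
mi-epicatechin,epicatechin,Mangifera indica,true,8.07 mg/g of stem bark,true,8.07,8.07,mg_per_g,stem bark,false,1,1,1,1,0,1,5
mi-gallic-acid,gallic acid,Mangifera indica,true,2.08 mg/g of stem bark,true,2.08,2.08,mg_per_g,stem bark,false,1,3,1,1,1,1,8
mi-quercetin,quercetin,Mangifera indica,true,0.76 to 1.16 mg/g of leaves,true,0.76,1.16,mg_per_g,leaves,false,1,3,1,1,1,1,8
ai-azadirachtin,azadirachtin,Azadirachta indica,true,3.8 to 4.8 mg/g of seeds,true,3.8,4.8,mg_per_g,seeds,false,1,3,1,1,1,1,8
ai-nimbin,nimbin,Azadirachta indica,true,0.018 to 0.64 mg/g of oil,true,0.018,0.64,mg_per_g,oil,false,1,3,1,1,1,1,8
ai-nimbolide,nimbolide,Azadirachta indica,true,0.9–6.7 mg/g of leaf,true,0.9,6.7,mg_per_g,leaf,false,1,2,1,1,1,1,7
ai-mahmoodin,mahmoodin,Azadirachta indica,true,Not determined,false,,,,,false,1,2,1,1,0,0,5
zo-12-gingerol,12-gingerol,Zingiber officinale,true,0.01–0.02 mg/g of rhizome,true,0.01,0.02,mg_per_g,rhizome,false,1,2,1,1,0,1,6
zo-10-gingerol,10-gingerol,Zingiber officinale,true,0.2–0.4 mg/g of rhizome,true,0.2,0.4,mg_per_g,rhizome,false,1,2,1,1,1,1,7
zo-8-gingerol,8-gingerol,Zingiber officinale,true,0.4–0.5 mg/g of rhizome,true,0.4,0.5,mg_per_g,rhizome,false,1,1,1,1,1,1,6
zo-6-gingerol,6-gingerol,Zingiber officinale,true,1.1-2.0 mg/g of rhizome,true,1.1,2.0,mg_per_g,rhizome,false,1,3,1,1,1,1,8
zo-6-shogaol,6-shogaol,Zingiber officinale,true,0.01–0.02 mg/g of rhizome,true,0.01,0.02,mg_per_g,rhizome,false,1,3,1,1,1,1,8
zo-zingerone,zingerone,Zingiber officinale,true,ND,false,,,,,false,1,2,0,0,1,1,5
wu-bemadienolide,bemadienolide,Warburgia ugandensis,true,ND,false,,,,,false,1,0,0,0,0,0,1
wu-muzigadial,muzigadial,Warburgia ugandensis,true,ND,false,,,,,false,1,1,0,0,0,0,2
wu-polygodial,polygodial,Warburgia ugandensis,true,ND,false,,,,,false,1,2,0,0,1,0,3
wu-warbuganal,warbuganal,Warburgia ugandensis,true,ND,false,,,,,false,1,1,0,0,0,0,2
wu-warbugin,warbugin,Warburgia ugandensis,true,ND,false,,,,,false,1,0,0,0,0,0,1
wu-ugandensidial,ugandensidial,Warburgia ugandensis,true,ND,false,,,,,false,1,1,0,0,0,0,2
wu-ugandensolide,ugandensolide,Warburgia ugandensis,true,ND,false,,,,,false,1,0,0,0,0,0,1
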