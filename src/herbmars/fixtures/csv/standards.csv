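compound_id,vendor,grade,pack_value,pack_unit,price_eur
eg-aromadendrine,Sigma-Aldrich/Supelco,analytical standard,5,mg,530.0
eg-aromadendrine,Sigma-Aldrich/Supelco,"HPLC grade, >=95%",10,mg,221.0
eg-aromadendrine,Sigma-Aldrich/Supelco,"LC/MS-ELSD, >=95%",1,mg,421.0
eg-terpineol,Sigma-Aldrich/Supelco,"analytical standard, >=95%",100,mg,63.9
eg-globulol,Sigma-Aldrich,">=98.5% (sum of enantiomers, GC)",100,mg,247.0
eg-cineol,Sigma-Aldrich/Supelco,analytical standard,1,mL,48.3
av-aloin-a,Sigma-Aldrich,analytical standard,10,mg,440.0
av-aloin-b,Sigma-Aldrich,Phyproof reference substance,10,mg,605.0
av-aloe-emodin,Sigma-Aldrich,analytical standard,10,mg,311.0
av-acemannan,Toronto Research Chemicals,technical grade,10,mg,208.3
av-m6p,Sigma-Aldrich,">=98% (HPLC), sodium salt",100,mg,354.0
ac-lupeol,Sigma-Aldrich,analytical standard,10,mg,130.0
ac-lupenone,Toronto Research Chemicals,analytical standard,2.5,mg,170.0
ac-betulinic-acid,Sigma-Aldrich/Supelco,analytical standard,10,mg,95.1
ac-betulinic-acid,Sigma-Aldrich/Supelco,>=98% (HPLC),5,mg,70.0
ac-catechin,Sigma-Aldrich/Supelco,analytical standard,10,mg,307.0
mi-mangiferin,Sigma-Aldrich/Supelco,analytical standard,10,mg,108.0
mi-catechin,Sigma-Aldrich/Supelco,analytical standard,10,mg,307.0
mi-gallic-acid,Sigma-Aldrich,Phyproof reference substance,10,mg,345.0
mi-quercetin,Sigma-Aldrich,USP reference standard,200,mg,357.0
mi-quercetin,Sigma-Aldrich,Phyproof reference substance,20,mg,253.0
mi-quercetin,Sigma-Aldrich,>=95% (HPLC),10,g,68.3
ai-azadirachtin,Sigma-Aldrich,Phyproof reference substance,5,mg,403.0
ai-azadirachtin,Sigma-Aldrich,~95%,0.5,mg,249.0
ai-nimbin,Toronto Research Chemicals,analytical standard,1,mg,105.0
ai-nimbolide,Sigma-Aldrich,>=98%,5,mg,624.0
zo-10-gingerol,Sigma-Aldrich,analytical standard,10,mg,546.0
zo-10-gingerol,Sigma-Aldrich,>=98% (HPLC),5,mg,276.0
zo-10-gingerol,Sigma-Aldrich,Phyproof reference substance,10,mg,472.0
zo-8-gingerol,Sigma-Aldrich/Supelco,analytical standard,10,mg,489.0
zo-6-gingerol,Sigma-Aldrich,analytical standard,10,mg,448.0
zo-6-gingerol,Sigma-Aldrich,>=98% (HPLC),5,mg,358.0
zo-6-gingerol,Sigma-Aldrich,Phyproof reference substance,10,mg,472.0
zo-6-shogaol,Sigma-Aldrich,analytical standard,10,mg,538.0
zo-6-shogaol,Sigma-Aldrich,Phyproof reference substance,10,mg,657.0
zo-zingerone,Sigma-Aldrich,analytical standard,50,mg,84.5
wu-polygodial,Sigma-Aldrich,>=97% (HPLC),10,mg,216.0
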