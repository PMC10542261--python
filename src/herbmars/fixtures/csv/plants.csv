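botanical_name,family,source,part_used,dosage_forms
Eucalyptus globulus,Myrtaceae,both,leaf oil,mouth wash;cough syrup;pain balm
Aloe vera,Asphodelaceae,cultivated,whole leaf;gel,mouth wash;aloe tablets;cough syrup;lip balm
Albizia coriaria,Fabaceae,wild,stem bark,cough syrup
Mangifera indica,Anacardiaceae,both,stem bark;leaves,cough syrup
Warburgia ugandensis,Canellaceae,both,stem bark;leaves,cough syrup;antiulcer syrup
Azadirachta indica,Meliaceae,both,stem bark;leaves;seed oil,cough syrup;antiulcer syrup;lip balm
Zingiber officinale,Zingiberaceae,cultivated,rhizome,cough syrup
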