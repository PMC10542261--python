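plant,condition,symptoms
Eucalyptus globulus,oral and dental conditions,toothache;bad odor;sensitivity;bleeding gums;tooth cavities;tooth decay;antibacterial;mouth sores
Eucalyptus globulus,respiratory tract disorders,cough;common cold;catarrh;sore throat;congestion from asthma;bronchitis;whooping cough;sinusitis;rhinitis;hiccups;relieving fever;measles symptoms
Eucalyptus globulus,pain and inflammation,pain relief
Aloe vera,oral and dental conditions,toothache;bad odor;sensitivity;bleeding gums;tooth cavities;tooth decay;antibacterial
Aloe vera,gastrointestinal cleansing,cleanses git
Aloe vera,respiratory tract disorders,cough;flu;sore throat;sinusitis
Aloe vera,lip care,dry cracked painful lips
Albizia coriaria,respiratory tract disorders,whooping cough;catarrh;sore throat;congestion from asthma;bronchitis;relieving fever;sinusitis
Mangifera indica,respiratory tract disorders,whooping cough;catarrh;sore throat;congestion from asthma;bronchitis
Warburgia ugandensis,respiratory tract disorders,cough;flu;mouth sores;measles symptoms;common colds;sinusitis;rhinitis;asthma;catarrh;whooping cough;bronchial congestion;hiccups
Warburgia ugandensis,gastric ulcers,git ulcers
Azadirachta indica,respiratory tract disorders,cough;flu;sore throat;sinusitis
Azadirachta indica,gastrointestinal disorders,gastric ulcers;stomach ulcers;flatulence;constipation
Azadirachta indica,lip care,dry cracked painful lips
Zingiber officinale,respiratory tract disorders,allergic cough;smokers cough;whooping cough;productive cough;flu;lung cleaning;sore throat;sinusitis;bronchial asthma;relieving fever
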