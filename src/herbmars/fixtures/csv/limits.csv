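compound_id,authority,analyte,limit_ppm,direction
,International Aloe Science Council,total anthraquinone glycosides (as aloin),10.0,maximum
,European Medicines Agency,total anthraquinone glycosides (as aloin),0.0,maximum
,US Food and Drug Administration,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloin-a,International Aloe Science Council,total anthraquinone glycosides (as aloin),10.0,maximum
av-aloin-a,European Medicines Agency,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloin-a,US Food and Drug Administration,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloin-b,International Aloe Science Council,total anthraquinone glycosides (as aloin),10.0,maximum
av-aloin-b,European Medicines Agency,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloin-b,US Food and Drug Administration,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloe-emodin,International Aloe Science Council,total anthraquinone glycosides (as aloin),10.0,maximum
av-aloe-emodin,European Medicines Agency,total anthraquinone glycosides (as aloin),0.0,maximum
av-aloe-emodin,US Food and Drug Administration,total anthraquinone glycosides (as aloin),0.0,maximum
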