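species,english_name,group,cites_listed,amplifies_bs1,amplifies_bs2,visual_distinguishable,dl_distinguishable,dl_misassignment_risk
Alopias pelagicus,Pelagic thresher,shark,Yes,Yes,Yes,Yes,Yes,No
Alopias superciliosus,Bigeye thresher,shark,Yes,Yes,Yes,Yes,Yes,No
Carcharhinus falciformis,Silky shark,shark,Yes,Yes,No,No,Yes,No
Carcharhinus longimanus,Oceanic whitetip shark,shark,Yes,No,Yes,Yes,No,No
Isurus oxyrinchus,Shortfin mako shark,shark,Yes,No,Yes,Yes,Yes,Yes
Isurus paucus,Longfin mako shark,shark,Yes,Yes,Yes,Yes,Yes,Yes
Lamna nasus,Porbeagle shark,shark,Yes,No,Yes,Yes,Yes,No
Sphyrna lewini,Scalloped hammerhead,shark,Yes,Yes,Yes,Yes,Yes,No
Sphyrna mokarran,Great hammerhead,shark,Yes,Yes,Yes,Yes,Yes,No
Carcharhinus brevipinna,Spinner shark,shark,Yes,Yes,No,Yes,Yes,No
Carcharhinus sorrah,Spot-tail shark,shark,Yes,Yes,Yes,Yes,No,No
Prionace glauca,Blue shark,shark,Yes,Yes,No,No,Yes,Yes
Anoxypristis cuspidata,Knifetooth sawfish,ray,Yes,Yes,Yes,Yes,Yes,No
Glaucostegus typus,Giant shovelnose ray,ray,Yes,No,No,No,No,No
Mobula birostris,Giant oceanic manta ray,ray,Yes,Yes,Yes,No,Yes,No
Mobula mobular,Giant devil ray,ray,Yes,Yes,Yes,No,Yes,No
Mobula tarapacana,Sicklefin devil ray,ray,Yes,Yes,Yes,Yes,Yes,No
Pristis pristis,Largetooth sawfish,ray,Yes,No,Yes,Yes,Yes,No
Rhina ancylostoma,Bowmouth guitarfish,ray,Yes,Yes,Yes,Yes,Yes,No
Rhynchobatus australiae,Whitespotted guitarfish,ray,Yes,Yes,Yes,Yes,Yes,No
Rhynchobatus laevis,Smoothnose wedgefish,ray,Yes,No,Yes,Yes,Yes,Yes
Rhynchobatus springeri,Broadnose wedgefish,ray,Yes,Yes,Yes,Yes,Yes,Yes
Galeocerdo cuvier,Tiger shark,shark,No,No,No,No,No,No
Stegostoma fasciatum,Zebra shark,shark,No,Yes,Yes,Yes,No,No
Gymnura poecilura,Longtail butterfly ray,ray,No,Yes,Yes,Yes,Yes,No
Himantura imbricata,Bengal whipray,ray,No,Yes,Yes,Yes,Yes,No
Neotrygon orientalis,Oriental bluespotted maskray,ray,No,Yes,Yes,Yes,Yes,No
Telatrygon zugei,Pale-edged stingray,ray,No,Yes,Yes,Yes,Yes,No
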