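abbrev,species,iv,bs_overall,bs_ph,bs_tk,bs_ak
Hh,Heptapleurum heptaphyllum,7.63,3.23,2.22,2.02,2.14
Lr,Litsea rotundifolia var. oblongifolia,6.24,3.45,2.25,2.30,2.34
Ss,Symplocos sumuntia,5.67,3.47,2.26,2.32,2.28
Rt,Rhodomyrtus tomentosa,5.58,2.93,1.98,2.00,1.80
Mp1,Mussaenda pubescens,4.88,3.40,2.33,2.21,2.25
Sc,Smilax china,3.99,3.55,2.36,2.37,2.31
Gj,Gardenia jasminoides,3.88,3.43,2.24,2.25,2.31
Am,Adinandra millettii,3.68,3.26,2.09,2.25,2.17
Pa1,Psychotria asiatica,3.21,3.03,2.13,2.13,2.02
Mm,Melastoma malabathricum,3.08,2.98,2.07,2.12,2.09
Sh,Syzygium hancei,2.82,2.70,1.68,1.63,2.04
Lc,Loropetalum chinense,2.73,2.82,2.13,1.97,1.92
Ip,Ilex pubescens,2.42,3.50,2.31,2.35,2.30
Mp2,Melicope pteleifolia,2.16,2.94,2.00,2.10,2.04
Ia,Ilex asprella,1.83,2.71,1.83,2.01,2.02
Ts,Toxicodendron succedaneum,1.74,3.32,2.29,2.20,2.32
Pa2,Pseudosasa amabilis,1.57,2.02,1.48,1.83,1.48
En,Eurya nitida,1.45,3.02,2.17,2.18,2.09
Sl,Smilax lanceifolia,1.35,1.95,1.80,1.55,1.21
Rc,Rubus corchorifolius,1.21,2.67,1.88,1.76,2.09
Sg,Smilax glabra,1.19,3.20,2.18,2.17,2.23
It,Ilex triflora,1.06,3.03,2.24,1.87,2.18
As,Alyxia sinensis,1.05,2.92,2.02,1.99,2.13
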