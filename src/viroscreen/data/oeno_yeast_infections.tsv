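Strain	ScV-L-A	ScV-M2	ScV-Mlus	ScV-L-BC	SbTV1	ScCV1	ScNV-20S	SbMV1
Lalvin ICV D254	ScV-LA-lus-D254(20.25)		ScV-Mlus-D254(19.33)	ScV-LBC-La-D254(26.86)		ScCV1-D254-RNA1(19.58)
Lalvin Rhone L2226	ScV-LA2-L2226(23.17)	ScV-M2-L2226(21.04)
Lalvin EC1118	ScV-LA2-EC118(22.34)	ScV-M2-EC118(20.44)		ScV-LBC2-EC1118(26.37)
Lalvin RC212				ScV-LBC-La-RC212(26.22)
Lalvin Rhone 2323	ScV-LA2-2323(23.05)	ScV-M2-2323(19.05)
Lalvin QA23	ScV-LA2-QA23(22.33)	ScV-M2-QA23(18.23)		ScV-LBC2-QA23(26.91)
Uvaferm 43	ScV-LA-lus-U43(24.28)	ScV-M2-U43(18.18)				ScCV1-U43-RNA1(20.71)
Zymaflore VL1	ScV-LA2-VL1(22.78)	ScV-M2-VL1(18.61)
Zymaflore X5	ScV-LA2-X5(23.61)	ScV-M2-X5(21.68)		ScV-LBC2-X5(27.08)
Zymaflore FX10	ScV-LA2-FX10(22.51)	ScV-M2-FX10(21.33)
Fermicru VR5	ScV-LA2-VR5(22.72)	ScV-M2-VR5(21.47)		ScV-LBC2-VR5(27.72)
PDM	ScV-LA2-PDM(23.50)	ScV-M2-PDM(21.78)		ScV-LBC2-PDM(28.30)
EZFERM44	ScV-LA2-EZ44(24.38)	ScV-M2-EZ44(20.56)		ScV-LBC2-EZ44(28.01)
NDA21							ScNV-20S-NDA21(18.00)
Cz12					SbTV1-Cz12(20.35)			SbMV1-Cz12(22.92)
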