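drug_1	grmax_1	drug_2	grmax_2	dgis	zip
Irinotecan	0.55	Selumetinib	0.85	-1.19	-4.355
PD-184352	0.04	Sorafenib	-0.94	-1.18	-2.113
Bosutinib	0.11	Niclosamide	-0.22	-1.05	1.531
Vemurafenib	-0.66	Vorinostat	0.03	-1.04	-0.932
Epirubicin	-0.31	Vemurafenib	-0.66	-0.99	9.855
Bortezomib	-0.49	Foretinib	-0.59	-0.98	-0.807
Alectinib	0	Irinotecan	0.55	-0.91	160
Foretinib	-0.59	Vorinostat	0.03	-0.9	2.107
Bortezomib	-0.49	Epirubicin	-0.31	-0.89	-2.129
Bortezomib	-0.49	Vorinostat	0.03	-0.87	3.605
3-Bromopyruvic acid	-0.64	Vemurafenib	-0.66	-0.85	24.096
Purvalanol-A	-0.62	Tozasertib	-0.56	-0.84	1.198
Bortezomib	-0.49	AG-1478	-0.63	-0.81	9.904
Afatinib	-0.77	Crizotinib	-0.53	-0.8	-0.154
Sorafenib	-0.94	Topotecan	-0.37	-0.78	-3.851
Bortezomib	-0.49	Trametinib	0.69	-0.76	-2.344
Epirubicin	-0.31	Sorafenib	-0.94	-0.72	24.209
MG-132	-0.41	Tozasertib	-0.56	-0.7	4.404
Roscovitine	-0.33	Vorinostat	0.03	-0.69	0.066
Afatinib	-0.77	Niclosamide	-0.22	-0.69	0.057
Niclosamide	-0.22	Nvp-Bez235	-0.26	-0.68	1.459
Imatinib	-0.53	PD-184352	0.04	-0.67	0.796
Epirubicin	-0.31	Temsirolimus	-0.66	-0.67	0.572
Epirubicin	-0.31	AG-1478	-0.63	-0.65	6.617
3-Bromopyruvic acid	-0.64	MG-132	-0.41	-0.64	2.356
Etoposide	0.12	Selumetinib	0.85	-0.64	1.07
Paclitaxel	-0.54	Vemurafenib	-0.66	-0.6	-1.369
Epirubicin	-0.31	Vorinostat	0.03	-0.59	10.066
AG-1478	-0.63	Vorinostat	0.03	-0.59	8.697
Afatinib	-0.77	Mk-1775	-0.42	-0.59	0.063
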