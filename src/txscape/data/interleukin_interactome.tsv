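ligand	receptor	source
IL1A	IL1R1	HGNC-interleukins
IL1B	IL1R1	HGNC-interleukins
IL1RN	IL1R1	HGNC-interleukins
IL1A	IL1R2	HGNC-interleukins
IL1B	IL1R2	HGNC-interleukins
IL2	IL2RA	HGNC-interleukins
IL2	IL2RB	HGNC-interleukins
IL2	IL2RG	HGNC-interleukins
IL3	IL3RA	HGNC-interleukins
IL3	CSF2RB	HGNC-interleukin-receptors
IL4	IL4R	HGNC-interleukins
IL4	IL2RG	HGNC-interleukin-receptors
IL5	IL5RA	HGNC-interleukins
IL5	CSF2RB	HGNC-interleukin-receptors
IL6	IL6R	HGNC-interleukins
IL6	IL6ST	HGNC-interleukin-receptors
IL7	IL7R	HGNC-interleukins
IL7	IL2RG	HGNC-interleukin-receptors
IL9	IL9R	HGNC-interleukins
IL10	IL10RA	HGNC-interleukins
IL10	IL10RB	HGNC-interleukins
IL11	IL11RA	HGNC-interleukins
IL12A	IL12RB1	HGNC-interleukins
IL12A	IL12RB2	HGNC-interleukins
IL12B	IL12RB1	HGNC-interleukins
IL12B	IL12RB2	HGNC-interleukins
IL13	IL13RA1	HGNC-interleukins
IL13	IL13RA2	HGNC-interleukins
IL13	IL4R	HGNC-interleukin-receptors
IL15	IL15RA	HGNC-interleukins
IL15	IL2RB	HGNC-interleukin-receptors
IL15	IL2RG	HGNC-interleukin-receptors
IL16	CD4	literature-review
IL17A	IL17RA	HGNC-interleukins
IL17A	IL17RC	HGNC-interleukins
IL17F	IL17RA	HGNC-interleukins
IL17F	IL17RC	HGNC-interleukins
IL18	IL18R1	HGNC-interleukins
IL18	IL18RAP	HGNC-interleukins
IL19	IL20RA	HGNC-interleukins
IL19	IL20RB	HGNC-interleukins
IL20	IL20RA	HGNC-interleukins
IL20	IL20RB	HGNC-interleukins
IL20	IL22RA1	HGNC-interleukin-receptors
IL21	IL21R	HGNC-interleukins
IL21	IL2RG	HGNC-interleukin-receptors
IL22	IL22RA1	HGNC-interleukins
IL22	IL22RA2	HGNC-interleukins
IL22	IL10RB	HGNC-interleukin-receptors
IL23A	IL23R	HGNC-interleukins
IL23A	IL12RB1	HGNC-interleukin-receptors
IL24	IL20RA	HGNC-interleukins
IL24	IL20RB	HGNC-interleukins
IL24	IL22RA1	HGNC-interleukin-receptors
IL25	IL17RA	HGNC-interleukins
IL25	IL17RB	HGNC-interleukins
IL26	IL20RA	HGNC-interleukins
IL26	IL10RB	HGNC-interleukin-receptors
IL27	IL27RA	HGNC-interleukins
IL27	IL6ST	HGNC-interleukin-receptors
IL31	IL31RA	HGNC-interleukins
IL31	OSMR	HGNC-interleukin-receptors
IL33	IL1RL1	HGNC-interleukins
IL33	IL1RAP	HGNC-interleukin-receptors
IL34	CSF1R	literature-review
IL36A	IL1RL2	HGNC-interleukins
IL36B	IL1RL2	HGNC-interleukins
IL36G	IL1RL2	HGNC-interleukins
IL36RN	IL1RL2	HGNC-interleukins
IL37	IL18R1	literature-review
IFNA1	IFNAR1	HGNC-interferons
IFNA1	IFNAR2	HGNC-interferons
IFNA2	IFNAR1	HGNC-interferons
IFNA2	IFNAR2	HGNC-interferons
IFNB1	IFNAR1	HGNC-interferons
IFNB1	IFNAR2	HGNC-interferons
IFNG	IFNGR1	HGNC-interferons
IFNG	IFNGR2	HGNC-interferons
IFNL1	IFNLR1	HGNC-interferons
IFNL1	IL10RB	HGNC-interferons
IFNL2	IFNLR1	HGNC-interferons
IFNL3	IFNLR1	HGNC-interferons
TSLP	CRLF2	literature-review
TSLP	IL7R	literature-review
LIF	LIFR	literature-review
LIF	IL6ST	literature-review
OSM	OSMR	literature-review
OSM	IL6ST	literature-review
CNTF	CNTFR	literature-review
IL32	PR3	interaction-database
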