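# Per-species summary statistics transcribed from a published survey of 310
# COI barcodes representing 73 Thai mosquito species (percent scale).
# Columns: specimens n, haplotypes h, mean/min/max intraspecific K2P distance,
# Nei haplotype diversity +- SD, nearest-neighbour species and K2P distance.
# Empty intraspecific/diversity cells mark single-specimen species (N/C).
species	n	h	mean_intra_pct	min_intra_pct	max_intra_pct	hd	hd_sd	nn_species	nn_pct
Ad. catasticta	4	4	0.6	0.3	0.7	1.0	0.2	Lt. chiangmaiensis	10.6
Ae. aegypti	4	3	1.7	0.0	2.8	0.8	0.2	Ae. vexans	9.2
Ae. albopictus	5	3	0.2	0.0	0.4	0.7	0.2	Ae. lineatopennis	10.2
Ae. desmotes	2	2	0.1	0.1	0.1	1.0	0.5	Ae. vittatus	9.5
Ae. lineatopennis	4	4	1.0	0.1	1.3	1.0	0.2	Ae. vittatus	7.6
Ae. poicilius	2	1	0.0	0.0	0.0	0.0	0.0	Cx. sitiens	10.4
Ae. vexans	7	7	0.8	0.1	1.4	1.0	0.1	Ae. vittatus	8.1
Ae. vittatus	5	3	0.5	0.0	1.1	0.7	0.2	Ae. lineatopennis	7.6
An. aconitus	5	5	0.9	0.1	2.0	1.0	0.1	An. minimus	8.1
An. annularis	6	4	2.6	0.0	4.3	0.8	0.2	An. culicifacies	7.6
An. baimaii	2	2	0.7	0.7	0.7	1.0	0.5	An. dirus	0.3
An. culicifacies	2	1	0.0	0.0	0.0	0.0	0.0	An. minimus	7.1
An. dirus	6	6	1.2	0.1	1.9	1.0	0.1	An. baimaii	0.3
An. dissidens	2	2	0.3	0.3	0.3	1.0	0.5	An. saeungae	3.3
An. dravidicus	6	3	0.1	0.0	0.3	0.6	0.2	An. maculatus	6.3
An. epiroticus	5	4	1.6	0.0	2.6	0.9	0.2	An. culicifacies	9.5
An. harrisoni	3	3	0.6	0.3	0.9	1.0	0.3	An. minimus	3.0
An. jamesii	4	4	1.0	0.1	1.7	1.0	0.2	An. maculatus	8.8
An. maculatus	5	4	0.3	0.0	0.4	0.9	0.2	An. dravidicus	6.3
An. minimus	5	3	0.6	0.0	1.0	0.8	0.2	An. harrisoni	3.0
An. nemophilous	1	1						An. dirus	5.6
An. nigerrimus	1	1						An. pursati	5.8
An. nitidus	3	3	0.2	0.1	0.3	1.0	0.3	An. pursati	4.0
An. nivipes	2	2	0.7	0.7	0.7	1.0	0.5	An. philippinensis	7.3
An. paraliae	6	3	0.3	0.0	1.0	0.6	0.2	An. peditaeniatus	4.1
An. peditaeniatus	1	1						An. paraliae	4.1
An. philippinensis	4	2	0.3	0.0	0.4	0.7	0.2	An. nivipes	7.3
An. pseudojamesi	6	6	1.4	0.1	2.0	1.0	0.1	An. philippinensis	8.5
An. pseudowillmori	2	2	1.0	1.0	1.0	1.0	0.5	An. dirus	9.3
An. pursati	3	3	0.5	0.4	0.6	1.0	0.3	An. nitidus	4.0
An. saeungae	2	2	0.7	0.7	0.7	1.0	0.5	An. wejchoochotei	1.9
An. sawadwongporni	6	4	0.2	0.0	0.3	0.9	0.1	An. maculatus	6.8
An. sinensis	2	2	0.3	0.3	0.3	1.0	0.5	An. paraliae	4.3
An. subpictus	4	3	1.6	0.0	2.9	0.8	0.2	An. paraliae	9.5
An. tessellatus	5	5	2.5	0.3	5.7	1.0	0.1	An. saeungae	7.8
An. vagus	3	3	1.1	1.0	1.1	1.0	0.3	An. paraliae	10.1
An. varuna	2	2	1.0	1.0	1.0	1.0	0.5	An. culicifacies	8.2
An. wejchoochotei	8	4	0.3	0.0	0.7	0.9	0.1	An. saeungae	1.9
Ar. durhami	6	1	0.0	0.0	0.0	0.0	0.0	Ar. subalbatus	9.1
Ar. flavus	2	1	0.0	0.0	0.0	0.0	0.0	Ar. malayi	9.9
Ar. malayi	1	1						Ar. subalbatus	9.4
Ar. subalbatus	5	2	0.1	0.0	0.1	0.4	0.2	Ae. lineatopennis	8.2
Co. macfarlanei	4	1	0.0	0.0	0.0	0.0	0.0	Oc. vigilax	9.5
Cq. crassipes	4	4	1.3	0.7	1.7	1.0	0.2	Cq. ochracea	11.7
Cq. ochracea	6	2	0.5	0.0	1.6	0.3	0.2	Co. macfarlanei	10.3
Cx. bicornutus	8	4	0.2	0.0	0.4	0.9	0.1	Cx. epidesmus	8.3
Cx. bitaeniorhynchus	4	3	0.1	0.0	0.3	0.8	0.2	Cx. epidesmus	4.6
Cx. brevipalpis	4	3	0.4	0.0	0.9	0.8	0.2	Cq. ochracea	10.6
Cx. epidesmus	3	3	0.8	0.6	1.0	1.0	0.3	Cx. bitaeniorhynchus	4.6
Cx. fuscocephala	5	1	0.0	0.0	0.0	0.0	0.0	Cx. epidesmus	6.6
Cx. gelidus	6	3	0.6	0.0	1.9	0.6	0.2	Cx. sitiens	5.3
Cx. infantulus	8	6	0.6	0.0	0.9	0.9	0.1	Cx. gelidus	6.6
Cx. murrelli	6	5	0.3	0.0	0.4	0.9	0.1	Cx. bitaeniorhynchus	6.3
Cx. nigropunctatus	7	7	0.9	0.1	1.6	1.0	0.1	Cx. pallidothorax	4.1
Cx. pallidothorax	7	5	0.6	0.0	0.9	0.9	0.1	Cx. nigropunctatus	4.1
Cx. pseudovishnui	2	1	0.0	0.0	0.0	0.0	0.0	Cx. vishnui	4.5
Cx. quinquefasciatus	8	2	0.1	0.0	0.1	0.4	0.2	Cx. pseudovishnui	7.3
Cx. sitiens	7	3	0.4	0.0	0.7	0.7	0.2	Cx. gelidus	5.3
Cx. tritaeniorhynchus	6	6	0.9	0.1	1.9	1.0	0.1	Cx. vishnui	4.8
Cx. vishnui	7	6	0.6	0.0	1.1	1.0	0.1	Cx. pseudovishnui	4.5
Lt. vorax	2	2	1.3	1.3	1.3	1.0	0.5	Lt. fuscana	4.5
Lt. fuscana	6	5	0.6	0.0	0.9	0.9	0.1	Lt. chiangmaiensis	1.6
Lt. chiangmaiensis	6	3	0.1	0.0	0.3	0.7	0.2	Lt. fuscana	1.6
Ma. annulifera	6	6	1.5	0.6	2.2	1.0	0.1	Ma. bonneae	12.3
Ma. bonneae	5	5	0.8	0.1	1.1	1.0	0.1	Ma. dives	4.8
Ma. dives	2	2	1.6	1.6	1.6	1.0	0.5	Ma. bonneae	4.8
Ma. indiana	3	2	0.3	0.0	0.4	0.7	0.3	Ma. bonneae	11.1
Ma. uniformis	6	4	0.3	0.0	0.9	0.8	0.2	Ma. bonneae	9.7
Mi. aurea	3	2	0.1	0.0	0.1	0.7	0.3	Lt. chiangmaiensis	12.4
Oc. vigilax	4	3	0.3	0.0	0.6	0.8	0.2	Ae. lineatopennis	9.5
Rh. longirostris	2	2	0.7	0.7	0.7	1.0	0.5	Ae. lineatopennis	9.0
Tx. splendens	2	1	0.0	0.0	0.0	0.0	0.0	Ae. poicilius	12.9
Ur. obscura	2	1	0.0	0.0	0.0	0.0	0.0	Ae. poicilius	12.0
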