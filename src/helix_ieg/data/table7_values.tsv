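assay	group	value
qpcr	control	5.53
qpcr	control	2.73
qpcr	control	1.11
qpcr	control	0.24
qpcr	control	0.25
qpcr	stimulated	2.99
qpcr	stimulated	6.5
qpcr	stimulated	NA
qpcr	stimulated	3.21
qpcr	stimulated	6.03
behavior_cs	control	23.3
behavior_cs	control	58.7
behavior_cs	control	45.3
behavior_cs	control	26
behavior_cs	control	36.7
behavior_cs	control	37.3
behavior_cs	control	23.3
behavior_ds	control	60.7
behavior_ds	control	57.7
behavior_ds	control	41.3
behavior_ds	control	64.3
behavior_ds	control	34
behavior_ds	control	40.3
behavior_ds	control	28.7
behavior_cs	unpaired	36.7
behavior_cs	unpaired	57.7
behavior_cs	unpaired	41.3
behavior_cs	unpaired	49.3
behavior_cs	unpaired	16.7
behavior_cs	unpaired	44.7
behavior_cs	unpaired	54
behavior_ds	unpaired	42
behavior_ds	unpaired	33.7
behavior_ds	unpaired	28.7
behavior_ds	unpaired	51.7
behavior_ds	unpaired	39
behavior_ds	unpaired	25.3
behavior_ds	unpaired	51
behavior_cs	paired	112.7
behavior_cs	paired	112.7
behavior_cs	paired	83
behavior_cs	paired	109
behavior_cs	paired	90.7
behavior_cs	paired	120
behavior_cs	paired	102.7
behavior_ds	paired	45.3
behavior_ds	paired	54
behavior_ds	paired	31.3
behavior_ds	paired	38.7
behavior_ds	paired	60.7
behavior_ds	paired	56.3
behavior_ds	paired	66.7
pa2_training	control	283.3
pa2_training	control	332.7
pa2_training	control	71.3
pa2_training	control	131.7
pa2_training	control	328.7
pa2_training	trained	819.7
pa2_training	trained	1223
pa2_training	trained	470.3
pa2_training	trained	698.3
pa2_training	trained	1100.3
pa3_unilateral	stimulated	735.7
pa3_unilateral	stimulated	976
pa3_unilateral	stimulated	637
pa3_unilateral	stimulated	498.3
pa3_unilateral	stimulated	844.7
pa3_unilateral	control	284.7
pa3_unilateral	control	38.7
pa3_unilateral	control	310
pa3_unilateral	control	214.3
pa3_unilateral	control	58.7
pa2_pairing	unpaired	603.3
pa2_pairing	unpaired	1449.3
pa2_pairing	unpaired	1181.7
pa2_pairing	unpaired	347.7
pa2_pairing	unpaired	352.7
pa2_pairing	paired	1274.7
pa2_pairing	paired	536.3
pa2_pairing	paired	736
pa2_pairing	paired	582.7
pa2_pairing	paired	339.3
serotonergic	unpaired	355.7
serotonergic	unpaired	766.3
serotonergic	unpaired	459
serotonergic	unpaired	788.3
serotonergic	unpaired	436.3
serotonergic	paired	1789
serotonergic	paired	1344
serotonergic	paired	1511
serotonergic	paired	1329.7
serotonergic	paired	1082
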