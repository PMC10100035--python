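label,prior_prob,rank_1,rank_2,rank_3,rank_4,rank_5,rank_6,rank_7,rank_8,rank_9,rank_10,rank_11,rank_12,rank_13,rank_14,rank_15,rank_16,rank_17,rank_18,rank_19,rank_20
N dominant; then total average weekly dose of M,0.24,1,2,6,3,7,4,5,8,9,10,11,12,16,13,17,14,15,18,19,20
"N dominant; then schedule (low/moderate average-dose gaps), then total average dose",0.1,1,2,3,6,4,5,7,8,9,10,11,12,13,16,14,15,17,18,19,20
"N dominant; schedule for small gaps, average dose at the top",0.19,1,2,6,3,4,7,5,8,9,10,11,12,16,13,14,17,15,18,19,20
"N dominant; schedule up to moderate doses, single dose at the top",0.1,1,2,3,6,4,7,8,5,9,10,11,12,13,16,14,17,18,15,19,20
"N dominant; then single dose of M, schedule last",0.1,1,6,2,3,7,4,8,5,9,10,11,16,12,13,17,14,18,15,19,20
N dominant up to moderate average dose; then average dose,0.1,1,2,6,3,7,4,5,11,12,8,16,13,9,17,14,15,10,18,19,20
N dominant up to moderate average dose; then schedule,0.09,1,2,3,6,4,5,7,11,12,8,13,16,9,14,15,17,10,18,19,20
N dominant at low doses; schedule strong at the top,0.04,1,2,3,6,7,4,11,12,5,8,13,16,17,9,14,15,10,18,19,20
through the grid by total average weekly dose,0.02,1,11,2,6,12,16,3,13,7,17,4,14,5,8,15,18,9,19,10,20
through the grid by regimen index,0.02,1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20
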