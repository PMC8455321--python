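block,name,intervention_cost,disease_cost,total_cost,total_qalys,printed_incremental_cost,printed_incremental_qalys,printed_icer_next,printed_icer_baseline,printed_status
base_case,baseline,0,2898,2898,1135676,,,,,nondominated
base_case,wmp1,94,2814,2909,1154944,11,19269,557,557,nondominated
base_case,vlcd_wmp1,220,2812,3032,1155963,,,,6628,dominated
base_case,wmp2,135,2798,2933,1158386,,,,1540,extendedly_dominated
base_case,look_ahead,889,2754,3643,1167101,,,,23725,extendedly_dominated
base_case,rygb,2024,2295,4319,1276038,1411,121094,11648,10126,nondominated
regain_sensitivity,baseline,0,2898,2898,1135676,,,,,dominated
regain_sensitivity,vlcd_wmp1,220,2840,3060,1150251,,,,11152,dominated
regain_sensitivity,wmp1,94,2834,2928,1151112,,,,1965,dominated
regain_sensitivity,wmp2,135,2740,2875,1168178,,,,Dominant,nondominated
regain_sensitivity,look_ahead,889,2666,3555,1179771,,,,14906,extendedly_dominated
regain_sensitivity,rygb,2024,2295,4319,1276038,1444,107860,13392,10126,nondominated
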