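intervention,year_start,year_end,annual_cost
wmp1,1,1,619
wmp1,2,2,268
wmp1,3,3,60
wmp1,4,4,9
vlcd_wmp1,1,1,1893
vlcd_wmp1,2,2,268
vlcd_wmp1,3,3,60
vlcd_wmp1,4,4,9
wmp2,1,1,754
wmp2,2,2,152
wmp2,3,3,186
wmp2,4,4,204
wmp2,5,5,111
look_ahead,1,1,2189
look_ahead,2,2,1452
look_ahead,3,3,1270
look_ahead,4,4,1092
look_ahead,5,9,760
rygb,1,1,8253
rygb,2,2,1559
rygb,3,3,921
rygb,4,4,659
rygb,5,5,663
rygb,6,10,619
rygb,11,30,536
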