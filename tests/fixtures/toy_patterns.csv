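id,ipv_w1,ipv_w2,ipv_w3,ipv_w4,ipv_w5,ipv_w6,rel_w1,rel_w2,rel_w3,rel_w4,rel_w5,rel_w6,pstress_w1,pstress_w2,pstress_w3,pstress_w4,pstress_w5,pstress_w6,istress_w1,istress_w2,istress_w3,istress_w4,istress_w5,istress_w6,area,qual,expected_class
p01,Y,Y,Y,,,,,,,,,,,,,,,,,,,,,,,,consistent_ipv
p02,Y,Y,Y,Y,Y,Y,,,,,,,,,,,,,,,,,,,,,consistent_ipv
p03,N,Y,Y,,,,,,,,,,,,,,,,,,,,,,,,consistent_later_ipv
p04,N,N,Y,,,,,,,,,,,,,,,,,,,,,,,,consistent_later_ipv
p05,N,N,N,N,Y,Y,,,,,,,,,,,,,,,,,,,,,consistent_later_ipv
p06,N,N,N,,,,,,,,,,,,,,,,,,,,,,,,consistent_never_ipv
p07,N,N,N,N,N,N,,,,,,,,,,,,,,,,,,,,,consistent_never_ipv
p08,Y,N,Y,,,,,,,,,,,,,,,,,,,,,,,,mainly_ipv
p09,Y,Y,N,,,,,,,,,,,,,,,,,,,,,,,,mainly_ipv
p10,Y,Y,Y,N,Y,Y,,,,,,,,,,,,,,,,,,,,,mainly_ipv
p11,Y,N,N,,,,,,,,,,,,,,,,,,,,,,,,mainly_no_ipv
p12,N,Y,N,,,,,,,,,,,,,,,,,,,,,,,,mainly_no_ipv
p13,Y,N,N,N,N,N,,,,,,,,,,,,,,,,,,,,,mainly_no_ipv
p14,Y,N,Y,N,,,,,,,,,,,,,,,,,,,,,,,mixed_ipv
p15,Y,N,N,Y,,,,,,,,,,,,,,,,,,,,,,,mixed_ipv
p16,Y,N,N,N,Y,N,,,,,,,,,,,,,,,,,,,,,mixed_ipv
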