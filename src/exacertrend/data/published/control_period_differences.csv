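year,quarter,diff,pct_change,ci_lo,ci_hi
2020,1,-6.6,-8.3,-16.0,2.8
2020,2,-21.6,-39.7,-24.3,-18.8
2020,3,-24.3,-46.5,-29.5,-19.2
2020,4,-43.6,-56.3,-49.5,-37.7
2021,1,-50.5,-63.2,-57.9,-43.1
2021,2,-31.3,-57.7,-33.9,-28.7
2021,3,-27.9,-53.3,-32.9,-22.9
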