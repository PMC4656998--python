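season,field_id,area_m2,I_m,d_m,K_d_pct,kd_below_lod,K_c_pct,kc_below_lod,gm_simplified_kd_pct,gm_simplified_kd_kc_pct,gm_standard_pct,note
2006,17,15128,27.11,8,0.48,False,0.25,False,0.51,0.48,0.64,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2006,30,14782,26.12,8,0.24,False,0.05,False,0.22,0.24,0.31,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2006,40,11621,22.05,8,0.11,False,0.03,False,0.11,0.12,0.16,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2006,105,15870,30.94,8,0.85,False,0.25,False,0.75,0.79,1.01,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2006,192,10481,25.32,8,0.24,False,0.10,False,0.25,0.25,0.41,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,187,22015,35.05,6,0.00,True,0.00,True,0.01,0.01,0.01,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,101,8755,21.89,6,0.24,False,0.10,False,0.22,0.22,0.17,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,103,7050,12.67,6,0.11,False,0.05,False,0.13,0.13,0.14,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,115,10481,15.86,6,0.43,False,0.15,False,0.46,0.47,0.87,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,192,10473,25.30,6,1.03,False,0.30,False,0.84,0.89,1.07,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,196,5217,18.37,6,1.22,False,0.42,False,1.16,1.24,1.44,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2007,17,15128,27.11,6,1.94,False,1.31,False,2.00,1.61,2.32,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2008,1,292099,175.00,6,0.18,False,0.00,True,0.05,0.05,0.04,printed simplified estimates not reproducible from K_d column (pooled qPCR reading)
2012,147,4772,14.46,3,0.35,False,0.20,False,0.31,0.29,0.24,printed K_3-only estimate not reproducible from K_d column
2012,149,4829,16.15,3,0.39,False,0.37,False,0.38,0.26,0.41,printed simplified estimates not reproducible from K_d column
2013,2A,2134,6.37,3,0.01,False,0.01,False,0.01,0.01,0.07,
2013,2B,10766,22.57,3,0.04,False,0.00,True,0.02,0.02,0.01,
2013,3,16766,26.57,3,0.06,False,0.00,True,0.03,0.03,0.16,
2013,4,4232,12.02,3,0.06,False,0.02,False,0.05,0.05,0.12,
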