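study_id,route,cmax_observed,cmax_predicted,cmax_ratio_printed,auc0t_observed,auc0t_predicted,auc0t_ratio_printed,cl_observed,cl_predicted,cl_ratio_printed
iv_1988_155,iv,1716.74,1457.96,1.17,6587.57,5405.63,1.21,16.9,20.6,0.82
iv_1988_310,iv,2321.71,2017.4,1.15,12607.25,11122.39,1.13,12,20.36,0.6
iv_1989_155,iv,2105.9,1517.82,1.38,8649.54,5553.82,1.55,10.2,20.27,0.51
iv_1992_155,iv,1287.03,1280.82,1.0,3984.54,3364.52,1.18,31.05,26.85,1.15
oral_1988_v1w1,oral,249.18,251.96,0.98,5812.48,6566.34,0.88,38.94,37.98,1.02
oral_1988_v1w4,oral,311.932,236.80,1.31,17952.57,9209.71,1.94,10.06,25.59,0.5
oral_1988_v2w1,oral,261.05,264.16,0.98,8237.36,9667.94,0.85,28.78,24.59,1.17
oral_1988_v2w4,oral,311.932,236.80,1.31,17938.45,9210.98,1.94,10.12,25.51,0.5
oral_1989_155,oral,180.77,197.96,0.91,5470.81,4596.05,1.19,21.56,24.05,0.89
oral_1992_155,oral,183.5,214.80,0.85,2432.33,3680.55,0.66,52.32,28.29,1.84
oral_1995_200,oral,117.427,226.99,0.51,988.14,1799.07,0.54,110.03,76.76,1.43
oral_2012_200,oral,171.833,288.66,0.59,2446.55,3771.88,0.64,61.33,38.94,1.57
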