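	value
fit_slope_Control_CLIP_1	1.02822039697
fit_intercept_Control_CLIP_1	-0.659640337829
fit_slope_Control_CLIP_2	0.966598427398
fit_intercept_Control_CLIP_2	0.206651741535
fit_slope_Control_CLIP_3	0.995251787759
fit_intercept_Control_CLIP_3	-0.340622951248
fit_slope_Control_CLIP_4	0.960905384086
fit_intercept_Control_CLIP_4	0.297475774362
fit_slope_Opto_CLIP_1	1.09747155354
fit_intercept_Opto_CLIP_1	-2.37221940255
fit_slope_Opto_CLIP_2	1.05495059217
fit_intercept_Opto_CLIP_2	-2.38449548969
fit_slope_Opto_CLIP_3	1.05612525521
fit_intercept_Opto_CLIP_3	-2.35760143453
fit_slope_Opto_CLIP_4	1.0600342653
fit_intercept_Opto_CLIP_4	-1.98082981293
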