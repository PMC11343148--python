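sample	assay	condition	replicate
Control_CLIP_1	CLIP	Control	1
Control_CLIP_2	CLIP	Control	2
Control_CLIP_3	CLIP	Control	3
Control_CLIP_4	CLIP	Control	4
Opto_CLIP_1	CLIP	Opto	1
Opto_CLIP_2	CLIP	Opto	2
Opto_CLIP_3	CLIP	Opto	3
Opto_CLIP_4	CLIP	Opto	4
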