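sample	assay	condition	replicate
Control_RiboIP_1	RiboTag-IP	Control	1
Control_RiboInput_1	RiboTag-Input	Control	1
Control_RiboIP_2	RiboTag-IP	Control	2
Control_RiboInput_2	RiboTag-Input	Control	2
Control_RiboIP_3	RiboTag-IP	Control	3
Control_RiboInput_3	RiboTag-Input	Control	3
Opto_RiboIP_1	RiboTag-IP	Opto	1
Opto_RiboInput_1	RiboTag-Input	Opto	1
Opto_RiboIP_2	RiboTag-IP	Opto	2
Opto_RiboInput_2	RiboTag-Input	Opto	2
Opto_RiboIP_3	RiboTag-IP	Opto	3
Opto_RiboInput_3	RiboTag-Input	Opto	3
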