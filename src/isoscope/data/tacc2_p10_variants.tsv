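parent	pattern	length_change	change_symmetric
rex07	L0:R-465	-465	yes
rex08	L-4412:R0	-4412	no
rex08	L-4463:R0	-4463	no
rex08	L0:R-2445	-2445	yes
rex08	L0:R-2656	-2656	no
rex08	L0:R-4536	-4536	yes
rex08	L0:R-5231	-5231	no
rex09	L0:R-19	-19	no
rex11	L-11:R0	-11	no
rex11	L-47:R0	-47	no
rex16	L0:R12	12	yes
rex17	L0:R4	4	no
rex18	L-12:R0	-12	yes
rex19	L-13:R0	-13	no
rex19	L0:R93	93	yes
rex21	L-3:R0	-3	yes
rex23	L-4:R0	-4	no
rex23	L0:R4	4	no
rex24	L9:R0	9	yes
rex25	L0:R26	26	no
rex26	L0:R4	4	no
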