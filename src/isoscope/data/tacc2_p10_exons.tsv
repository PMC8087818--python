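name	exon_label	chrom	start	end	state	annotation
rex01	Ex1-2	chr10	123779335	123779396	stable	known
rex02	Ex2	chr10	123781451	123781529	stable	known
rex03	Ex2-3	chr10	123792608	123792668	rare	known
rex04	Ex2-3	chr10	123794962	123795075	rare	novel
rex05	Ex3	chr10	123809952	123810065	stable	known
rex06	Ex3-4	chr10	123822912	123823005	rare	novel
rex07	Ex3-4	chr10	123838491	123839151	rare	partially_known
rex08	Ex4	chr10	123842161	123847474	variable	known
rex09	Ex5	chr10	123847992	123848106	variable	known
rex10	Ex6	chr10	123892123	123892249	variable	known
rex11	Ex7	chr10	123903086	123903221	variable	known
rex12	Ex-8	chr10	123943555	123943720	rare	novel
rex13	Ex8	chr10	123954554	123954691	stable	known
rex14	Ex8-9	chr10	123962081	123962141	rare	partially_known
rex15	Ex8-9	chr10	123969388	123969484	rare	known
rex16	Ex9	chr10	123969911	123971223	stable	known
rex17	Ex9-10	chr10	123972856	123972892	rare	known
rex18	Ex10	chr10	123974905	123974966	stable	known
rex19	Ex11	chr10	123976141	123976343	stable	known
rex20	Ex12	chr10	123984240	123984302	stable	known
rex21	Ex13	chr10	123985880	123985996	stable	known
rex22	Ex14	chr10	123987351	123987523	stable	known
rex23	Ex15	chr10	123988860	123989001	rare	known
rex24	Ex17	chr10	123996909	123997053	stable	known
rex25	Ex18	chr10	123997475	123997552	stable	known
rex26	Ex19	chr10	124001472	124001516	stable	known
rex27	Ex20	chr10	124008157	124008318	stable	known
rex28	Ex21	chr10	124008564	124008671	stable	known
rex29	Ex22	chr10	124009058	124009089	stable	known
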