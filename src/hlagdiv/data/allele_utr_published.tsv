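allele	utr	global_frequency	internal_frequency
G*01:01:01:01	UTR-06	0.0027	0.0116
G*01:01:01:01	UTR-60	0.0002	0.0009
G*01:01:01:01	UTR-01	0.2277	0.9846
G*01:01:01:04	UTR-20	0.0036	0.1000
G*01:01:01:04	UTR-18	0.0198	0.5576
G*01:01:01:04	UTR-06	0.0121	0.3394
G*01:01:01:05	UTR-04	0.0704	0.9985
G*01:01:01:06	UTR-27	0.0002	0.0161
G*01:01:01:06	UTR-04	0.0131	0.9839
G*01:01:01:08	UTR-01	0.0204	1.0000
G*01:01:01:09	UTR-01	0.0033	1.0000
G*01:01:01:13	UTR-06	0.0066	1.0000
G*01:01:01:14Q	UTR-01	0.0004	1.0000
G*01:01:02:01	UTR-02	0.1470	0.9956
G*01:01:02:01	UTR-10	0.0002	0.0015
G*01:01:02:02	UTR-02	0.0045	1.0000
G*01:01:02:04	UTR-02	0.0015	1.0000
G*01:01:03:03	UTR-07	0.0744	0.9957
G*01:01:03:03	UTR-31	0.0002	0.0029
G*01:01:03:04	UTR-07	0.0002	1.0000
G*01:01:12	UTR-02	0.0022	1.0000
G*01:01:14	UTR-02	0.0025	1.0000
G*01:01:15	UTR-06	0.0039	1.0000
G*01:01:17	UTR-02	0.0026	1.0000
G*01:01:19	UTR-02	0.0017	1.0000
G*01:01:22:01	UTR-02	0.0128	1.0000
G*01:01:22:04	UTR-02	0.0004	1.0000
G*01:03:01:02	UTR-56	0.0029	0.0510
G*01:03:01:02	UTR-17	0.0038	0.0662
G*01:03:01:02	UTR-48	0.0004	0.0076
G*01:03:01:02	UTR-05	0.0499	0.8752
G*01:04:01:01	UTR-03	0.1211	0.9799
G*01:04:01:01	UTR-02	0.0004	0.0035
G*01:04:01:01	UTR-13	0.0018	0.0148
G*01:04:01:02	UTR-53	0.0002	0.0227
G*01:04:01:02	UTR-03	0.0093	0.9773
G*01:04:04	UTR-23	0.0009	0.0171
G*01:04:04	UTR-03	0.0495	0.9829
G*01:04:05	UTR-03	0.0027	1.0000
G*01:05N	UTR-02	0.0243	1.0000
G*01:06:01:01	UTR-02	0.0484	1.0000
G*01:06:01:02	UTR-02	0.0009	1.0000
G*01:08:02	UTR-02	0.0003	1.0000
G*01:11	UTR-03	0.0009	1.0000
G*01:14	UTR-05	0.0006	1.0000
G*01:21N	UTR-03	0.0002	1.0000
G*01:26	UTR-02	0.0002	1.0000
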