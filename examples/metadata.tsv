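sample	outcome	sex	age_z
S1	-0.61400	-0.93922	1.91630
S2	1.91556	-0.93922	1.62391
S3	1.59786	-0.93922	0.69736
S4	1.72348	-0.93922	-1.37674
S5	0.28321	-0.93922	2.06765
S6	-0.22847	1.03809	-0.35306
S7	-2.87060	-0.93922	-0.78040
S8	0.38921	1.03809	-1.07139
S9	1.82839	1.03809	-1.11047
S10	6.29386	-0.93922	0.05863
S11	4.71651	-0.93922	0.47808
S12	-1.56407	-0.93922	-0.94260
S13	-1.71693	1.03809	-0.75827
S14	-4.93539	-0.93922	-0.24127
S15	3.92384	1.03809	-0.37145
S16	0.23716	1.03809	-0.51857
S17	-0.07884	1.03809	-0.97995
S18	0.42763	-0.93922	-0.48906
S19	-1.92848	1.03809	-2.10344
S20	1.28532	1.03809	0.20910
S21	-0.02008	1.03809	-0.21597
S22	-1.60858	-0.93922	0.50815
S23	-0.73598	-0.93922	0.55787
S24	-0.91841	1.03809	-1.25225
S25	1.95321	1.03809	1.54540
S26	-0.49811	-0.93922	1.43888
S27	5.36834	-0.93922	0.98732
S28	-0.98907	1.03809	-0.39404
S29	3.30751	1.03809	0.58755
S30	-2.15534	-0.93922	-0.06302
S31	0.42642	1.03809	1.20636
S32	-0.67887	-0.93922	-0.24356
S33	1.97330	1.03809	-1.13019
S34	0.02137	-0.93922	-0.72874
S35	1.19526	1.03809	-0.49132
S36	-0.85410	-0.93922	0.93464
S37	0.40768	-0.93922	-0.76649
S38	0.55401	1.03809	0.20434
S39	-2.86338	1.03809	1.37886
S40	-3.20424	-0.93922	-0.01816
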