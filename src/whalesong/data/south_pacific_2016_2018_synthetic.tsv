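singer_id	location	year	song_type	duration_minutes	themes
FP16_1	FP	2016	1	32.0	1 2a 3 4 5 6 7a 8 1 2a 3 4 5 6 7a 8
FP16_2	FP	2016	1	28.5	1 2a 3 4 5 6 7a 8 1 2a 3 4 5 7a 8
FP16_3	FP	2016	1	21.0	1 2a 3 4 5 6 7a 8 1 2a 3 4
FP17_4	FP	2017	1	35.0	1 2b 3 4 5 6 7a 7b 8 1 2b 3 4 5 6 7a 8
FP17_5	FP	2017	2	30.0	9 10a 11 12 13 14 15 9 10a 11 12 13 14 15
FP17_6	FP	2017	2	26.0	9 10a 11 12 13 14 15 9 10a 11 12 13 15
FP18_7	FP	2018	1+3	24.0	1 2b 4 5 7a 8 21 22 1 2b 4 5 7a 8
FP18_8	FP	2018	1+2	33.0	1 2b 3 4 5 6 7a 7b 8 9 10b 1 2b 3 4 5 6 7a
FP18_9	FP	2018	3	18.0	20 21 22 23 20 21 22 23 20 21 22 23
EC16_10	EC	2016	4	27.0	24 25a 26 27 28 29a 30 31 32 33 24 25a 26 27 28 29a 30 31 32 33
EC16_11	EC	2016	4	22.0	24 25a 26 27 28 29a 30 31 32 33 24 25a 26 27 28 29a 30
EC16_12	EC	2016	4	31.0	24 25a 26 27 28 29a 30 31 32 33 24 25a 26 27 28 29a 30 31 33
EC17_13	EC	2017	4	36.0	24 25b 26 27 28 29a 29b 30 31 34 35 36 24 25b 26 27 28 29a 29b 30 31 34 35 36
EC17_14	EC	2017	4	29.0	24 25b 26 27 28 29a 29b 30 31 34 35 36 24 25b 26 27 28 29a 29b 30 31 34
EC17_15	EC	2017	4	14.0	24 25b 26 27 28 29a 29b 30 31 34 35 36
EC17_16	EC	2017	4	12.0	24 25b 26 27 28 29b 30 31 34 35
EC17_17	EC	2017	4	8.0	24 25b 26 27 28
EC17_18	EC	2017	4	6.5	29b 30 31 34
EC18_19	EC	2018	1	25.0	1 5 7a 16 17 18 19 1 5 7a 16 17 18 19
EC18_20	EC	2018	1	30.0	1 5 7a 16 17 18 19 1 5 7a 16 17 19
EC18_21	EC	2018	1	20.0	1 5 7a 16 17 18 19 1 5 7a 16
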