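name	chr	focal_position	from	to	length_avg_haplotype_sharing
SR1	1	12104888	12102020	12108376	6356
SR2	1	23826967	23824815	23829023	4208
SR3	3	16905787	16905273	16906447	1174
SR4	3	17859222	17858441	17860021	1580
SR5	4	198623	195197	201162	5965
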