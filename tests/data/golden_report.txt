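selected_d	4
recovery_angle_deg	8.92614514197791
csf_extent_original	1
csf_extent_first_level_original	207
csf_extent_gcca	89
csf_extent_first_level_gcca	1827
roi	n_subjects	mean_extent_original	mean_extent_gcca	pct_change_extent_mean	pct_change_extent_sd	paired_t_extent	paired_p_extent	mean_peak_t_original	mean_peak_t_gcca	pct_change_peak_t_mean	pct_change_peak_t_sd	paired_t_peak_t	paired_p_peak_t	mean_snr_original	mean_snr_gcca	pct_change_snr_mean	pct_change_snr_sd	paired_t_snr	paired_p_snr
EBA	25	76.28	78.0	2.434957739630099	4.555698714846912	2.7364861402070093	0.011500685483965094	14.075215252133182	21.56562779330019	54.63668643298924	22.998233687147664	13.838045662896032	6.198038380915665e-13	958.9618069018882	2827.6930689452547	199.74411076240213	79.23543239243986	16.023231545632402	2.558457439353926e-14
PMd	25	76.44	79.36	4.229042168439892	6.451810913228086	3.576970490115184	0.0015223106530429294	13.39187163404134	20.94986616097925	58.856339007048604	19.404866108824393	18.760554268560174	7.609589823575722e-16	1019.4555992809022	3006.087372399652	199.74411076240216	79.23543239243989	16.022810413130532	2.55993902642496e-14
PMv	25	58.72	75.08	33.08119443666335	30.28957681026364	7.779077579783007	5.162129313544537e-08	7.640098915130812	21.424439280890944	191.35319027314935	64.34029013969642	26.50745527781732	2.758685991795842e-19	981.3526989157665	2893.708247201355	199.7441107624021	79.23543239243986	16.02445370113685	2.5541628089886565e-14
SI	25	74.8	76.0	1.759687334393217	4.307610899036794	2.132455959932732	0.043401842780310444	13.899500605574122	21.102191794332366	53.35232490935937	19.928586333260153	16.57742396673575	1.2073176116208072e-14	981.9027794937277	2895.358029851025	199.74411076240213	79.23543239243985	16.02198710817056	2.5628380700712573e-14
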