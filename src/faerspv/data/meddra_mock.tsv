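pt_name	pt_code	soc_name	soc_code
Atrial fibrillation	90000001	Cardiac disorders	80000010
Myocardial infarction	90000002	Cardiac disorders	80000010
Cardiac failure congestive	90000003	Cardiac disorders	80000010
Cardiac disorder	90000004	Cardiac disorders	80000010
Cardiogenic shock	90000005	Cardiac disorders	80000010
Arteriosclerosis coronary artery	90000006	Cardiac disorders	80000010
Ventricular fibrillation	90000007	Cardiac disorders	80000010
Cardiac arrest	90000008	Cardiac disorders	80000010
Cardiac failure	90000009	Cardiac disorders	80000010
Palpitations	90000010	Cardiac disorders	80000010
Cardiomegaly	90000011	Cardiac disorders	80000010
Ventricular extrasystoles	90000012	Cardiac disorders	80000010
Coronary artery disease	90000013	Cardiac disorders	80000010
Tachycardia	90000014	Cardiac disorders	80000010
Bradycardia	90000015	Cardiac disorders	80000010
Angina pectoris	90000016	Cardiac disorders	80000010
Atrial flutter	90000017	Cardiac disorders	80000010
Acute myocardial infarction	90000018	Cardiac disorders	80000010
Cardio-respiratory arrest	90000019	Cardiac disorders	80000010
Supraventricular tachycardia	90000020	Cardiac disorders	80000010
Cardiac failure acute	90000021	Cardiac disorders	80000010
Cardiac failure chronic	90000022	Cardiac disorders	80000010
Myocardial ischaemia	90000023	Cardiac disorders	80000010
Dyspnoea	90000101	Respiratory, thoracic and mediastinal disorders	80000020
Chronic obstructive pulmonary disease	90000102	Respiratory, thoracic and mediastinal disorders	80000020
Cough	90000103	Respiratory, thoracic and mediastinal disorders	80000020
Wheezing	90000104	Respiratory, thoracic and mediastinal disorders	80000020
Pulmonary embolism	90000105	Respiratory, thoracic and mediastinal disorders	80000020
Respiratory failure	90000106	Respiratory, thoracic and mediastinal disorders	80000020
Asthma	90000107	Respiratory, thoracic and mediastinal disorders	80000020
Condition aggravated	90000201	General disorders and administration site conditions	80000030
Fatigue	90000202	General disorders and administration site conditions	80000030
Malaise	90000203	General disorders and administration site conditions	80000030
Death	90000204	General disorders and administration site conditions	80000030
Drug ineffective	90000205	General disorders and administration site conditions	80000030
Oedema peripheral	90000206	General disorders and administration site conditions	80000030
Blood pressure increased	90000301	Investigations	80000040
Heart rate increased	90000302	Investigations	80000040
Weight decreased	90000303	Investigations	80000040
Pneumonia	90000401	Infections and infestations	80000050
Bronchitis	90000402	Infections and infestations	80000050
Urinary tract infection	90000403	Infections and infestations	80000050
Headache	90000501	Nervous system disorders	80000060
Dizziness	90000502	Nervous system disorders	80000060
Tremor	90000503	Nervous system disorders	80000060
Cerebrovascular accident	90000504	Nervous system disorders	80000060
Thrombosis	90000601	Vascular disorders	80000070
Hypertension	90000602	Vascular disorders	80000070
Hypotension	90000603	Vascular disorders	80000070
Anxiety	90000701	Psychiatric disorders	80000080
Insomnia	90000702	Psychiatric disorders	80000080
Nausea	90000801	Gastrointestinal disorders	80000090
Diarrhoea	90000802	Gastrointestinal disorders	80000090
Vomiting	90000803	Gastrointestinal disorders	80000090
Rash	90000901	Skin and subcutaneous tissue disorders	80000100
Pruritus	90000902	Skin and subcutaneous tissue disorders	80000100
Fall	90001001	Injury, poisoning and procedural complications	80000110
Arthralgia	90001101	Musculoskeletal and connective tissue disorders	80000120
Muscle spasms	90001102	Musculoskeletal and connective tissue disorders	80000120
Decreased appetite	90001201	Metabolism and nutrition disorders	80000130
Acute kidney injury	90001301	Renal and urinary disorders	80000140
Vision blurred	90001401	Eye disorders	80000150
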