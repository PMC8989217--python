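name,base,low,high,family,units
p_uc,0.568,0.483,0.654,beta,proportion of ulcerative colitis among IBD patients
h_uc,0.186,0.158,0.213,beta,UC hospitalization probability per patient-year
s_uc,0.051,0.043,0.059,beta,UC surgery probability per hospitalization
m_uc,0.003,0.003,0.003,beta,UC in-hospital mortality probability
h_cd,0.225,0.191,0.258,beta,CD hospitalization probability per patient-year
s_cd,0.331,0.282,0.381,beta,CD surgery probability per hospitalization
m_cd,0.018,0.015,0.021,beta,CD in-hospital mortality probability
p_avoid,0.261,0.222,0.300,beta,proportion with medical avoidance during the pandemic
rr_avoid,1.156,1.050,1.329,lognormal,RR of hospitalization with healthcare avoidance
p_comply,0.590,0.502,0.679,beta,proportion meeting telemonitoring compliance requirement
rr_tm,0.364,0.310,0.419,lognormal,RR of hospitalization with weekly telemonitoring
cost_visit_uc,858,729,987,gamma,UC outpatient visits USD per patient-year
cost_meds_uc,3060,2607,3528,gamma,UC medications USD per patient-year
cost_imaging_uc,74,63,85,gamma,UC non-invasive diagnostic imaging USD per patient-year
cost_endoscopy_uc,3647,3100,4194,gamma,UC endoscopy USD per patient-year
cost_hosp_uc,7290,6197,8384,gamma,UC hospitalization USD per patient-year
cost_surgery_uc,5765,4900,6630,gamma,UC surgery USD per patient-year
cost_death_uc,26990,22942,31039,gamma,UC in-hospital death USD per patient-year
cost_visit_cd,1129,960,1298,gamma,CD outpatient visits USD per patient-year
cost_meds_cd,2894,2460,3328,gamma,CD medications USD per patient-year
cost_imaging_cd,485,412,558,gamma,CD non-invasive diagnostic imaging USD per patient-year
cost_endoscopy_cd,3328,2829,3827,gamma,CD endoscopy USD per patient-year
cost_hosp_cd,9389,7981,10797,gamma,CD hospitalization USD per patient-year
cost_surgery_cd,5534,4704,6364,gamma,CD surgery USD per patient-year
cost_death_cd,44596,37907,51285,gamma,CD in-hospital death USD per patient-year
visit_reduction,0.261,0.222,0.300,lognormal,relative reduction in outpatient-visit cost among avoiders
tm_maintenance,50,43,58,gamma,telemonitoring annual maintenance fee USD
tm_encounters,4.760,4.046,5.474,normal,excess telemonitoring-mediated encounters per patient-year
tm_encounter_hours,0.250,0.213,0.288,normal,length of each telemonitoring encounter in hours
tm_wage,101,86,116,gamma,specialist medical staff cost USD per hour
rr_imaging_tm,1.565,1.331,1.800,lognormal,relative increase of non-invasive diagnostics with telemonitoring
u_out,0.830,0.789,0.872,beta,utility of outpatient care
u_hosp,0.550,0.523,0.578,beta,utility of non-surgical hospitalization
u_surg,0.400,0.380,0.420,beta,utility of surgical hospitalization
wtp,46450,46450,46450,point,willingness-to-pay threshold USD per QALY
horizon,1,1,1,point,model time horizon in years
usd_to_hkd,7.8,7.8,7.8,point,currency conversion metadata HKD per USD
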