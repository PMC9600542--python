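report_id,drug,event_pt,continent,age_group,sex,serious,notifier
R01,omalizumab,Ear pain,Americas,45–65 years,Female,Yes,Physician
R01,omalizumab,Otorrhoea,Americas,45–65 years,Female,Yes,Physician
R02,mepolizumab,Ear discomfort,Europe,18–44 years,Male,No,Pharmacist
R02,omalizumab,Ear discomfort,Europe,18–44 years,Male,No,Pharmacist
R03,dupilumab,Eosinophil count abnormal,Asia,≥75 years,Female,Yes,Other Health Professional
R04,benralizumab,Asthma,Americas,Unknown,Unknown,Unknown,Consumer/Non-Health Professional
R04,benralizumab,Cough,Americas,Unknown,Unknown,Unknown,Consumer/Non-Health Professional
R05,reslizumab,Headache,Oceania,2–11 years,Male,No,Unknown
R06,omalizumab,Meniere's disease,Americas,65–74 years,Female,Yes,Physician
R07,mepolizumab,Ear disorder,Africa,12–17 years,Male,Yes,Lawyer
R07,mepolizumab,Ear pain,Africa,12–17 years,Male,Yes,Lawyer
R08,omalizumab,Eosinophilia,Europe,28 days to 23 months,Female,No,Physician
R08,omalizumab,Rash,Europe,28 days to 23 months,Female,No,Physician
R08,omalizumab,Urticaria,Europe,28 days to 23 months,Female,No,Physician
R09,dupilumab,Nasopharyngitis,Americas,0–27 days,Unknown,Unknown,Consumer/Non-Health Professional
R09,omalizumab,Nasopharyngitis,Americas,0–27 days,Unknown,Unknown,Consumer/Non-Health Professional
R10,omalizumab,Tympanic membrane perforation,Americas,45–65 years,Female,Yes,Other Health Professional
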