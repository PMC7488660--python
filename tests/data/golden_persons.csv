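person_id,birth_year,sex,qualification,income_group,income_value
P01,1980,male,vocational_training,low,12000
P02,1990,female,unknown,unknown,
P03,1955,male,master_craftsman,high,40000
P04,1948,female,not_applicable,middle,20000
P05,1985,male,no_vocational_training,low,9000
P06,1975,female,bachelor,middle,25000
P07,1992,male,vocational_training,unknown,
P08,1940,female,not_applicable,low,8000
P09,1970,male,diploma_master,high,50000
P10,2000,male,not_applicable,unknown,
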