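person_id,admission_date,main_dx,secondary_dx
P01,2017-03-10,I21.4,I10
P03,2017-08-15,I63.5,
P04,2016-05-20,I21.0,
P04,2017-04-02,I21.9,I10;E11.9
P06,2015-11-11,J18.9,I25.2
P06,2017-09-09,I21.1,
P07,2017-07-07,I64,
P08,2014-02-02,I60.7,
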