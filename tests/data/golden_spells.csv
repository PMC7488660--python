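person_id,start_date,end_date
P01,2012-01-01,2017-12-31
P02,2016-07-01,2017-12-31
P03,2012-01-01,2016-12-31
P03,2017-06-01,2017-12-31
P04,2012-01-01,2017-12-31
P05,2014-03-01,2017-12-31
P06,2013-01-01,2017-12-31
P07,2017-05-01,2017-12-31
P08,2012-01-01,2017-12-31
P09,2012-01-01,2016-12-30
P09,2017-01-01,2017-12-31
P10,2012-01-01,2017-12-31
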