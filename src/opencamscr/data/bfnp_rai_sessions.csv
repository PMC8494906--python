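# Published per-session summary of the unmarked-species camera-trap record
# from the Bavarian Forest National Park lynx survey (sessions 2009-2018):
# mean bootstrap event counts per species, camera sites and effective trap nights.
session,roe_deer_events,red_deer_events,red_fox_events,sites,trap_nights
2009,12,12,136,29,1238
2010,28,56,306,31,2786
2011,29,87,291,31,2914
2012,52,52,315,31,2621
2013,57,57,315,31,2865
2014,57,86,401,30,2865
2015,110,110,274,29,2745
2016,57,17,258,29,2871
2017,27,189,189,29,2698
2018,27,191,273,29,2732
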