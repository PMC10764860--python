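# Negative opinion terms (compact excerpt of a standard sentiment lexicon,
# restricted to the survey-domain vocabulary).
afraid
bad
clot
concern
danger
dangerous
death
die
doubt
fatal
fatality
fear
harm
hesitant
illness
pain
prolonged
risk
scared
sick
suffer
unsafe
unwilling
worried
worry
worse
worst
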