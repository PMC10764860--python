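# Positive opinion terms (compact excerpt of a standard sentiment lexicon,
# restricted to the survey-domain vocabulary).
assure
benefit
beneficial
best
better
confident
convince
effective
effectiveness
efficiency
encourage
free
good
happy
help
immune
protect
protection
safe
safety
trust
well
willing
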