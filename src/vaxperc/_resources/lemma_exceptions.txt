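# Irregular form -> lemma pairs, applied before suffix rules.
took take
taken take
children child
people people
men man
women woman
felt feel
saw see
thought think
got get
made make
went go
said say
gave give
better good
worse bad
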