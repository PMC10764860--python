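# Accepted lemma forms. A candidate produced by a suffix transformation is
# accepted only if it appears here; inflected forms absent from this list fall
# back to conservative suffix stripping. Participial / predicative terms that
# the word graphs display as-is (worried, vaccinated, confident, ...) are
# listed so the pipeline preserves them.
advice
advise
affect
age
appointment
assure
available
believe
blood
body
book
campaign
certificate
change
child
clot
colleague
confident
convince
country
death
decide
decision
disease
doctor
dose
effective
effectiveness
efficiency
family
fatality
fear
feel
fever
flight
free
friend
get
government
harm
health
help
hospital
hotel
illness
immunity
industry
job
kidney
long
lung
make
market
mask
media
member
money
neighbor
news
office
pain
parent
peer
people
person
prolonged
promote
protect
queue
reason
risk
safe
safety
school
see
seem
shop
shot
side
slot
society
spread
strain
supply
take
talk
think
time
tour
train
travel
trust
vaccinate
vaccinated
vaccination
vaccine
virus
wait
want
work
worried
worry
year
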