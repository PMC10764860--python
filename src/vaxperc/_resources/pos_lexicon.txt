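# Coarse part-of-speech lexicon: "word class" with class in {noun, verb}.
# Words absent here are classified by suffix heuristics (nouns by default).
# Participial / predicative transition markers (worried, vaccinated,
# confident, safe, effective, prolonged) are grouped with verbs, the way the
# association-graph figures present them.
advice noun
advise verb
affect verb
age noun
appointment noun
assure verb
available verb
believe verb
blood noun
body noun
book verb
campaign noun
certificate noun
change verb
child noun
clot noun
colleague noun
confident verb
convince verb
country noun
death noun
decide verb
decision noun
disease noun
doctor noun
dose noun
effective verb
effectiveness noun
efficiency noun
family noun
fatality noun
fear verb
feel verb
fever noun
flight noun
friend noun
get verb
government noun
harm noun
health noun
help verb
hospital noun
hotel noun
illness noun
immunity noun
industry noun
kidney noun
long verb
lung noun
make verb
market noun
mask noun
media noun
member noun
money noun
neighbor noun
news noun
pain noun
parent noun
peer noun
people noun
person noun
prolonged verb
promote verb
protect verb
queue noun
reason noun
risk noun
safe verb
safety noun
school noun
see verb
seem verb
shot noun
side noun
slot noun
society noun
spread verb
strain noun
supply noun
take verb
talk verb
think verb
time noun
tour noun
train noun
travel noun
trust verb
vaccinate verb
vaccinated verb
vaccination noun
vaccine noun
virus noun
wait verb
want verb
work noun
worried verb
worry verb
year noun
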