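# Terms marking peer / social-circle influence (purple nodes in the
# association-graph convention).
FamilyMembers
colleague
doctor
family
friend
member
neighbor
parent
peer
people
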