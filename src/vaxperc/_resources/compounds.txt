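# Multiword driver terms fused to a single canonical token, the form the
# word-association graphs display. Format: "spaced form -> CanonicalToken".
side effect -> SideEffects
side effects -> SideEffects
family member -> FamilyMembers
family members -> FamilyMembers
new strain -> NewStrain
new strains -> NewStrain
herd immunity -> HerdImmunity
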