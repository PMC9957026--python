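# Relation words signalling that a nearby military mention belongs to
# another person (family member or close contact), not the patient.
father
dad
stepfather
grandfather
grandad
granddad
grandpa
mother
mum
mom
stepmother
grandmother
grandma
nan
husband
wife
ex husband
ex wife
partner
boyfriend
girlfriend
son
daughter
brother
sister
stepbrother
stepsister
uncle
aunt
auntie
cousin
nephew
niece
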