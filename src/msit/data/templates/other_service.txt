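# Sentences describing another person's military service.
# {relation} is a relation word; {branch} a military branch phrase.
# The relation word always lies within five tokens of the military phrase,
# matching the attribution window the preprocessor assumes.
Her {relation} served in the {branch} when she was a child.
His {relation} was in the {branch} for many years.
Patient's {relation} is a veteran and talks about it often.
Grew up moving frequently because her {relation} was in the {branch}.
Worries about his {relation} who is a soldier currently deployed abroad.
States her {relation} served in the forces and rarely spoke of it.
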