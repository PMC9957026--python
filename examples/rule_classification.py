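"""Classify single notes with the stage-1 keyword rule.

The rule flags a note when a military phrase survives both other-person
attribution removal and confounder suppression; each printed decision shows
the surviving evidence.
"""

from msit import ClinicalDocument, default_lexicons, rule_classify

lex = default_lexicons()

notes = [
    "Patient served in the forces between 1989 and 1995.",
    "Her husband was in the army; she has never served.",
    "Receives food parcels from the Salvation Army each week.",
    "Describes fighting a losing battle with low mood.",
]

for i, text in enumerate(notes):
    doc = ClinicalDocument(doc_id=f"n{i}", patient_id="p0", text=text)
    dec = rule_classify(doc, lex["military"], lex["confounder"], lex["relation"])
    evidence = ", ".join(m.entry for m in dec.evidence) or "-"
    print(f"label={dec.label}  evidence=[{evidence}]  text={text!r}")

# Only the first note is evidence of the patient's own service: the family
# mention is attributed away, the charity mention is suppressed by span
# containment, and the metaphor never matches a lexicon entry.
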