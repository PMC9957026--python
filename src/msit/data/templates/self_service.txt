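# Sentences disclosing the patient's own military service.
# {branch} is filled with a service-branch phrase from the military lexicon.
# Every line yields at least one surviving military match after
# normalization, with no relation word present.
Patient is a veteran and attends a local support group.
He served in the forces for several years before moving to London.
She describes her time in the {branch} as formative.
Previously served in the {branch} and was discharged on medical grounds.
Patient completed national service as a young adult.
Reports being a veteran of the {branch}.
Occupational history includes a period in the {branch}.
He was a soldier for six years and then retrained as an electrician.
States she enlisted at eighteen and left after one tour of duty.
Patient mentioned he was demobbed after the conflict ended.
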