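# Neutral psychiatric-note filler sentences. One per line.
# Co-designed with the default lexicons: no military, relation or confounder
# tokens appear here, so filler never interacts with attribution or
# suppression logic.
Patient attended the outpatient clinic today for a scheduled review.
Reports low mood and poor sleep over the past two weeks.
Medication reviewed and continued at the current dose.
Denies any thoughts of self harm at present.
Appetite reduced but weight stable since the last appointment.
Engaging well with the community mental health team.
Anxiety symptoms remain prominent in crowded places.
Discussed coping strategies and agreed a follow up in four weeks.
Mental state examination showed good eye contact and coherent speech.
Risk assessment completed with no acute concerns identified.
Reports occasional alcohol use at weekends.
Sleep hygiene advice provided and a diary requested.
Currently unemployed and looking for work locally.
Attended with a support worker from the housing team.
Mood described as flat with little interest in usual activities.
Concentration difficulties noted during the assessment.
No side effects reported from the current medication.
Plans to restart swimming as part of behavioural activation.
Lives alone in a first floor flat and manages daily tasks independently.
Referred to psychology for cognitive behavioural therapy.
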