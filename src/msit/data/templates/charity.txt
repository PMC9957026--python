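# Sentences mentioning charitable support with confounding vocabulary.
# "salvation army" contains the military term "army"; suppression and the
# confusion-term removal step must neutralize these.
Receives support from the Salvation Army with food parcels.
Currently staying at a Salvation Army hostel in the area.
Volunteers at the local Salvation Army shop twice a week.
Was referred to the Salvation Army for emergency accommodation.
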